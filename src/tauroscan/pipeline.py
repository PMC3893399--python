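"""File-level pipeline stages and the end-to-end run.

Every stage reads and writes ordinary files (VCF / TSV / BED), so each is
runnable standalone on the outputs of any earlier stage; :func:`run_all` is
exactly their composition.  With a fixed config and master seed the emitted
report is byte-identical between runs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, ancestry, mixed_model
from .io import GenotypeMatrix, read_phenotypes, read_vcf, write_ancestry_bed
from .simulate import SimConfig, simulate_dataset, write_simulation

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    out_dir: str = "tauroscan_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    window_size: int = ancestry.DEFAULT_WINDOW_SIZE
    thresholds: tuple[float, float] = ancestry.DEFAULT_THRESHOLDS
    denominator: str = "classified_only"
    traits: tuple = SimConfig.trait_names
    fixed_effects: tuple = ("contemporary_group", "year_month")
    exact_reml: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the master seed drives every stage through SimConfig.seed
        self.sim = replace_seed(self.sim, self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in fields(cls)}})
        if sim_raw:
            sim_raw.setdefault("seed", cfg.seed)
            cfg.sim = SimConfig(**{**vars(cfg.sim), **sim_raw})
            cfg.sim = replace_seed(cfg.sim, cfg.seed)
        return cfg


def replace_seed(sim: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace
    return replace(sim, seed=seed)


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
    return _T()


def _candidate_genotypes(gm: GenotypeMatrix, snp_id: str) -> dict[str, int]:
    m = gm.marker_index(snp_id)
    col = gm.counts[:, m]
    if (col < 0).any():
        missing = [gm.animal_ids[i] for i in np.nonzero(col < 0)[0]]
        raise ValueError(f"missing candidate-SNP call for: {missing[:5]}")
    return dict(zip(gm.animal_ids, col.astype(int)))


def stage_simulate(cfg: RunConfig):
    with _timed("simulate"):
        ds = simulate_dataset(cfg.sim)
        write_simulation(ds, Path(cfg.out_dir) / "sim")
    return ds


def stage_paint(targets_vcf, panel_taurus_vcf, panel_indicus_vcf, out_dir,
                window_size=ancestry.DEFAULT_WINDOW_SIZE,
                thresholds=ancestry.DEFAULT_THRESHOLDS,
                denominator="classified_only",
                group_snp_id: str | None = None,
                window_range: tuple[int, int] | None = None):
    """Paint target animals; write BED, per-window profiles and per-animal
    proportions; optionally contrast allele groups at ``group_snp_id``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with _timed("paint"):
        targets = read_vcf(targets_vcf)
        ref_t = read_vcf(panel_taurus_vcf)
        ref_i = read_vcf(panel_indicus_vcf)
        paintings = ancestry.paint_all(targets, ref_t, ref_i, window_size, thresholds)
        all_calls = [c for calls in paintings.values() for c in calls]
        write_ancestry_bed(all_calls, out_dir / "painting.bed")
        props = pd.DataFrame({
            "animal_id": list(paintings),
            "taurine_proportion": [ancestry.taurine_proportion(v, denominator)
                                   for v in paintings.values()],
        })
        props.to_csv(out_dir / "taurine_proportions.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
        profile = summary = None
        if group_snp_id is not None:
            groups = _candidate_genotypes(targets, group_snp_id)
            profile, summary = ancestry.allele_group_profile(paintings, groups,
                                                             window_range)
            profile.to_csv(out_dir / "window_profiles.tsv", sep="\t",
                           float_format=FLOAT_FMT)
            summary.to_csv(out_dir / "group_profile_summary.tsv", sep="\t",
                           float_format=FLOAT_FMT)
    return paintings, profile, summary


def stage_admix(targets_vcf, panel_taurus_vcf, panel_indicus_vcf, out_dir,
                label: str = "alpha", group_by: tuple[str, str] | None = None):
    """Estimate per-animal taurine proportion; optionally summarize by the
    allele groups of ``group_by = (vcf_with_the_snp, snp_id)``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with _timed(f"admix[{label}]"):
        targets = read_vcf(targets_vcf)
        freqs_t = admixture.panel_frequencies(read_vcf(panel_taurus_vcf))
        freqs_i = admixture.panel_frequencies(read_vcf(panel_indicus_vcf))
        ests = admixture.estimate_alpha_all(targets, freqs_t, freqs_i)
        df = pd.DataFrame([vars(e) for e in ests])
        df.to_csv(out_dir / f"{label}_estimates.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
        summary = None
        if group_by is not None:
            vcf_path, snp_id = group_by
            groups = _candidate_genotypes(read_vcf(vcf_path), snp_id)
            summary = admixture.group_alpha_summary(ests, groups)
            summary.to_csv(out_dir / f"{label}_group_summary.tsv", sep="\t",
                           float_format=FLOAT_FMT)
    return ests, summary


def stage_assoc(vcf, pheno_tsv, out_dir, snp_ids, traits,
                fixed=("contemporary_group", "year_month"),
                exact=False, grm_vcfs=()):
    """Mixed-model association of the listed SNPs against the listed traits.

    The GRM is computed from the test VCF's markers plus any ``grm_vcfs``
    (e.g. the genome-background markers)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with _timed("assoc"):
        gm = read_vcf(vcf)
        counts = gm.counts
        for extra in grm_vcfs:
            other = read_vcf(extra)
            if other.animal_ids != gm.animal_ids:
                raise ValueError("GRM VCFs must cover the same animals in order")
            counts = np.hstack([counts, other.counts])
        grm_gm = GenotypeMatrix(
            animal_ids=list(gm.animal_ids),
            marker_ids=[f"m{i}" for i in range(counts.shape[1])],
            chrom="NA", positions=100_000 * (1 + np.arange(counts.shape[1])),
            alleles=[("A", "G")] * counts.shape[1], counts=counts,
            ploidy=gm.ploidy.copy())
        kin = mixed_model.compute_grm(grm_gm)
        pheno = read_phenotypes(pheno_tsv, traits)
        table = mixed_model.association_table(gm, pheno, kin, snp_ids,
                                              traits=list(traits),
                                              factors=tuple(fixed), exact=exact)
        table.to_csv(out_dir / "association.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
    return table


def _fmt_df(df: pd.DataFrame) -> str:
    return df.to_string(float_format=lambda x: FLOAT_FMT % x)


def run_all(cfg: RunConfig) -> str:
    """simulate -> paint -> global ancestry -> association; returns the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = stage_simulate(cfg)
    sim_dir = out / "sim"
    candidate_id = ds.targets.marker_ids[cfg.sim.candidate_snp_index]
    lo, hi = cfg.sim.tract_interval
    tract_windows = (lo // cfg.window_size, -(-hi // cfg.window_size))

    _, profile, paint_summary = stage_paint(
        sim_dir / "targets.vcf", sim_dir / "panel_taurus.vcf",
        sim_dir / "panel_indicus.vcf", out / "paint",
        cfg.window_size, cfg.thresholds, cfg.denominator,
        group_snp_id=candidate_id, window_range=tract_windows)

    _, x_summary = stage_admix(
        sim_dir / "targets.vcf", sim_dir / "panel_taurus.vcf",
        sim_dir / "panel_indicus.vcf", out / "admix", label="alpha_x",
        group_by=(str(sim_dir / "targets.vcf"), candidate_id))
    genome_summary = None
    if ds.targets_bg is not None:
        _, genome_summary = stage_admix(
            sim_dir / "background_targets.vcf",
            sim_dir / "background_panel_taurus.vcf",
            sim_dir / "background_panel_indicus.vcf", out / "admix",
            label="alpha_genome",
            group_by=(str(sim_dir / "targets.vcf"), candidate_id))

    grm_extra = [sim_dir / "background_targets.vcf"] if ds.targets_bg is not None else []
    assoc = stage_assoc(sim_dir / "targets.vcf", sim_dir / "phenotypes.tsv",
                        out / "assoc", [candidate_id], list(cfg.traits),
                        fixed=cfg.fixed_effects, exact=cfg.exact_reml,
                        grm_vcfs=grm_extra)

    lines = [
        "tauroscan end-to-end report",
        f"seed: {cfg.seed}",
        f"candidate SNP: {candidate_id} (favourable allele "
        f"{ds.truth.favourable_allele})",
        f"tract windows: [{tract_windows[0]}, {tract_windows[1]})",
        "",
        "Taurine-fraction profile by candidate allele group "
        "(mean/min/max over tract windows):",
        _fmt_df(paint_summary),
        "",
        "Global taurine proportion (alpha) by allele group, X markers:",
        _fmt_df(x_summary),
    ]
    if genome_summary is not None:
        lines += ["",
                  "Global taurine proportion (alpha) by allele group, "
                  "genome-background markers:",
                  _fmt_df(genome_summary)]
    lines += ["", "Mixed-model association (candidate SNP):", _fmt_df(assoc), ""]
    report = "\n".join(lines)
    (out / "report.txt").write_text(report)
    return report
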