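"""Synthetic admixed-cattle data with the statistical structure the analysis
assumes: two divergent ancestral populations (Balding-Nichols allele
frequencies), haploid reference panels, an indicine-dominant admixed target
population of bulls whose hemizygous X carries a high-frequency taurine tract
around a candidate locus, and phenotypes with contemporary-group fixed
effects, a polygenic component and a candidate-SNP effect.

Each animal's X is an ancestry mosaic: a two-state switch process along
genetic distance with stationary taurine probability ``baseline_taurine``
(breakpoints Poisson at ``switch_rate_per_morgan`` per Morgan, emulating some
tens of generations since admixture), overridden inside ``tract_interval``
where the haplotype is taurine with probability ``tract_taurine_freq``.  The
candidate SNP is made strongly ancestry-informative so that its alleles tag
the tract, the way the real tag SNP separates carriers of the selected
taurine haplotype.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .io import GenotypeMatrix, PhenotypeTable, write_phenotypes, write_vcf
from .mixed_model import KinshipMatrix, compute_grm

import pandas as pd

FREQ_CLIP = (0.01, 0.99)        # avoid degenerate monomorphic markers
TAG_SNP_FREQS = (0.98, 0.02)    # taurine / indicine alt frequency at the candidate
DEFAULT_TRAITS = ("SC12", "SC18", "SC24", "PNS18", "PNS24")
GROUP_EFFECT_SD = 0.5           # contemporary-group spread, phenotypic SD units
YEAR_MONTH_EFFECT_SD = 0.3
N_YEAR_MONTH_LEVELS = 6
PHENOTYPIC_VARIANCE = 1.0       # sigma_g2 + sigma_e2; trait units are arbitrary


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) derived from the master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic scenario.

    Defaults mirror the study design: a ~50k-chip-density X chromosome
    (1,000 SNPs -> 100 ten-SNP windows), strong taurine/indicine divergence
    (fst 0.3), reference panels of 3,666 taurine and 1,105 indicine
    haplotypes, an indicine-dominant population with 2.5% baseline taurine
    content, and a 5-window tract where the taurine haplotype segregates at
    frequency 0.67 (the 67%-vs-1.33% contrast, qualitatively).
    """

    seed: int = 0
    n_snps: int = 1000
    n_ref_taurus: int = 3666
    n_ref_indicus: int = 1105
    fst: float = 0.3
    n_animals: int = 500
    baseline_taurine: float = 0.025
    tract_interval: tuple[int, int] | None = (500, 550)
    tract_taurine_freq: float = 0.67
    candidate_snp_index: int | None = 525
    morgans: float = 1.0
    switch_rate_per_morgan: float = 20.0
    n_groups: int = 5
    h2: float = 0.4
    snp_effect: float = 1.0
    trait_names: tuple = DEFAULT_TRAITS
    n_background_snps: int = 1000
    n_founder_haplotypes: int | None = 30
    window_size: int = 10
    tag_candidate: bool = True
    chrom: str = "X"

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 <= self.baseline_taurine <= 1:
            raise ValueError("baseline_taurine must be in [0, 1]")
        if not 0 <= self.tract_taurine_freq <= 1:
            raise ValueError("tract_taurine_freq must be in [0, 1]")
        if self.tract_interval is not None:
            lo, hi = self.tract_interval
            if not (0 <= lo < hi <= self.n_snps):
                raise ValueError("tract_interval must lie within [0, n_snps)")
            if self.candidate_snp_index is not None and not (
                    lo <= self.candidate_snp_index < hi):
                raise ValueError("candidate_snp_index must lie inside tract_interval")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    ancestry_mask: np.ndarray                 # animals x markers, 1 = taurine
    true_variance_components: tuple[float, float] = (np.nan, np.nan)
    true_snp_effect: float = np.nan
    true_group_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    background_mask: np.ndarray | None = None
    candidate_snp_index: int | None = None
    favourable_allele: str | None = None

    def __post_init__(self) -> None:
        if not np.isin(self.ancestry_mask, (0, 1)).all():
            raise ValueError("ancestry mask must be binary")


def simulate_ancestral_frequencies(n_snps: int, fst: float,
                                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-marker allele frequencies under the Balding-Nichols model.

    An ancestral frequency p ~ U(0.05, 0.95) per marker; each descendant
    population draws its frequency from Beta(p (1-F)/F, (1-p)(1-F)/F) so the
    expected divergence matches the target FST.  Frequencies are clipped to
    [0.01, 0.99].
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, n_snps)
    shape = (1 - fst) / fst
    p_t = rng.beta(anc * shape, (1 - anc) * shape)
    p_i = rng.beta(anc * shape, (1 - anc) * shape)
    return np.clip(p_t, *FREQ_CLIP), np.clip(p_i, *FREQ_CLIP)


def default_positions(n_snps: int) -> np.ndarray:
    """1-based bp positions at even ~100 kb chip-like spacing."""
    return 100_000 * (1 + np.arange(n_snps, dtype=np.int64))


def _marker_ids(chrom: str, n: int) -> list[str]:
    return [f"{chrom}_snp{m:05d}" for m in range(n)]


def _make_matrix(counts: np.ndarray, chrom: str, prefix: str) -> GenotypeMatrix:
    n, m = counts.shape
    return GenotypeMatrix(
        animal_ids=[f"{prefix}{i:05d}" for i in range(n)],
        marker_ids=_marker_ids(chrom, m),
        chrom=chrom,
        positions=default_positions(m),
        alleles=[("A", "G")] * m,
        counts=counts.astype(np.int8),
        ploidy=np.ones(n, dtype=np.int8),
    )


def simulate_reference_panels(freqs: tuple[np.ndarray, np.ndarray],
                              n_ref_taurus: int, n_ref_indicus: int,
                              seed: int, chrom: str = "X"
                              ) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Haploid reference panels drawn marker-independently from each frequency
    vector (panel haplotypes carry no LD beyond ancestry)."""
    if n_ref_taurus < 1 or n_ref_indicus < 1:
        raise ValueError("panel sizes must be >= 1")
    p_t, p_i = freqs
    rng = np.random.default_rng(seed)
    taur = (rng.random((n_ref_taurus, len(p_t))) < p_t).astype(np.int8)
    indi = (rng.random((n_ref_indicus, len(p_i))) < p_i).astype(np.int8)
    return (_make_matrix(taur, chrom, "T"), _make_matrix(indi, chrom, "I"))


def simulate_admixed_animals(freqs: tuple[np.ndarray, np.ndarray],
                             config: SimConfig, seed: int | None = None,
                             chrom: str | None = None,
                             pools: HaplotypePools | None = None
                             ) -> tuple[GenotypeMatrix, SimTruth]:
    """Hemizygous admixed bulls with a mosaic X and an optional taurine tract.

    With ``pools`` the alleles come from the founder-haplotype pools
    (within-breed LD); otherwise each marker is drawn independently from the
    ancestry-matched frequency vector.
    """
    p_t, p_i = freqs
    n_snps = len(p_t)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gpos = (np.arange(n_snps) + 0.5) / n_snps * config.morgans
    lam = config.morgans * config.switch_rate_per_morgan
    mask = np.zeros((config.n_animals, n_snps), dtype=np.int8)
    tract_carrier = np.zeros(config.n_animals, dtype=bool)
    for i in range(config.n_animals):
        n_breaks = rng.poisson(lam)
        breaks = np.sort(rng.uniform(0, config.morgans, n_breaks))
        seg_anc = rng.random(n_breaks + 1) < config.baseline_taurine
        mask[i] = seg_anc[np.searchsorted(breaks, gpos)]
        if config.tract_interval is not None:
            lo, hi = config.tract_interval
            if rng.random() < config.tract_taurine_freq:
                mask[i, lo:hi] = 1
                tract_carrier[i] = True
    if pools is not None:
        counts = _draw_from_pools(pools, mask, tract_carrier, freqs, rng)
    else:
        probs = np.where(mask == 1, p_t, p_i)
        counts = (rng.random(mask.shape) < probs).astype(np.int8)
    gm = _make_matrix(counts, chrom or config.chrom, "A")
    fav = None
    if config.candidate_snp_index is not None:
        c = config.candidate_snp_index
        fav = "G" if p_t[c] > p_i[c] else "A"  # allele elevated in the taurine vector
    truth = SimTruth(ancestry_mask=mask, candidate_snp_index=config.candidate_snp_index,
                     favourable_allele=fav)
    return gm, truth


@dataclass
class HaplotypePools:
    """Per-window founder haplotypes of each ancestral population.

    Real breeds carry limited 10-SNP haplotype diversity (strong within-breed
    LD); the frequency-ratio painting method relies on it.  Each window holds
    ``n_founders`` founder haplotypes per population, drawn from that
    population's allele-frequency vector, with Dirichlet(1) frequencies.
    A swept taurine lineage (one founder per tract window) models the
    positively selected tract; it carries the favourable candidate allele.
    """

    window_size: int
    n_snps: int
    founders_t: list[np.ndarray]     # per window: K x window_size in {0,1}
    founders_i: list[np.ndarray]
    weights_t: list[np.ndarray]
    weights_i: list[np.ndarray]
    swept_founder: dict[int, int]    # tract window index -> taurine founder row

    @property
    def n_windows(self) -> int:
        return len(self.founders_t)


def simulate_founder_pools(freqs: tuple[np.ndarray, np.ndarray],
                           config: SimConfig, seed: int) -> HaplotypePools:
    """Draw the per-window founder haplotype pools for both populations."""
    p_t, p_i = freqs
    n_snps = len(p_t)
    ws = config.window_size
    K = config.n_founder_haplotypes
    rng = np.random.default_rng(seed)
    founders_t, founders_i, weights_t, weights_i = [], [], [], []
    n_windows = n_snps // ws
    for w in range(n_windows):
        sl = slice(w * ws, (w + 1) * ws)
        founders_t.append((rng.random((K, ws)) < p_t[sl]).astype(np.int8))
        founders_i.append((rng.random((K, ws)) < p_i[sl]).astype(np.int8))
        weights_t.append(rng.dirichlet(np.ones(K)))
        weights_i.append(rng.dirichlet(np.ones(K)))
    swept: dict[int, int] = {}
    if config.tract_interval is not None:
        lo, hi = config.tract_interval
        for w in range(lo // ws, -(-hi // ws)):
            if w >= n_windows:
                continue
            swept[w] = int(rng.integers(config.n_founder_haplotypes))
        if config.candidate_snp_index is not None and config.tag_candidate:
            c = config.candidate_snp_index
            wc, off = divmod(c, ws)
            if wc in swept:
                # the swept lineage carries the favourable (taurine) allele
                founders_t[wc][swept[wc], off] = 1
    return HaplotypePools(ws, n_snps, founders_t, founders_i,
                          weights_t, weights_i, swept)


def _draw_from_pools(pools: HaplotypePools, mask: np.ndarray,
                     tract_carrier: np.ndarray,
                     freqs: tuple[np.ndarray, np.ndarray],
                     rng: np.random.Generator) -> np.ndarray:
    """Window-wise haplotype draws matching each animal's ancestry mask.

    Windows whose markers span both ancestries splice a taurine and an
    indicine founder draw at the mask; trailing markers beyond the last full
    window are drawn marker-independently.
    """
    n_animals, n_snps = mask.shape
    ws = pools.window_size
    counts = np.empty((n_animals, n_snps), dtype=np.int8)
    for w in range(pools.n_windows):
        sl = slice(w * ws, (w + 1) * ws)
        mwin = mask[:, sl]
        idx_t = rng.choice(len(pools.weights_t[w]), size=n_animals,
                           p=pools.weights_t[w])
        idx_i = rng.choice(len(pools.weights_i[w]), size=n_animals,
                           p=pools.weights_i[w])
        if w in pools.swept_founder:
            idx_t = np.where(tract_carrier, pools.swept_founder[w], idx_t)
        hap_t = pools.founders_t[w][idx_t]
        hap_i = pools.founders_i[w][idx_i]
        counts[:, sl] = np.where(mwin == 1, hap_t, hap_i)
    tail = slice(pools.n_windows * ws, n_snps)
    if tail.start < n_snps:
        p_t, p_i = freqs
        probs = np.where(mask[:, tail] == 1, p_t[tail], p_i[tail])
        counts[:, tail] = (rng.random(probs.shape) < probs).astype(np.int8)
    return counts


def sample_pool_panel(pools: HaplotypePools, population: str, n_haplotypes: int,
                      freqs: tuple[np.ndarray, np.ndarray],
                      seed: int, chrom: str = "X",
                      prefix: str = "P") -> GenotypeMatrix:
    """A haploid reference panel drawn from one population's founder pools."""
    if n_haplotypes < 1:
        raise ValueError("panel size must be >= 1")
    rng = np.random.default_rng(seed)
    anc = 1 if population == "taurus" else 0
    mask = np.full((n_haplotypes, pools.n_snps), anc, dtype=np.int8)
    carrier = np.zeros(n_haplotypes, dtype=bool)   # panels are not swept
    counts = _draw_from_pools(pools, mask, carrier, freqs, rng)
    return _make_matrix(counts, chrom, prefix)


def simulate_unlinked_admixed(freqs: tuple[np.ndarray, np.ndarray], alpha: float,
                              n_animals: int, seed: int) -> GenotypeMatrix:
    """Haploid animals whose per-marker ancestry is iid Bernoulli(alpha) —
    unlinked draws for calibrating the global-ancestry estimator."""
    p_t, p_i = freqs
    rng = np.random.default_rng(seed)
    anc = rng.random((n_animals, len(p_t))) < alpha
    probs = np.where(anc, p_t, p_i)
    return _make_matrix((rng.random(anc.shape) < probs).astype(np.int8), "X", "U")


def simulate_phenotypes(gm: GenotypeMatrix, kinship: KinshipMatrix | np.ndarray,
                        config: SimConfig, truth: SimTruth,
                        seed: int | None = None) -> tuple[PhenotypeTable, SimTruth]:
    """Traits y = group effects + s * snp_effect + u + e.

    The polygenic value u is drawn through a matrix square root of the
    kinship, scaled so Var(u) / (Var(u) + Var(e)) targets h2 (total baseline
    variance 1.0); each trait gets its own polygenic and residual draw.
    """
    K = kinship.K if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
    n = gm.n_animals
    if K.shape != (n, n):
        raise ValueError("kinship dimension mismatch")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma_g2 = config.h2 * PHENOTYPIC_VARIANCE
    sigma_e2 = (1 - config.h2) * PHENOTYPIC_VARIANCE

    groups = rng.integers(0, config.n_groups, n)
    year_month = rng.integers(0, N_YEAR_MONTH_LEVELS, n)
    group_eff = rng.normal(0.0, GROUP_EFFECT_SD, config.n_groups)
    ym_eff = rng.normal(0.0, YEAR_MONTH_EFFECT_SD, N_YEAR_MONTH_LEVELS)

    if config.candidate_snp_index is not None:
        s = gm.counts[:, config.candidate_snp_index].astype(float)
    else:
        s = np.zeros(n)

    if sigma_g2 > 0:
        d, U = np.linalg.eigh((K + K.T) / 2)
        root = U * np.sqrt(np.clip(d, 0.0, None))
    data = {"contemporary_group": [f"cg{g}" for g in groups],
            "year_month": [f"ym{m}" for m in year_month]}
    for t, trait in enumerate(config.trait_names):
        trng = np.random.default_rng([config.seed if seed is None else seed, t])
        u = root @ trng.normal(size=n) * np.sqrt(sigma_g2) if sigma_g2 > 0 else np.zeros(n)
        e = trng.normal(0.0, np.sqrt(sigma_e2), n)
        data[trait] = (group_eff[groups] + ym_eff[year_month]
                       + s * config.snp_effect + u + e)
    df = pd.DataFrame(data, index=pd.Index(gm.animal_ids, name="animal_id"))
    pheno = PhenotypeTable(df, list(config.trait_names))
    truth = replace(truth, true_variance_components=(sigma_g2, sigma_e2),
                    true_snp_effect=config.snp_effect, true_group_effects=group_eff)
    return pheno, truth


@dataclass
class SimDataset:
    """Everything one simulated study produces."""

    config: SimConfig
    freqs: tuple[np.ndarray, np.ndarray]          # X-chromosome markers
    panel_taurus: GenotypeMatrix
    panel_indicus: GenotypeMatrix
    targets: GenotypeMatrix
    freqs_bg: tuple[np.ndarray, np.ndarray] | None
    panel_taurus_bg: GenotypeMatrix | None
    panel_indicus_bg: GenotypeMatrix | None
    targets_bg: GenotypeMatrix | None
    kinship: KinshipMatrix
    phenotypes: PhenotypeTable
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the whole generator: frequencies, panels, animals, GRM, phenotypes.

    A second, tract-free "background" marker set (``n_background_snps``)
    stands in for the genome-wide chip SNPs used for global-ancestry
    estimation; the same animals receive an independent baseline mosaic there.
    """
    freqs = simulate_ancestral_frequencies(config.n_snps, config.fst,
                                           stage_seed(config.seed, "freqs"))
    if config.candidate_snp_index is not None:
        p_t, p_i = freqs[0].copy(), freqs[1].copy()
        if config.tag_candidate:
            # tag SNP: near-fixed between ancestries, tracking the tract
            p_t[config.candidate_snp_index] = TAG_SNP_FREQS[0]
            p_i[config.candidate_snp_index] = TAG_SNP_FREQS[1]
        else:
            # null grouping marker: carries no ancestry information
            p_t[config.candidate_snp_index] = 0.5
            p_i[config.candidate_snp_index] = 0.5
        freqs = (p_t, p_i)
    if config.n_founder_haplotypes is not None:
        pools = simulate_founder_pools(freqs, config,
                                       stage_seed(config.seed, "pools"))
        panel_t = sample_pool_panel(pools, "taurus", config.n_ref_taurus, freqs,
                                    stage_seed(config.seed, "panel_t"),
                                    chrom=config.chrom, prefix="T")
        panel_i = sample_pool_panel(pools, "indicus", config.n_ref_indicus, freqs,
                                    stage_seed(config.seed, "panel_i"),
                                    chrom=config.chrom, prefix="I")
    else:
        pools = None
        panel_t, panel_i = simulate_reference_panels(
            freqs, config.n_ref_taurus, config.n_ref_indicus,
            stage_seed(config.seed, "panels"), chrom=config.chrom)
    targets, truth = simulate_admixed_animals(freqs, config,
                                              stage_seed(config.seed, "targets"),
                                              pools=pools)

    freqs_bg = panel_t_bg = panel_i_bg = targets_bg = None
    combined_counts = targets.counts
    if config.n_background_snps > 0:
        bg_config = replace(config, n_snps=config.n_background_snps,
                            tract_interval=None, candidate_snp_index=None,
                            chrom="1")
        freqs_bg = simulate_ancestral_frequencies(
            config.n_background_snps, config.fst, stage_seed(config.seed, "bg_freqs"))
        panel_t_bg, panel_i_bg = simulate_reference_panels(
            freqs_bg, config.n_ref_taurus, config.n_ref_indicus,
            stage_seed(config.seed, "bg_panels"), chrom="1")
        targets_bg, truth_bg = simulate_admixed_animals(
            freqs_bg, bg_config, stage_seed(config.seed, "bg_targets"))
        truth = replace(truth, background_mask=truth_bg.ancestry_mask)
        combined_counts = np.hstack([targets.counts, targets_bg.counts])

    kin = compute_grm(_make_matrix(combined_counts, "NA", "A"))
    kin = KinshipMatrix(list(targets.animal_ids), kin.K)
    pheno, truth = simulate_phenotypes(targets, kin, config, truth,
                                       stage_seed(config.seed, "phenotypes"))
    return SimDataset(config, freqs, panel_t, panel_i, targets,
                      freqs_bg, panel_t_bg, panel_i_bg, targets_bg,
                      kin, pheno, truth)


def write_simulation(ds: SimDataset, outdir: str | Path) -> None:
    """Write the dataset: VCFs, phenotype TSV, truth sidecars, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(ds.targets, outdir / "targets.vcf")
    write_vcf(ds.panel_taurus, outdir / "panel_taurus.vcf")
    write_vcf(ds.panel_indicus, outdir / "panel_indicus.vcf")
    if ds.targets_bg is not None:
        write_vcf(ds.targets_bg, outdir / "background_targets.vcf")
        write_vcf(ds.panel_taurus_bg, outdir / "background_panel_taurus.vcf")
        write_vcf(ds.panel_indicus_bg, outdir / "background_panel_indicus.vcf")
    write_phenotypes(ds.phenotypes, outdir / "phenotypes.tsv")
    mask = pd.DataFrame(ds.truth.ancestry_mask, index=ds.targets.animal_ids,
                        columns=ds.targets.marker_ids)
    mask.to_csv(outdir / "truth_ancestry_mask.tsv", sep="\t")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(ds.config).items()}
    truth_scalars = {
        "sigma_g2": float(ds.truth.true_variance_components[0]),
        "sigma_e2": float(ds.truth.true_variance_components[1]),
        "snp_effect": float(ds.truth.true_snp_effect),
        "candidate_snp_index": ds.truth.candidate_snp_index,
        "favourable_allele": ds.truth.favourable_allele,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({"sim_config": cfg, "truth": truth_scalars}, fh,
                       sort_keys=True)
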