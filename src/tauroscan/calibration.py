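"""Calibration and recovery studies run on synthetic data.

These are the package's statistical self-checks: consistency of the %Va
arithmetic against published single-SNP association results for scrotal
circumference in Brahman bulls, REML variance-component recovery, Wald-test
type-I error, SNP-effect unbiasedness, supervised-admixture calibration, and
the end-to-end local/global ancestry dissociation of the default scenario.
Each function simulates from scratch, runs the corresponding estimator, and
returns summary numbers.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import admixture, ancestry, mixed_model
from .simulate import (
    SimConfig,
    simulate_admixed_animals,
    simulate_ancestral_frequencies,
    simulate_dataset,
    simulate_phenotypes,
    simulate_unlinked_admixed,
    stage_seed,
)

# Published Brahman association rows for scrotal circumference at 12 months:
# SNP id -> (alt-allele frequency, additive effect per allele copy, %Va).
# Used to check the internal consistency of %Va = 100 * 2pq a^2 / sigma_g2:
# back-solving sigma_g2 from each row must give near-identical values, since
# all four share one trait (one REML genetic variance).
BRAHMAN_SC12_ROWS = {
    "AR_In4": (0.52, -0.5531, 3.249),
    "Tex11_r38k": (0.17, 1.038, 6.579),
    "Tex11_g297d": (0.27, -0.119, 0.120),
    "Tex11_r696h": (0.17, 1.012, 6.037),
}


def sc12_variance_arithmetic() -> dict:
    """Back-solve the genetic variance from each published SC12 row.

    Returns the four sigma_g2 values, their max/min ratio, and the %Va for
    the largest-effect SNP cross-predicted from the first row's sigma_g2.
    """
    sigma = {snp: mixed_model.backsolve_sigma_g2(p, a, pct)
             for snp, (p, a, pct) in BRAHMAN_SC12_ROWS.items()}
    vals = np.array(list(sigma.values()))
    p, a, _ = BRAHMAN_SC12_ROWS["Tex11_r38k"]
    cross = mixed_model.variance_explained(p, a, sigma["AR_In4"])
    return {"sigma_g2": sigma,
            "max_min_ratio": float(vals.max() / vals.min()),
            "cross_predicted_pct_va": float(cross),
            "published_pct_va": BRAHMAN_SC12_ROWS["Tex11_r38k"][2]}


def _assoc_config(seed: int, n_animals: int, n_markers: int, h2: float,
                  snp_effect: float) -> SimConfig:
    tract = (n_markers // 2 - 20, n_markers // 2 + 20)
    return SimConfig(seed=seed, n_snps=n_markers, n_animals=n_animals, h2=h2,
                     snp_effect=snp_effect, tract_interval=tract,
                     candidate_snp_index=n_markers // 2, n_background_snps=0,
                     n_founder_haplotypes=None)


def _simulate_assoc_rep(cfg: SimConfig, seed: int):
    freqs = simulate_ancestral_frequencies(cfg.n_snps, cfg.fst,
                                           stage_seed(seed, "freqs"))
    # the tested SNP is a common variant in both ancestries (never monomorphic,
    # not confounded with ancestry)
    for p in freqs:
        p[cfg.candidate_snp_index] = 0.5
    gm, truth = simulate_admixed_animals(freqs, cfg, stage_seed(seed, "animals"))
    kin = mixed_model.compute_grm(gm)
    pheno, truth = simulate_phenotypes(gm, kin, cfg, truth,
                                       stage_seed(seed, "pheno"))
    X, names = mixed_model.fixed_effect_design(pheno)
    y = pheno.data[cfg.trait_names[0]].to_numpy(float)
    s = gm.counts[:, cfg.candidate_snp_index].astype(float)
    return y, X, kin, s


def reml_h2_recovery(n_reps: int = 200, n_animals: int = 500,
                     n_markers: int = 400, h2: float = 0.4,
                     seed: int = 0) -> dict:
    """Mean REML heritability over replicates simulated at true h2."""
    cfg = _assoc_config(seed, n_animals, n_markers, h2, snp_effect=0.0)
    h2_hats = []
    for r in range(n_reps):
        y, X, kin, _ = _simulate_assoc_rep(cfg, stage_seed(seed, f"h2rep{r}"))
        fit = mixed_model.reml_fit(y, X, kin)
        h2_hats.append(fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2))
    return {"mean_h2": float(np.mean(h2_hats)), "true_h2": h2,
            "n_reps": n_reps, "h2_hats": h2_hats}


def wald_type1_error(n_reps: int = 1000, n_genotype_draws: int = 10,
                     n_animals: int = 500, n_markers: int = 400,
                     h2: float = 0.4, alpha_level: float = 0.05,
                     seed: int = 0) -> dict:
    """Rejection rate of the Wald test for a SNP with no simulated effect.

    Genotypes (and the kinship eigendecomposition) are redrawn every
    ``n_reps / n_genotype_draws`` replicates; phenotypes are fresh each
    replicate.
    """
    cfg = _assoc_config(seed, n_animals, n_markers, h2, snp_effect=0.0)
    per_draw = n_reps // n_genotype_draws
    pvals = []
    for g in range(n_genotype_draws):
        gseed = stage_seed(seed, f"null_geno{g}")
        freqs = simulate_ancestral_frequencies(cfg.n_snps, cfg.fst,
                                               stage_seed(gseed, "freqs"))
        gm, truth = simulate_admixed_animals(freqs, cfg, stage_seed(gseed, "animals"))
        kin = mixed_model.compute_grm(gm)
        eigen = mixed_model.eigendecompose(kin)
        s = gm.counts[:, cfg.candidate_snp_index].astype(float)
        for r in range(per_draw):
            pheno, _ = simulate_phenotypes(gm, kin, cfg, truth,
                                           stage_seed(gseed, f"ph{r}"))
            X, _ = mixed_model.fixed_effect_design(pheno)
            y = pheno.data[cfg.trait_names[0]].to_numpy(float)
            fit = mixed_model.reml_fit(y, X, kin, eigen=eigen)
            res = mixed_model.snp_wald_test(y, X, kin, s, fit)
            pvals.append(res.p)
    pvals = np.asarray(pvals)
    return {"rejection_rate": float(np.mean(pvals < alpha_level)),
            "alpha_level": alpha_level, "n_reps": int(len(pvals))}


def snp_effect_recovery(n_reps: int = 200, effect: float = 1.0,
                        n_animals: int = 500, n_markers: int = 400,
                        h2: float = 0.4, seed: int = 0) -> dict:
    """Mean estimated additive effect for a SNP simulated at ``effect``."""
    cfg = _assoc_config(seed, n_animals, n_markers, h2, snp_effect=effect)
    effects = []
    for r in range(n_reps):
        y, X, kin, s = _simulate_assoc_rep(cfg, stage_seed(seed, f"eff{r}"))
        fit = mixed_model.reml_fit(y, X, kin)
        res = mixed_model.snp_wald_test(y, X, kin, s, fit)
        effects.append(res.effect)
    return {"mean_effect": float(np.mean(effects)), "true_effect": effect,
            "n_reps": n_reps}


def admixture_recovery(n_markers: int = 5000, n_animals: int = 20,
                       alpha: float = 0.2, fst: float = 0.3,
                       n_grid_animals: int = 5, seed: int = 0) -> dict:
    """Supervised-EM calibration on unlinked markers at a known mixture.

    Ancestry is iid per marker, so the realized taurine fraction concentrates
    tightly at ``alpha``; the EM estimate is compared per animal against it
    and, for the first few animals, against an exhaustive 1e-4 grid search.
    """
    freqs = simulate_ancestral_frequencies(n_markers, fst,
                                           stage_seed(seed, "adm_freqs"))
    gm = simulate_unlinked_admixed(freqs, alpha, n_animals,
                                   stage_seed(seed, "adm_targets"))
    ests = admixture.estimate_alpha_all(gm, freqs[0], freqs[1])
    alphas = np.array([e.alpha for e in ests])
    grid_diffs = [
        abs(ests[i].alpha - admixture.grid_search_alpha(
            gm.counts[i], 1, freqs[0], freqs[1]))
        for i in range(min(n_grid_animals, n_animals))
    ]
    return {"true_alpha": alpha,
            "alphas": alphas.tolist(),
            "max_abs_error": float(np.max(np.abs(alphas - alpha))),
            "mean_abs_error": float(np.mean(np.abs(alphas - alpha))),
            "group_mean": float(alphas.mean()),
            "group_mean_error": float(abs(alphas.mean() - alpha)),
            "em_vs_grid_max": float(np.max(grid_diffs)),
            "all_converged": bool(all(e.converged for e in ests))}


def dissociation_study(seed: int = 0, config: SimConfig | None = None) -> dict:
    """End-to-end run of the default scenario.

    Measures the key contrast: carriers of the favourable candidate allele
    show a high taurine fraction over tract windows while non-carriers stay
    near the baseline, yet genome-wide taurine proportion barely differs
    between the groups.  Also returns the candidate SNP's mixed-model p.
    """
    cfg = replace(config or SimConfig(), seed=seed)
    ds = simulate_dataset(cfg)
    paintings = ancestry.paint_all(ds.targets, ds.panel_taurus, ds.panel_indicus,
                                   window_size=cfg.window_size)
    cand = dict(zip(ds.targets.animal_ids,
                    ds.targets.counts[:, cfg.candidate_snp_index].astype(int)))
    lo, hi = cfg.tract_interval
    wrange = (lo // cfg.window_size, -(-hi // cfg.window_size))
    _, summary = ancestry.allele_group_profile(paintings, cand, wrange)

    freqs_t = admixture.panel_frequencies(ds.panel_taurus_bg)
    freqs_i = admixture.panel_frequencies(ds.panel_indicus_bg)
    ests = admixture.estimate_alpha_all(ds.targets_bg, freqs_t, freqs_i)
    gsum = admixture.group_alpha_summary(ests, cand)

    X, _ = mixed_model.fixed_effect_design(ds.phenotypes)
    y = ds.phenotypes.data[cfg.trait_names[0]].to_numpy(float)
    fit = mixed_model.reml_fit(y, X, ds.kinship)
    s = ds.targets.counts[:, cfg.candidate_snp_index].astype(float)
    res = mixed_model.snp_wald_test(y, X, ds.kinship, s, fit)

    return {
        "carrier_tract_taurine": float(summary.loc[1, "window_mean"]),
        "noncarrier_tract_taurine": float(summary.loc[0, "window_mean"]),
        "genomewide_alpha_by_group": {int(a): float(gsum.loc[a, "mean"])
                                      for a in gsum.index},
        "genomewide_alpha_diff": float(abs(gsum.loc[1, "mean"] - gsum.loc[0, "mean"])),
        "candidate_p": float(res.p),
        "candidate_effect": float(res.effect),
        "n_animals": cfg.n_animals,
    }
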