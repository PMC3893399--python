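"""Supervised two-population admixture estimation.

Each animal's taurine proportion ``alpha`` is the single free parameter of a
binomial mixture: at marker m the alt-allele probability is
``q_m = alpha * p_t,m + (1 - alpha) * p_i,m`` with the taurine/indicine
reference frequencies held fixed.  ``alpha`` is fitted per animal by EM over
allele draws (one draw per marker for hemizygous X, two for diploids), which
is guaranteed not to decrease the log-likelihood and converges to the global
optimum of this unimodal 1-D problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix

FREQ_CLIP = (0.001, 0.999)  # keeps the log-likelihood finite


@dataclass(frozen=True)
class AdmixtureEstimate:
    animal_id: str
    alpha: float
    loglik: float
    n_used: int
    converged: bool


def panel_frequencies(panel: GenotypeMatrix) -> np.ndarray:
    """Per-marker alt-allele frequency of a reference panel (missing excluded)."""
    counts = panel.counts.astype(float)
    counts[panel.counts == MISSING] = np.nan
    denom = np.nansum(np.where(np.isnan(counts), np.nan, panel.ploidy[:, None]), axis=0)
    return np.nansum(counts, axis=0) / denom


def _prepare(counts_row: np.ndarray, ploidy: int,
             freqs_t: np.ndarray, freqs_i: np.ndarray):
    """Clip frequencies, drop missing and uninformative markers."""
    p_t = np.clip(np.asarray(freqs_t, dtype=float), *FREQ_CLIP)
    p_i = np.clip(np.asarray(freqs_i, dtype=float), *FREQ_CLIP)
    keep = (counts_row != MISSING) & (p_t != p_i)
    return counts_row[keep].astype(float), p_t[keep], p_i[keep], int(keep.sum())


def admixture_loglik(alpha: float, counts_row: np.ndarray, ploidy: int,
                     freqs_t: np.ndarray, freqs_i: np.ndarray) -> float:
    """Binomial log-likelihood of one animal's genotypes at mixture weight alpha.

    Markers monomorphic in both panels (equal clipped frequencies) and missing
    genotypes are skipped.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    c, p_t, p_i, _ = _prepare(counts_row, ploidy, freqs_t, freqs_i)
    q = alpha * p_t + (1 - alpha) * p_i
    coef = gammaln(ploidy + 1) - gammaln(c + 1) - gammaln(ploidy - c + 1)
    return float(np.sum(coef + c * np.log(q) + (ploidy - c) * np.log1p(-q)))


def estimate_alpha(counts_row: np.ndarray, ploidy: int,
                   freqs_t: np.ndarray, freqs_i: np.ndarray,
                   animal_id: str = "", tol: float = 1e-6,
                   max_iter: int = 500, alpha0: float = 0.5) -> AdmixtureEstimate:
    """Fit alpha by EM.

    Per allele draw the taurine responsibility is
    ``r = alpha p_t / (alpha p_t + (1-alpha) p_i)`` for alt copies (and the
    1-frequency analogue for ref copies); the update sets alpha to the mean
    responsibility.  With no informative markers the problem is
    unidentifiable: alpha is reported as 0.5 with ``converged=False``.
    """
    c, p_t, p_i, n_used = _prepare(counts_row, ploidy, freqs_t, freqs_i)
    if n_used == 0:
        return AdmixtureEstimate(animal_id, 0.5, 0.0, 0, False)
    alpha = float(alpha0)
    converged = False
    for _ in range(max_iter):
        r_alt = alpha * p_t / (alpha * p_t + (1 - alpha) * p_i)
        r_ref = alpha * (1 - p_t) / (alpha * (1 - p_t) + (1 - alpha) * (1 - p_i))
        new = float(np.sum(c * r_alt + (ploidy - c) * r_ref) / (ploidy * n_used))
        if abs(new - alpha) < tol:
            alpha = new
            converged = True
            break
        alpha = new
    ll = admixture_loglik(alpha, counts_row, ploidy, freqs_t, freqs_i)
    return AdmixtureEstimate(animal_id, alpha, ll, n_used, converged)


def estimate_alpha_all(targets: GenotypeMatrix, freqs_t: np.ndarray,
                       freqs_i: np.ndarray, **kwargs) -> list[AdmixtureEstimate]:
    return [
        estimate_alpha(targets.counts[i], int(targets.ploidy[i]), freqs_t,
                       freqs_i, animal_id=aid, **kwargs)
        for i, aid in enumerate(targets.animal_ids)
    ]


def grid_search_alpha(counts_row: np.ndarray, ploidy: int,
                      freqs_t: np.ndarray, freqs_i: np.ndarray,
                      step: float = 1e-4) -> float:
    """Exhaustive likelihood search over an alpha grid (oracle for the EM fit)."""
    c, p_t, p_i, n_used = _prepare(counts_row, ploidy, freqs_t, freqs_i)
    if n_used == 0:
        return 0.5
    grid = np.arange(0.0, 1.0 + step / 2, step)
    best_alpha, best_ll = 0.5, -np.inf
    for block in np.array_split(grid, max(1, len(grid) * len(c) // 2_000_000)):
        q = block[:, None] * p_t + (1 - block[:, None]) * p_i
        ll = np.log(q) @ c + np.log1p(-q) @ (ploidy - c)
        j = int(np.argmax(ll))
        if ll[j] > best_ll:
            best_ll, best_alpha = float(ll[j]), float(block[j])
    return best_alpha


def group_alpha_summary(estimates: list[AdmixtureEstimate],
                        candidate_genotypes: dict[str, int]) -> pd.DataFrame:
    """Mean/SD/n of alpha per candidate-SNP allele group."""
    rows: dict[int, list[float]] = {}
    for est in estimates:
        if est.animal_id not in candidate_genotypes:
            raise ValueError(f"no candidate-SNP call for animal {est.animal_id}")
        rows.setdefault(int(candidate_genotypes[est.animal_id]), []).append(est.alpha)
    out = []
    for allele, alphas in sorted(rows.items()):
        if not alphas:
            raise ValueError(f"allele group {allele} is empty")
        out.append({"allele": allele, "n": len(alphas),
                    "mean": float(np.mean(alphas)),
                    "sd": float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0})
    return pd.DataFrame(out).set_index("allele")
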