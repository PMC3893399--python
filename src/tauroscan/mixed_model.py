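"""Single-SNP linear mixed-model association.

Model per trait:  y = X beta + s a_j + u + e,  u ~ N(0, sigma_g2 K),
e ~ N(0, sigma_e2 I), with K a genomic relationship matrix and X the
fixed-effect design (intercept + contemporary-group + year-month dummies).

Variance components are estimated by REML through a single spectral
decomposition of K: rotating into K's eigenbasis makes the covariance
diagonal, so the restricted likelihood is a 1-D function of the variance
ratio lambda = sigma_g2 / sigma_e2, maximized by a log-scale grid scan plus
bounded refinement.  By default the components are estimated once under the
null model (no SNP term) and reused for every SNP (the EMMAX approximation);
``exact=True`` re-maximizes REML with the SNP in the design.

Hemizygous male-X genotypes are coded 0/1 copies; effect sizes are therefore
per single allele copy (half the scale of a 0/2 coding).  The per-SNP share
of genetic variance is reported with the diploid form
``%Va = 100 * 2 p q a^2 / sigma_g2`` regardless of ploidy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING, GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)

LOG10_LAMBDA_BOUNDS = (-6.0, 6.0)
GRID_POINTS = 121


@dataclass
class KinshipMatrix:
    animal_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.animal_ids),) * 2:
            raise ValueError("kinship dimension mismatch")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")


@dataclass
class RemlFit:
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    loglik_reml: float
    converged: bool
    lam: float                     # sigma_g2 / sigma_e2
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class AssocResult:
    snp_id: str
    allele: str
    effect: float
    se: float
    p: float
    pct_va: float


def compute_grm(gm: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden-style genomic relationship matrix.

    Counts are centered by the per-marker mean and the cross-product scaled by
    the summed ploidy-appropriate binomial variance, sum_m k p_m (1 - p_m)
    (k = ploidy), so the mean diagonal is about 1 for a homogeneous
    population.  Monomorphic markers are excluded; missing genotypes are
    mean-imputed (centered contribution zero).
    """
    if gm.n_animals < 2:
        raise ValueError("need at least 2 animals")
    ploidies = np.unique(gm.ploidy)
    if len(ploidies) != 1:
        raise ValueError("mixed-ploidy genotype matrices are not supported for GRM")
    k = int(ploidies[0])
    counts = gm.counts.astype(float)
    counts[gm.counts == MISSING] = np.nan
    p = np.nanmean(counts, axis=0) / k
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    Z = counts[:, poly] - k * p[poly]
    Z = np.nan_to_num(Z, nan=0.0)
    denom = float(np.sum(k * p[poly] * (1 - p[poly])))
    K = Z @ Z.T / denom
    return KinshipMatrix(list(gm.animal_ids), (K + K.T) / 2)


def _check_full_rank(X: np.ndarray, names: list[str] | None) -> None:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # columns with a vanishing QR diagonal are (part of) the collinear set
        q, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.nonzero(diag < 1e-8 * diag.max())[0]
        labels = [names[i] if names else f"column {i}" for i in bad] or ["(unresolved)"]
        raise ValueError(f"design matrix is rank deficient; collinear: {labels}")


def _reml_neg_loglik(log10_lam: float, d: np.ndarray, yr: np.ndarray,
                     Xr: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Negative restricted log-likelihood at variance ratio 10**log10_lam.

    Returns (-llR, beta, sigma_e2); all quantities in K's eigenbasis where
    V = sigma_e2 (lam D + I) is diagonal.
    """
    lam = 10.0 ** log10_lam
    n, p = Xr.shape
    w = 1.0 / (lam * d + 1.0)
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWy = Xr.T @ (w * yr)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(np.sum(w * resid ** 2))
    sigma_e2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    sign0, logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)
    llr = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma_e2) + 1)
                  - np.sum(np.log(w)) + logdet_XtWX - logdet_XtX)
    return -llr, beta, sigma_e2


def eigendecompose(kin: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh(kin.K)
    return np.clip(d, 0.0, None), U


def reml_fit(y: np.ndarray, X: np.ndarray, kin: KinshipMatrix,
             eigen: tuple[np.ndarray, np.ndarray] | None = None,
             design_names: list[str] | None = None) -> RemlFit:
    """REML variance components via spectral decomposition of K.

    ``eigen`` may carry a precomputed ``(eigenvalues, eigenvectors)`` pair so
    many traits/replicates can share one decomposition.  When the restricted
    likelihood is flat in the variance ratio (e.g. K = identity: only
    sigma_g2 + sigma_e2 is identifiable) the boundary solution sigma_g2 = 0
    is returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values; drop missing rows first")
    _check_full_rank(X, design_names)
    d, U = eigen if eigen is not None else eigendecompose(kin)
    yr = U.T @ y
    Xr = U.T @ X

    grid = np.linspace(*LOG10_LAMBDA_BOUNDS, GRID_POINTS)
    nll = np.array([_reml_neg_loglik(g, d, yr, Xr)[0] for g in grid])
    j = int(np.argmin(nll))
    flat = (nll.max() - nll.min()) < 1e-6 * (1.0 + abs(float(nll.min())))
    if flat or j == 0:
        # unidentifiable ratio or optimum at sigma_g2 -> 0: boundary solution
        neg, beta, sigma_e2 = _reml_neg_loglik(LOG10_LAMBDA_BOUNDS[0], d, yr, Xr)
        lam = 0.0
        converged = not flat and j == 0
        return RemlFit(0.0, sigma_e2, beta, -neg, converged, lam, d, U)
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda g: _reml_neg_loglik(g, d, yr, Xr)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    neg, beta, sigma_e2 = _reml_neg_loglik(float(res.x), d, yr, Xr)
    lam = 10.0 ** float(res.x)
    return RemlFit(lam * sigma_e2, sigma_e2, beta, -neg, bool(res.success), lam, d, U)


def gls_effect(yr: np.ndarray, Ar: np.ndarray, w: np.ndarray,
               sigma_e2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimates and covariance for a rotated design with diagonal weights."""
    AtWA = Ar.T @ (w[:, None] * Ar)
    coef = np.linalg.solve(AtWA, Ar.T @ (w * yr))
    cov = sigma_e2 * np.linalg.inv(AtWA)
    return coef, cov


def snp_wald_test(y: np.ndarray, X: np.ndarray, kin: KinshipMatrix,
                  snp: np.ndarray, fit: RemlFit, snp_id: str = "",
                  allele: str = "", exact: bool = False) -> AssocResult:
    """Wald test of one SNP with variance components held at ``fit``.

    With ``exact=True`` REML is re-maximized with the SNP in the design before
    the Wald test (per-SNP REML instead of the EMMAX approximation).
    """
    y = np.asarray(y, dtype=float)
    snp = np.asarray(snp, dtype=float)
    if np.nanvar(snp) == 0:
        raise ValueError(f"monomorphic SNP {snp_id or '(unnamed)'}")
    A = np.column_stack([X, snp])
    if np.linalg.matrix_rank(A) <= np.linalg.matrix_rank(X):
        raise ValueError(f"SNP {snp_id or '(unnamed)'} is collinear with the design")
    if exact:
        fit = reml_fit(y, A, kin, eigen=(fit.eigenvalues, fit.eigenvectors))
    d, U = fit.eigenvalues, fit.eigenvectors
    w = 1.0 / (fit.lam * d + 1.0)
    coef, cov = gls_effect(U.T @ y, U.T @ A, w, fit.sigma_e2)
    effect = float(coef[-1])
    se = float(np.sqrt(cov[-1, -1]))
    chi2 = (effect / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return AssocResult(snp_id, allele, effect, se, max(p, np.nextafter(0, 1)),
                       np.nan)


def variance_explained(p: float, a: float, sigma_g2: float) -> float:
    """%Va = 100 * 2 p (1-p) a^2 / sigma_g2 (may exceed 100, reported as-is)."""
    if not 0 < p < 1:
        raise ValueError("allele frequency must be strictly inside (0, 1)")
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    pct = 100.0 * 2.0 * p * (1 - p) * a ** 2 / sigma_g2
    if pct > 100:
        log.warning("%%Va = %.1f exceeds 100; reported as-is", pct)
    return pct


def backsolve_sigma_g2(p: float, a: float, pct_va: float) -> float:
    """Invert the %Va formula: sigma_g2 = 100 * 2 p (1-p) a^2 / %Va."""
    if pct_va <= 0:
        raise ValueError("pct_va must be positive")
    return 100.0 * 2.0 * p * (1 - p) * a ** 2 / pct_va


def fixed_effect_design(pheno: PhenotypeTable,
                        factors=("contemporary_group", "year_month")):
    """Full-rank design: intercept + dummy columns (first level dropped)."""
    cols = [np.ones(len(pheno.data))]
    names = ["intercept"]
    for f in factors:
        dummies = pd.get_dummies(pheno.data[f], prefix=f, drop_first=True)
        cols.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    return np.column_stack(cols), names


def association_table(gm: GenotypeMatrix, pheno: PhenotypeTable,
                      kin: KinshipMatrix, snp_ids: list[str],
                      traits: list[str] | None = None,
                      factors=("contemporary_group", "year_month"),
                      exact: bool = False) -> pd.DataFrame:
    """Per trait x SNP association results, Tables-3/4 layout.

    Columns: Trait, SNP, P, Allele, Effect, SE, PctVa.  Animals are matched
    between genotypes and phenotypes by id; rows with a missing trait value
    are dropped per trait.
    """
    traits = list(traits) if traits is not None else list(pheno.trait_names)
    common = [a for a in gm.animal_ids if a in set(pheno.animal_ids)]
    if not common:
        raise ValueError("no animals shared between genotypes and phenotypes")
    g_idx = [gm.animal_ids.index(a) for a in common]
    sub = gm.subset_animals(np.array(g_idx))
    ptab = PhenotypeTable(pheno.data.loc[common].copy(), pheno.trait_names)
    k_idx = [kin.animal_ids.index(a) for a in common]
    K = KinshipMatrix(common, kin.K[np.ix_(k_idx, k_idx)])

    rows = []
    for trait in traits:
        yfull = ptab.data[trait].to_numpy(dtype=float)
        keep = np.isfinite(yfull)
        ksub = KinshipMatrix([common[i] for i in np.nonzero(keep)[0]],
                             K.K[np.ix_(keep.nonzero()[0], keep.nonzero()[0])])
        sub_t = sub.subset_animals(np.nonzero(keep)[0])
        ptab_t = PhenotypeTable(ptab.data.loc[keep].copy(), ptab.trait_names)
        X, names = fixed_effect_design(ptab_t, factors)
        y = yfull[keep]
        fit = reml_fit(y, X, ksub, design_names=names)
        for snp_id in snp_ids:
            m = sub_t.marker_index(snp_id)
            s = sub_t.counts[:, m].astype(float)
            s[sub_t.counts[:, m] == MISSING] = np.nan
            ok = np.isfinite(s)
            if not ok.all():
                # drop animals missing this SNP for this test
                kk = KinshipMatrix([ksub.animal_ids[i] for i in np.nonzero(ok)[0]],
                                   ksub.K[np.ix_(ok.nonzero()[0], ok.nonzero()[0])])
                fit_s = reml_fit(y[ok], X[ok], kk, design_names=names)
                res = snp_wald_test(y[ok], X[ok], kk, s[ok], fit_s,
                                    snp_id=snp_id, exact=exact)
                freq = float(np.mean(s[ok])) / int(sub_t.ploidy[0])
            else:
                res = snp_wald_test(y, X, ksub, s, fit, snp_id=snp_id, exact=exact)
                freq = float(np.mean(s)) / int(sub_t.ploidy[0])
            pct = variance_explained(freq, res.effect,
                                     fit.sigma_g2 if fit.sigma_g2 > 0 else np.nan) \
                if 0 < freq < 1 and fit.sigma_g2 > 0 else np.nan
            rows.append({"Trait": trait, "SNP": snp_id, "P": res.p,
                         "Allele": sub_t.alleles[m][1], "Effect": res.effect,
                         "SE": res.se, "PctVa": pct})
    return pd.DataFrame(rows)
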