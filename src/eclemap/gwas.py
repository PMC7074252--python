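"""Array QC, kinship estimation, mixed-model association and inflation
diagnostics.

The association scan follows the EMMA/GEMMA construction: a linear mixed
model

    y = W a + x b + u + e,   cov(u) = sg^2 K,  cov(e) = se^2 I

fitted by REML through a single eigendecomposition of the kinship matrix K
(the rotation trick).  The variance ratio delta = se^2 / sg^2 is
re-optimized per marker by a vectorized grid search with two local
refinement passes, and each marker gets a Wald test on b whose p-value uses
the F(1, n-p) reference distribution, so that with K = I the scan reduces
exactly to ordinary least squares.

QC applies, in one fixed pass, sample call-rate, marker call-rate, minor
allele frequency, and an exact Hardy-Weinberg test in controls; every
removal is logged with the rule that triggered it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genio import GenotypeMatrix, MISSING, ValidationError

CHI2_MEDIAN_1DF = 0.4549364231195724  # chi2.ppf(0.5, 1)


@dataclass
class QcConfig:
    """Marker/sample quality-control thresholds.

    Defaults: callrate >= 90% for both samples and markers, minor allele
    frequency >= 10%, and exclusion of markers whose exact Hardy-Weinberg
    p-value in controls falls below 1e-5.
    """

    min_call_rate_sample: float = 0.90
    min_call_rate_marker: float = 0.90
    min_maf: float = 0.10
    hwe_p_floor_controls: float = 1e-5

    def __post_init__(self) -> None:
        for name in (
            "min_call_rate_sample",
            "min_call_rate_marker",
            "min_maf",
            "hwe_p_floor_controls",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name}={v} outside (0, 1]")


@dataclass
class KinshipMatrix:
    values: np.ndarray
    samples: list[str]
    estimator: str  # 'ibs' or 'centered-grm'

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("kinship matrix not square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("kinship matrix not symmetric")
        if not np.all(np.isfinite(v)):
            raise ValidationError("kinship matrix has non-finite entries")
        if np.any(np.diag(v) <= 0):
            raise ValidationError("kinship diagonal must be positive")
        self.values = v


@dataclass
class GwasDiagnostics:
    lambda_before: float
    lambda_after: float
    n_markers_after_qc: int
    n_samples_after_qc: int
    suggestive_threshold: float
    bonferroni_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote count whose conditional probability does not exceed that of
    the observed count.  Probabilities are accumulated in log space.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValidationError("all genotype counts are zero")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0

    # log P(het = h | n, rare) up to a shared constant:
    #   P(h) ∝ 2^h * n! / (h! * n_aa! * n_AA!)   with fixed allele counts
    hs = np.arange(rare % 2, rare + 1, 2)
    log_p = (
        hs * math.log(2)
        - gammaln(hs + 1)
        - gammaln((rare - hs) / 2 + 1)
        - gammaln((2 * n - rare - hs) / 2 + 1)
    )
    log_p -= log_p.max()
    p = np.exp(log_p)
    p /= p.sum()
    obs = p[np.where(hs == n_het)[0]]
    if obs.size == 0:
        raise ValidationError(
            f"heterozygote count {n_het} infeasible for allele counts"
        )
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QcRemoval:
    kind: str  # 'sample' or 'marker'
    identifier: str
    rule: str
    value: float


@dataclass
class QcResult:
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    removals: list[QcRemoval] = field(default_factory=list)

    def removed_ids(self, rule: str | None = None) -> set[str]:
        return {
            r.identifier
            for r in self.removals
            if rule is None or r.rule == rule
        }


def _marker_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hom_ref = (calls == 0).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    hom_alt = (calls == 2).sum(axis=0)
    return hom_ref, het, hom_alt


def qc_filter(
    g: GenotypeMatrix, samples: pd.DataFrame, cfg: QcConfig | None = None
) -> QcResult:
    """One fixed-order QC pass: sample call-rate, then marker call-rate,
    MAF (both phenotypes pooled, computed after sample removal) and exact
    Hardy-Weinberg in controls.

    Markers monomorphic in controls are exempt from Hardy-Weinberg removal.
    Idempotent: re-running on its own output removes nothing further.
    """
    cfg = cfg or QcConfig()
    removals: list[QcRemoval] = []
    pheno = samples.set_index("sample_id")["phenotype"]
    if not (pheno.loc[g.samples] == "control").any():
        raise ValidationError("QC requires at least one control sample")

    # 1. sample call rate
    rate = np.mean(g.calls != MISSING, axis=1) if g.n_markers else np.ones(g.n_samples)
    keep_samples = []
    for i, s in enumerate(g.samples):
        if rate[i] < cfg.min_call_rate_sample:
            removals.append(
                QcRemoval("sample", s, "sample-call-rate", float(rate[i]))
            )
        else:
            keep_samples.append(s)
    if not keep_samples:
        raise ValidationError("QC removed every sample")
    g = g.subset_samples(keep_samples)

    # 2-4. marker rules on the pruned sample set
    calls = g.calls
    n_s = g.n_samples
    nonmiss = (calls != MISSING).sum(axis=0)
    call_rate = nonmiss / n_s
    hom_ref, het, hom_alt = _marker_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (2 * hom_alt + het) / (2 * nonmiss)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    is_ctrl = np.array(
        [pheno.loc[s] == "control" for s in g.samples]
    )
    ctrl_calls = calls[is_ctrl, :]
    c_hr, c_het, c_ha = _marker_counts(ctrl_calls)

    keep_idx = []
    for j in range(g.n_markers):
        mid = g.markers.ids[j]
        if call_rate[j] < cfg.min_call_rate_marker:
            removals.append(
                QcRemoval("marker", mid, "marker-call-rate", float(call_rate[j]))
            )
            continue
        if nonmiss[j] == 0 or maf[j] < cfg.min_maf:
            removals.append(QcRemoval("marker", mid, "maf", float(maf[j])))
            continue
        n_ctrl_obs = c_hr[j] + c_het[j] + c_ha[j]
        ctrl_alt = 2 * c_ha[j] + c_het[j]
        monomorphic = ctrl_alt == 0 or ctrl_alt == 2 * n_ctrl_obs
        if n_ctrl_obs > 0 and not monomorphic:
            p = hwe_exact_test(int(c_hr[j]), int(c_het[j]), int(c_ha[j]))
            if p < cfg.hwe_p_floor_controls:
                removals.append(QcRemoval("marker", mid, "hwe-controls", p))
                continue
        keep_idx.append(j)

    g = g.subset_markers(np.array(keep_idx, dtype=int))
    samples = samples[samples["sample_id"].isin(g.samples)].reset_index(
        drop=True
    )
    return QcResult(g, samples, removals)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


def kinship(g: GenotypeMatrix, estimator: str = "centered-grm") -> KinshipMatrix:
    """Sample-by-sample relatedness.

    ``ibs``: proportion of shared alleles (1 - |d_i - d_j|/2) averaged over
    markers where both samples are called.  ``centered-grm``: cross-product
    of mean-centered dosages scaled by sum(2 p (1-p)), with missing dosages
    set to the marker mean (zero after centering).
    """
    calls = g.calls.astype(float)
    miss = calls < 0
    calls[miss] = np.nan
    if estimator == "ibs":
        n = g.n_samples
        vals = np.zeros((n, n))
        obs = ~np.isnan(calls)
        for i in range(n):
            for j in range(i, n):
                both = obs[i] & obs[j]
                if not both.any():
                    raise ValidationError(
                        f"samples {g.samples[i]} and {g.samples[j]} share no "
                        "called markers"
                    )
                sim = 1 - np.abs(calls[i, both] - calls[j, both]) / 2
                vals[i, j] = vals[j, i] = sim.mean()
        return KinshipMatrix(vals, list(g.samples), "ibs")
    if estimator == "centered-grm":
        p = np.nanmean(calls, axis=0) / 2
        centered = calls - 2 * p
        centered[np.isnan(centered)] = 0.0
        denom = float(np.sum(2 * p * (1 - p)))
        if denom <= 0:
            raise ValidationError("all markers monomorphic; GRM undefined")
        vals = centered @ centered.T / denom
        vals = (vals + vals.T) / 2
        return KinshipMatrix(vals, list(g.samples), "centered-grm")
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# Mixed-model scan
# ---------------------------------------------------------------------------


def _imputed_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-marker mean imputation of missing calls
    (used for the regression only)."""
    x = g.calls.astype(float)
    x[x < 0] = np.nan
    means = np.nanmean(x, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(x))
    x[idx] = means[idx[1]]
    return x


def _reml_profile(
    yr: np.ndarray,
    x1r: np.ndarray,
    xr: np.ndarray,
    s: np.ndarray,
    deltas: np.ndarray,
):
    """REML criterion and GLS pieces for all markers at all deltas.

    Returns (crit, rss, beta, a_inv22) arrays of shape (n_deltas, n_markers)
    where crit is the negative restricted log-likelihood up to a constant.
    """
    m = xr.shape[1]
    nd = len(deltas)
    n = len(yr)
    p = 2
    crit = np.empty((nd, m))
    rss_out = np.empty((nd, m))
    beta_out = np.empty((nd, m))
    ainv22_out = np.empty((nd, m))
    for di, d in enumerate(deltas):
        w = 1.0 / (s + d)  # (n,)
        logdet_v = np.sum(np.log(s + d))
        a11 = float(np.sum(w * x1r * x1r))
        b1 = float(np.sum(w * x1r * yr))
        wy = w * yr
        a12 = (w * x1r) @ xr  # (m,)
        a22 = w @ (xr * xr)
        b2 = wy @ xr
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        beta1 = (a22 * b1 - a12 * b2) / det
        beta2 = (a11 * b2 - a12 * b1) / det
        ywy = float(np.sum(wy * yr))
        rss = ywy - b1 * beta1 - b2 * beta2
        rss = np.maximum(rss, 1e-12)
        with np.errstate(invalid="ignore"):
            crit[di] = (
                (n - p) * np.log(rss) + logdet_v + np.log(np.abs(det))
            )
        rss_out[di] = rss
        beta_out[di] = beta2
        ainv22_out[di] = a11 / det
    crit[~np.isfinite(crit)] = np.inf
    return crit, rss_out, beta_out, ainv22_out


def reml_delta(
    y: np.ndarray, x: np.ndarray, K: np.ndarray,
    log10_bounds: tuple[float, float] = (-5.0, 5.0),
    n_grid: int = 64, n_refine: int = 2,
) -> float:
    """REML estimate of delta = se^2/sg^2 for a single marker (used directly
    by tests; lmm_scan runs the same search vectorized across markers)."""
    s, u = np.linalg.eigh((K + K.T) / 2)
    yr = u.T @ y
    x1r = u.T @ np.ones_like(y)
    xr = (u.T @ x).reshape(-1, 1)
    lo, hi = log10_bounds
    grid = np.logspace(lo, hi, n_grid)
    best = None
    for _ in range(n_refine + 1):
        crit, *_ = _reml_profile(yr, x1r, xr, s, grid)
        k = int(np.argmin(crit[:, 0]))
        best = grid[k]
        lo_i, hi_i = max(k - 1, 0), min(k + 1, len(grid) - 1)
        grid = np.logspace(
            np.log10(grid[lo_i]), np.log10(grid[hi_i]), n_grid
        )
    return float(best)


def lmm_scan(
    g: GenotypeMatrix,
    phenotype: np.ndarray,
    K: KinshipMatrix,
    n_grid: int = 64,
    n_refine: int = 2,
) -> pd.DataFrame:
    """Per-marker mixed-model association scan.

    Phenotype is case/control coded 1/0 (treated quantitatively, as GEMMA
    does for binary traits).  For each marker the variance ratio delta is
    re-optimized by REML on a log-spaced grid spanning 1e-5..1e5 with two
    refinement passes, then a Wald test on the marker effect is carried out
    against F(1, n-2).

    Returns a DataFrame with marker_id, chromosome, position_bp, beta, se,
    statistic (the squared Wald ratio) and p_value.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != g.n_samples:
        raise ValidationError("phenotype length != sample count")
    Kv = K.values
    s, u = np.linalg.eigh((Kv + Kv.T) / 2)
    if s[0] < -1e-8 * max(1.0, s[-1]):
        raise ValidationError(
            f"kinship matrix not PSD: smallest eigenvalue {s[0]:.3e}"
        )
    s = np.clip(s, 0.0, None)
    x = _imputed_dosages(g)
    poly = np.std(x, axis=0) > 0
    n, m = x.shape
    p = 2

    yr = u.T @ y
    x1r = u.T @ np.ones(n)
    xr = u.T @ x

    grid = np.logspace(-5, 5, n_grid)
    lo = np.full(m, -5.0)
    hi = np.full(m, 5.0)
    best_delta = np.ones(m)
    for _ in range(n_refine + 1):
        # per-marker grids share shape; build log-spaced grid per marker
        t = np.linspace(0, 1, n_grid)[:, None]
        grids = 10 ** (lo[None, :] + t * (hi - lo)[None, :])
        crit = _reml_profile_rows(yr, x1r, xr, s, grids)
        k = np.argmin(crit, axis=0)
        best_delta = grids[k, np.arange(m)]
        step = (hi - lo) / (n_grid - 1)
        lo = np.log10(best_delta) - step
        hi = np.log10(best_delta) + step

    # final statistics at the chosen delta
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    stat = np.zeros(m)
    pval = np.ones(m)
    for j in range(m):
        if not poly[j]:
            continue
        w = 1.0 / (s + best_delta[j])
        a11 = np.sum(w * x1r * x1r)
        a12 = np.sum(w * x1r * xr[:, j])
        a22 = np.sum(w * xr[:, j] ** 2)
        b1 = np.sum(w * x1r * yr)
        bb2 = np.sum(w * xr[:, j] * yr)
        det = a11 * a22 - a12**2
        if det <= 0:
            continue
        beta1 = (a22 * b1 - a12 * bb2) / det
        beta2 = (a11 * bb2 - a12 * b1) / det
        r = np.sum(w * yr**2) - b1 * beta1 - bb2 * beta2
        sigma2 = max(r, 1e-12) / (n - p)
        var_b = sigma2 * a11 / det
        beta[j] = beta2
        se[j] = math.sqrt(var_b)
        stat[j] = beta2**2 / var_b
        pval[j] = float(stats.f.sf(stat[j], 1, n - p))

    return pd.DataFrame(
        {
            "marker_id": g.markers.ids,
            "chromosome": g.markers.chrom,
            "position_bp": g.markers.pos,
            "beta": beta,
            "se": se,
            "statistic": stat,
            "p_value": np.clip(pval, np.finfo(float).tiny, 1.0),
            "monomorphic": ~poly,
            "delta": best_delta,
        }
    )


def _reml_profile_rows(
    yr: np.ndarray, x1r: np.ndarray, xr: np.ndarray, s: np.ndarray,
    grids: np.ndarray,
) -> np.ndarray:
    """REML criterion where row di of ``grids`` holds a per-marker delta
    vector; returns (n_grid, n_markers)."""
    nd, m = grids.shape
    n = len(yr)
    p = 2
    crit = np.empty((nd, m))
    y2 = yr * yr
    for di in range(nd):
        d = grids[di]  # (m,)
        w = 1.0 / (s[:, None] + d[None, :])  # (n, m)
        logdet_v = np.log(s[:, None] + d[None, :]).sum(axis=0)
        a11 = (w * x1r[:, None] ** 2).sum(axis=0)
        a12 = (w * x1r[:, None] * xr).sum(axis=0)
        a22 = (w * xr * xr).sum(axis=0)
        b1 = (w * x1r[:, None] * yr[:, None]).sum(axis=0)
        b2 = (w * xr * yr[:, None]).sum(axis=0)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        beta1 = (a22 * b1 - a12 * b2) / det
        beta2 = (a11 * b2 - a12 * b1) / det
        rss = (w * y2[:, None]).sum(axis=0) - b1 * beta1 - b2 * beta2
        rss = np.maximum(rss, 1e-12)
        with np.errstate(invalid="ignore"):
            crit[di] = (n - p) * np.log(rss) + logdet_v + np.log(np.abs(det))
    crit[~np.isfinite(crit)] = np.inf
    return crit


# ---------------------------------------------------------------------------
# Allelic chi-square scan
# ---------------------------------------------------------------------------


def allelic_chisq_scan(g: GenotypeMatrix, phenotype: np.ndarray) -> pd.DataFrame:
    """Uncorrected 1-df allelic chi-square per marker (2x2 allele-count
    table, no continuity correction).  Monomorphic markers get p = 1 and a
    flag."""
    y = np.asarray(phenotype)
    calls = g.calls
    is_case = y == 1
    stat = np.zeros(g.n_markers)
    pval = np.ones(g.n_markers)
    mono = np.zeros(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        c = calls[:, j]
        obs = c >= 0
        a_case = int(c[obs & is_case].sum())
        n_case = 2 * int((obs & is_case).sum())
        a_ctrl = int(c[obs & ~is_case].sum())
        n_ctrl = 2 * int((obs & ~is_case).sum())
        a = a_case
        b = n_case - a_case
        cc = a_ctrl
        d = n_ctrl - a_ctrl
        tot = a + b + cc + d
        col1, col2 = a + cc, b + d
        if col1 == 0 or col2 == 0 or n_case == 0 or n_ctrl == 0:
            mono[j] = True
            continue
        x2 = tot * (a * d - b * cc) ** 2 / (
            (a + b) * (cc + d) * col1 * col2
        )
        stat[j] = x2
        pval[j] = float(stats.chi2.sf(x2, 1))
    return pd.DataFrame(
        {
            "marker_id": g.markers.ids,
            "chromosome": g.markers.chrom,
            "position_bp": g.markers.pos,
            "statistic": stat,
            "p_value": np.clip(pval, np.finfo(float).tiny, 1.0),
            "monomorphic": mono,
        }
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile of the
    observed p-values divided by the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValidationError("no finite p-values")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def significance_thresholds(
    n_markers: int, alpha: float = 0.05, suggestive: float = 5e-5
) -> tuple[float, float]:
    """(suggestive, Bonferroni) genome-wide thresholds."""
    if n_markers < 1:
        raise ValidationError("n_markers must be >= 1")
    return suggestive, alpha / n_markers


def classical_mds(matrix: np.ndarray, n_dims: int = 2,
                  is_distance: bool = False) -> np.ndarray:
    """Classical (Torgerson) metric MDS.

    When ``is_distance`` is false the input is a similarity (e.g. an IBS
    kinship) converted to distances as 1 - similarity.  Double-centers the
    squared distance matrix and returns the top ``n_dims`` eigenvectors
    scaled by the square roots of their (non-negative) eigenvalues.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("MDS input must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValidationError("MDS input must be symmetric")
    d = m if is_distance else 1.0 - m
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1][:n_dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]
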