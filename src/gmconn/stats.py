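"""Edge-level statistics: distribution tests, robust regressions with
permutation-tested slopes, slope comparisons, FDR and top-fraction
thresholding.

The robust fits use Huber's loss (tuning constant 1.345, ~95% Gaussian
efficiency) solved by iteratively reweighted least squares with a
median-absolute-deviation scale, matching the conventional "Huber's T"
robust linear model.  The IRLS core is vectorized over many response
vectors at once so that slope permutation tests (the observed and the
shuffled fits share one estimator) stay cheap at thousands of
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import EdgeSubsetLabeling
from .matrix import ConnectivityMatrix

HUBER_C = 1.345

__all__ = [
    "RobustFitResult",
    "PairedTestResult",
    "shapiro_normality",
    "paired_wilcoxon",
    "huber_fit",
    "permute_slope_p",
    "compare_slopes_z",
    "bh_fdr",
    "threshold_top_fraction",
    "subset_regression_report",
]


@dataclass(frozen=True)
class RobustFitResult:
    """Huber regression of one edge vector on another."""

    slope: float
    intercept: float
    slope_se: float
    n_edges: int
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank comparison of two paired edge vectors."""

    statistic: float
    p_value: float
    n_pairs: int
    direction: int


def shapiro_normality(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p for a sample of 3..5000 values."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3..5000 values, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant sample; normality test undefined")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def paired_wilcoxon(vec_a: np.ndarray, vec_b: np.ndarray) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment) and the
    reported W is the smaller of the positive/negative rank sums.
    ``direction`` is the sign of the median difference a - b.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D with equal length")
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs, got {a.size}")
    d = a - b
    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("all paired differences are zero; test degenerate")
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=int(nonzero.sum()),
        direction=int(np.sign(np.median(d))),
    )


# ---------------------------------------------------------------------------
# Huber IRLS (batched over response rows)
# ---------------------------------------------------------------------------

def _huber_irls(
    x: np.ndarray,
    Y: np.ndarray,
    c: float = HUBER_C,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """IRLS for y = a + b x with Huber weights, one row of Y at a time.

    Scale is re-estimated each iteration as MAD(resid)/0.6745 (zero
    centre).  Returns (slope, intercept, converged mask, iterations run).
    A row with an exact linear fit has zero scale; it keeps unit weights,
    i.e., collapses to OLS, which is already exact.
    """
    n = x.size
    sx = x.sum()
    # OLS start
    xc = x - x.mean()
    varx = (xc**2).sum()
    b = (Y @ xc) / varx
    a = Y.mean(axis=1) - b * x.mean()
    converged = np.zeros(Y.shape[0], dtype=bool)
    it = 0
    for it in range(1, maxiter + 1):
        resid = Y - a[:, None] - b[:, None] * x
        scale = np.median(np.abs(resid), axis=1) / 0.6745
        safe = np.where(scale > 1e-12, scale, 1.0)
        u = np.abs(resid) / safe[:, None]
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, c / np.where(u > 0, u, np.inf))
        w[scale <= 1e-12] = 1.0
        sw = w.sum(axis=1)
        swx = w @ x
        swxx = w @ (x**2)
        swy = (w * Y).sum(axis=1)
        swxy = (w * Y) @ x
        det = sw * swxx - swx**2
        b_new = (sw * swxy - swx * swy) / det
        a_new = (swy - b_new * swx) / sw
        step = np.maximum(np.abs(a_new - a), np.abs(b_new - b))
        a, b = a_new, b_new
        converged = step < tol
        if converged.all():
            break
    return b, a, converged, it


def _huber_slope_se(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    """Asymptotic slope SE for the Huber fit (Huber's correction factor)."""
    n, p = x.size, 2
    resid = y - intercept - slope * x
    scale = np.median(np.abs(resid)) / 0.6745
    if scale <= 1e-12:
        return 0.0
    u = resid / scale
    psi = np.clip(u, -HUBER_C, HUBER_C)
    psi_prime = (np.abs(u) <= HUBER_C).astype(float)
    m = psi_prime.mean()
    k = 1.0 + (p / n) * psi_prime.var() / m**2
    s2 = k**2 * (scale**2) * (psi**2).sum() / (n - p) / m**2
    X = np.column_stack([np.ones(n), x])
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(np.sqrt(cov[1, 1]))


def huber_fit(
    x: np.ndarray, y: np.ndarray, tol: float = 1e-8, maxiter: int = 100
) -> RobustFitResult:
    """Robust line fit of y on x with Huber's loss (c = 1.345)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    slope, intercept, converged, it = _huber_irls(x, y[None, :], tol=tol, maxiter=maxiter)
    if not converged[0]:
        raise RuntimeError(f"Huber IRLS did not converge within {it} iterations")
    s, a = float(slope[0]), float(intercept[0])
    return RobustFitResult(
        slope=s, intercept=a, slope_se=_huber_slope_se(x, y, s, a), n_edges=x.size
    )


def permute_slope_p(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    chunk: int = 250,
) -> RobustFitResult:
    """Two-sided permutation p for the Huber slope of y on x.

    y is shuffled relative to x ``n_perm`` times and the fraction of
    permuted |slopes| at least as extreme as the observed one is reported
    with the add-one estimator (1 + k) / (1 + N), which cannot return 0.
    """
    fit = huber_fit(x, y)
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    count = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(y.size) for _ in range(m)])
        slopes, _, _, _ = _huber_irls(x, y[perms])
        count += int((np.abs(slopes) >= abs(fit.slope)).sum())
        done += m
    p = (1 + count) / (1 + n_perm)
    return replace(fit, permutation_p=p, n_permutations=n_perm, seed=seed)


def compare_slopes_z(fit_1: RobustFitResult, fit_2: RobustFitResult) -> tuple[float, float]:
    """Z = (b1 - b2) / sqrt(se1^2 + se2^2) and its two-sided normal p."""
    if not (np.isfinite(fit_1.slope_se) and np.isfinite(fit_2.slope_se)):
        raise ValueError("both fits must carry finite slope SEs")
    denom = np.hypot(fit_1.slope_se, fit_2.slope_se)
    if denom == 0:
        raise ValueError("combined slope SE is zero; Z undefined")
    z = (fit_1.slope - fit_2.slope) / denom
    return float(z), float(2 * sps.norm.sf(abs(z)))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_top_fraction(
    matrices: list[ConnectivityMatrix],
    fraction: float = 0.25,
    mode: str = "adapted",
) -> tuple[list[float], list[np.ndarray]]:
    """Thresholds keeping the strongest ``fraction`` of edges.

    ``adapted``: each matrix gets its own threshold, the k-th largest of
    its upper-triangle values with k = ceil(fraction * n_edges).
    ``common``: one threshold from the pooled upper-triangle values of all
    supplied matrices, applied to each.  Masks keep edges with value >=
    threshold, so ties at the threshold are all retained.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    uppers = [m.upper() for m in matrices]
    if mode == "adapted":
        thresholds = []
        for v in uppers:
            k = int(np.ceil(fraction * v.size))
            thresholds.append(float(np.sort(v)[-k]))
    elif mode == "common":
        pooled = np.concatenate(uppers)
        k = int(np.ceil(fraction * pooled.size))
        thr = float(np.sort(pooled)[-k])
        thresholds = [thr] * len(uppers)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    masks = [v >= t for v, t in zip(uppers, thresholds)]
    return thresholds, masks


DEFAULT_SUBSETS = (
    "whole-brain",
    "cortico-subcortical",
    "thalamo-cortical",
    "cc-intraH",
    "cc-interH-homo",
    "cc-interH-non-homo",
    "SM",
    "VIS",
)


def subset_regression_report(
    mc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    labeling: EdgeSubsetLabeling,
    subsets: tuple[str, ...] = DEFAULT_SUBSETS,
    n_perm: int = 1000,
    seed: int = 0,
    min_edges: int = 10,
) -> pd.DataFrame:
    """Per-subset robust MC->FC regressions with BH-adjusted permutation p.

    MC edges are the predictor and FC edges the response.  Subsets with
    fewer than ``min_edges`` edges are recorded as skipped; BH correction
    runs across the fitted family only.
    """
    x_all = mc.upper()
    y_all = fc.upper()
    if len(labeling.category) != x_all.size:
        raise ValueError("edge labeling does not match the matrix size")
    masks = labeling.subset_masks()
    rows = []
    for i, name in enumerate(subsets):
        if name not in masks:
            raise ValueError(f"unknown subset {name!r}")
        mask = masks[name]
        n = int(mask.sum())
        if n < min_edges:
            rows.append(
                {"subset": name, "n_edges": n, "slope": np.nan, "intercept": np.nan,
                 "slope_se": np.nan, "perm_p": np.nan, "skipped": True}
            )
            continue
        fit = permute_slope_p(x_all[mask], y_all[mask], n_perm=n_perm, seed=seed + i)
        rows.append(
            {"subset": name, "n_edges": n, "slope": fit.slope, "intercept": fit.intercept,
             "slope_se": fit.slope_se, "perm_p": fit.permutation_p, "skipped": False}
        )
    df = pd.DataFrame(rows)
    df["perm_p_bh"] = np.nan
    fitted = ~df["skipped"]
    if fitted.any():
        df.loc[fitted, "perm_p_bh"] = bh_fdr(df.loc[fitted, "perm_p"].to_numpy())
    df["n_perm"] = n_perm
    df["seed"] = seed
    return df
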