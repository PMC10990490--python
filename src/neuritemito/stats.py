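"""Statistical layer: ROUT outlier removal (Q = 1%), the FRAP
animal-exclusion rule, one-way ANOVA with Dunnett's many-to-one test,
paired t-tests, and the Pearson effect-size screen (|r| < 0.3).

ROUT here is the published robust-regression-and-outlier-test specialized to
a constant (location-only) model, which is how it applies to a list of
measurements: a robust center is found by iteratively reweighted least
squares with a Lorentzian loss, scale is the sample-size-corrected 68.27th
percentile of absolute residuals (RSDR), and outliers are declared by a
false-discovery step-up on the most extreme residuals with budget Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "OutlierResult",
    "DunnettResult",
    "rout_outliers",
    "frap_exclusion",
    "anova_dunnett",
    "paired_t",
    "effect_size_screen",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class GroupData:
    """One experimental group's scalar measurements."""

    group_name: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise InsufficientDataError(
                f"group {self.group_name!r} needs n >= 2, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group_name!r} has non-finite values")


@dataclass
class OutlierResult:
    kept_indices: list[int]
    outlier_indices: list[int]
    Q_percent: float
    method_details: dict = field(default_factory=dict)


@dataclass
class DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons."""

    anova_F: float
    anova_p: float
    control: str
    comparisons: list[dict]  # group, mean_diff, t, p_unadjusted, p_adjusted
    mc_tolerance: float


# ---------------------------------------------------------------------------
# ROUT


def _robust_location(x: np.ndarray, max_iter: int = 60, tol: float = 1e-10) -> float:
    """IRLS fit of a constant with Lorentzian weights w = 1/(1 + (r/s)^2)."""
    center = float(np.median(x))
    for _ in range(max_iter):
        r = x - center
        s = np.percentile(np.abs(r), 68.27)
        if s == 0:
            return center
        w = 1.0 / (1.0 + (r / s) ** 2)
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - center) < tol * max(abs(center), 1.0):
            return new
        center = new
    return center


def rout_outliers(values: Sequence[float], Q_percent: float = 1.0) -> OutlierResult:
    """Flag outliers in a measurement list by the ROUT construction.

    ``Q_percent`` is the maximum desired false-discovery rate in percent
    (default 1).  Residuals from the robust location fit are scaled by the
    RSDR and converted to two-sided t tail probabilities (df = n - 1); the
    most extreme points are then flagged by a false-discovery step-up with
    boundary ``i * Q / n`` for the i-th smallest p-value.  ``Q_percent = 0``
    flags nothing.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"ROUT needs n >= 5, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    K = 1  # parameters of the constant model
    center = _robust_location(x)
    resid = x - center
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / (n - K)
    details = {"robust_center": center, "rsdr": rsdr}
    if rsdr == 0 or Q_percent <= 0:
        # constant data (or zero budget): any deviation from an exact
        # constant is tested against machine tolerance
        if Q_percent <= 0 or np.allclose(x, center):
            return OutlierResult(list(range(n)), [], Q_percent, details)
        out = [int(i) for i in np.flatnonzero(~np.isclose(x, center))]
        kept = [i for i in range(n) if i not in out]
        return OutlierResult(kept, out, Q_percent, details)

    t_vals = np.abs(resid) / rsdr
    p_vals = 2.0 * sps.t.sf(t_vals, df=n - K)
    order = np.argsort(p_vals)  # most extreme first
    q = Q_percent / 100.0
    # Benjamini-Hochberg step-up: flag the i most extreme points where i is
    # the largest index with p_(i) <= i*q/n
    n_out = 0
    for i, idx in enumerate(order, start=1):
        if p_vals[idx] <= i * q / n:
            n_out = i
    outliers = sorted(int(i) for i in order[:n_out])
    kept = [i for i in range(n) if i not in set(outliers)]
    details["t_values"] = t_vals.tolist()
    details["p_values"] = p_vals.tolist()
    return OutlierResult(kept, outliers, Q_percent, details)


def frap_exclusion(outlier_flags_by_animal: dict[str, Sequence[bool]]) -> list[str]:
    """Animals kept under the FRAP rule: excluded iff >= 50% of their
    timepoints were flagged as outliers."""
    counts = {len(list(v)) for v in outlier_flags_by_animal.values()}
    if len(counts) > 1:
        raise ValueError("all animals must have the same timepoint count")
    kept = []
    for animal, flags in outlier_flags_by_animal.items():
        flags = list(flags)
        if sum(bool(f) for f in flags) / len(flags) < 0.5:
            kept.append(animal)
    return kept


# ---------------------------------------------------------------------------
# Dunnett


_MC_CACHE: dict[tuple, np.ndarray] = {}


def _dunnett_max_t_sample(
    lambdas: tuple[float, ...], df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo sample of max_j |T_j| under the Dunnett null.

    T_j = (Z_j) / sqrt(W) with Z ~ MVN(0, R), R_ij = lambda_i*lambda_j for
    i != j, and W ~ chi2(df)/df shared across comparisons.
    """
    key = (lambdas, df, n_draws, seed)
    if key not in _MC_CACHE:
        rng = np.random.default_rng(seed)
        lam = np.asarray(lambdas)
        # factor structure: Z_j = lam_j * Z0 + sqrt(1 - lam_j^2) * E_j
        z0 = rng.standard_normal(n_draws)
        e = rng.standard_normal((n_draws, len(lam)))
        z = lam[None, :] * z0[:, None] + np.sqrt(1 - lam**2)[None, :] * e
        w = rng.chisquare(df, size=n_draws) / df
        _MC_CACHE[key] = np.max(np.abs(z), axis=1) / np.sqrt(w)
    return _MC_CACHE[key]


def anova_dunnett(
    groups: Sequence[GroupData],
    seed: int = 0,
    n_draws: int = 100_000,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett's test of every group against the control.

    Adjusted p-values come from the multivariate-t reference distribution,
    evaluated exactly for a single comparison and by fixed-seed Monte Carlo
    (``n_draws`` draws, tolerance ~1/sqrt(n_draws)) otherwise.
    """
    controls = [g for g in groups if g.is_control]
    if len(groups) < 2 or len(controls) != 1:
        raise ValueError("need >= 2 groups with exactly one control")
    control = controls[0]
    treatments = [g for g in groups if not g.is_control]

    all_values = [g.values for g in groups]
    if all(np.var(v) == 0 for v in all_values):
        raise DegenerateDataError("zero within-group variance in every group")
    F, p = sps.f_oneway(*all_values)

    n_total = sum(len(v) for v in all_values)
    k = len(groups)
    df = n_total - k
    # pooled within-group variance
    ss_within = sum(np.sum((v - v.mean()) ** 2) for v in all_values)
    s2 = ss_within / df

    lambdas = tuple(
        float(np.sqrt(len(g.values) / (len(g.values) + len(control.values))))
        for g in treatments
    )
    comparisons = []
    if len(treatments) == 1:
        sampler = None
        tol = 0.0
    else:
        sampler = _dunnett_max_t_sample(lambdas, df, n_draws, seed)
        tol = 1.0 / np.sqrt(n_draws)
    for g in treatments:
        diff = float(g.values.mean() - control.values.mean())
        se = np.sqrt(s2 * (1.0 / len(g.values) + 1.0 / len(control.values)))
        t = diff / se
        p_un = float(2.0 * sps.t.sf(abs(t), df))
        if sampler is None:
            p_adj = p_un  # single comparison: multivariate t is univariate t
        else:
            # max over the family dominates each marginal, so clip at p_un
            p_adj = max(float(np.mean(sampler >= abs(t))), p_un)
        comparisons.append({
            "group": g.group_name, "mean_diff": diff, "t": float(t),
            "df": df, "p_unadjusted": p_un, "p_adjusted": max(p_adj, 0.0),
        })
    return DunnettResult(anova_F=float(F), anova_p=float(p),
                         control=control.group_name, comparisons=comparisons,
                         mc_tolerance=tol)


# ---------------------------------------------------------------------------


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-sided paired t-test; returns p-value and mean difference (a - b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise InsufficientDataError(f"paired t needs n >= 3, got {len(a)}")
    d = a - b
    mean_diff = float(d.mean())
    if np.var(d, ddof=1) == 0:
        # all differences identical; the t statistic is undefined
        return {"p": 1.0 if mean_diff == 0 else 0.0, "mean_diff": mean_diff,
                "t": float("nan"), "df": len(a) - 1, "degenerate": True}
    t, p = sps.ttest_rel(a, b)
    return {"p": float(p), "mean_diff": mean_diff, "t": float(t),
            "df": len(a) - 1, "degenerate": False}


def effect_size_screen(
    values: Sequence[float],
    covariate: Sequence[float] | None = None,
    r_max: float = 0.3,
) -> dict:
    """Pearson correlation screen for small effect size.

    ``covariate`` defaults to acquisition order (0..n-1).  Passes iff
    ``|r| < r_max`` (strict).  Zero variance in either vector yields an
    undefined-r flag rather than a pass/fail verdict.
    """
    v = np.asarray(values, dtype=float)
    if covariate is None:
        covariate = np.arange(len(v), dtype=float)
    c = np.asarray(covariate, dtype=float)
    if len(v) != len(c):
        raise ValueError("values and covariate must have equal length")
    if len(v) < 3:
        raise InsufficientDataError(f"need n >= 3, got {len(v)}")
    if np.var(v) == 0 or np.var(c) == 0:
        return {"r": float("nan"), "pass": None, "undefined": True}
    r, p = sps.pearsonr(v, c)
    return {"r": float(r), "p": float(p), "pass": bool(abs(r) < r_max),
            "undefined": False}
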