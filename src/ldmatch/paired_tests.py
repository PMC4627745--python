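"""Paired comparison of region-level LD summaries.

Each matched pair (reference region, control region) contributes one paired
observation per measure (median r^2, median r^2_s, haplotype diversity...).
The two-sided Wilcoxon signed-rank test assesses whether the paired
differences are symmetric about zero, per chromosome and genome-wide.
Reported effect sizes are percentage differences
Delta = (ref - ctrl) / ref * 100, averaged over pairs with their standard
error; the test itself always runs on the raw paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata


class PairedTestError(ValueError):
    """Raised for invalid paired-test inputs."""


@dataclass
class PairedSample:
    """Paired (reference, control) values for one measure/comparison/scope."""

    ref: np.ndarray
    ctrl: np.ndarray
    measure: str = ""
    comparison: str = ""  # G_vs_IG | IG_vs_IGprime
    scope: str = "genome"

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=float)
        self.ctrl = np.asarray(self.ctrl, dtype=float)
        if self.ref.shape != self.ctrl.shape or self.ref.ndim != 1:
            raise PairedTestError("ref/ctrl must be 1-D arrays of equal length")
        if self.ref.size == 0:
            raise PairedTestError("paired sample is empty")
        if not (np.isfinite(self.ref).all() and np.isfinite(self.ctrl).all()):
            raise PairedTestError("paired values must be finite")

    @property
    def n_pairs(self) -> int:
        return int(self.ref.size)


@dataclass
class ComparisonResult:
    """Summary of one paired comparison at one scope."""

    scope: str
    measure: str
    comparison: str
    n_pairs: int
    mean_ref: float
    mean_ctrl: float
    mean_pct_diff: float
    se_pct_diff: float
    wilcoxon_statistic: float
    p_value: float
    significant: bool
    testable: bool = True


_EXACT_N_MAX = 25


def _exact_signed_rank_p(w: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the positive-rank sum under the sign-flip null.

    Dynamic programming over the 2^n equiprobable sign assignments; average
    ranks are half-integers, so doubling them gives an integer-supported
    distribution.  Equivalent to full sign enumeration.
    """
    s = np.rint(2.0 * ranks).astype(np.int64)
    total = int(s.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for si in s:
        nxt = counts.copy()
        nxt[si:] += counts[: total + 1 - si]
        counts = nxt
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(differences, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; absolute differences get average ranks;
    the statistic W is the rank sum of the positive differences.  The null
    distribution is exact (full sign-assignment enumeration via dynamic
    programming) for n <= 25, and a normal approximation with tie-corrected
    variance and continuity correction beyond that.  Returns ``(W, p)``.
    """
    if mode not in ("auto", "exact", "normal"):
        raise PairedTestError(f"unknown mode {mode!r}")
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise PairedTestError("differences must be a non-empty 1-D array")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn(
            "all paired differences are zero; test degenerate, p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    n = d.size
    ranks = rankdata(np.abs(d))  # average ranks for ties
    w = float(ranks[d > 0].sum())
    if mode == "exact" or (mode == "auto" and n <= _EXACT_N_MAX):
        return w, _exact_signed_rank_p(w, ranks)
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (
        (tie_counts**3 - tie_counts).sum() / 48.0
    )
    if sigma2 <= 0:
        return w, 1.0
    dev = w - mu
    if dev == 0:
        return w, 1.0
    z = (abs(dev) - 0.5) / np.sqrt(sigma2)  # continuity correction
    return w, float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def percent_difference(value_ref: float, value_ctrl: float) -> float:
    """Delta in percent: (ref - ctrl) / ref * 100.  A zero reference makes
    the pair unusable (NaN, with a warning)."""
    if value_ref == 0:
        warnings.warn(
            "reference value is zero; percentage difference undefined, "
            "pair skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return (value_ref - value_ctrl) / value_ref * 100.0


def compare(
    sample: PairedSample, alpha: float = 0.05, delta_mode: str = "per_pair"
) -> ComparisonResult:
    """Paired comparison: mean percentage difference with its standard error,
    and a two-sided Wilcoxon signed-rank test on the raw differences.

    ``delta_mode='per_pair'`` (default) averages per-pair percentages;
    ``'pooled'`` reports the percentage difference of the pooled means.
    Fewer than 2 pairs yields an untestable result (p = NaN).
    """
    if delta_mode not in ("per_pair", "pooled"):
        raise PairedTestError(f"unknown delta_mode {delta_mode!r}")
    ref, ctrl = sample.ref, sample.ctrl
    n = sample.n_pairs

    if delta_mode == "per_pair":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pct = np.array(
                [percent_difference(a, b) for a, b in zip(ref, ctrl)]
            )
        pct = pct[np.isfinite(pct)]
        if pct.size == 0:
            mean_pct, se_pct = float("nan"), float("nan")
        else:
            mean_pct = float(pct.mean())
            se_pct = (
                float(pct.std(ddof=1) / np.sqrt(pct.size))
                if pct.size > 1
                else float("nan")
            )
    else:
        mr, mc = float(ref.mean()), float(ctrl.mean())
        mean_pct = percent_difference(mr, mc)
        se_pct = float("nan")

    if n < 2:
        return ComparisonResult(
            scope=sample.scope, measure=sample.measure,
            comparison=sample.comparison, n_pairs=n,
            mean_ref=float(ref.mean()), mean_ctrl=float(ctrl.mean()),
            mean_pct_diff=mean_pct, se_pct_diff=se_pct,
            wilcoxon_statistic=float("nan"), p_value=float("nan"),
            significant=False, testable=False,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        w, p = wilcoxon_signed_rank(ref - ctrl)
    return ComparisonResult(
        scope=sample.scope, measure=sample.measure,
        comparison=sample.comparison, n_pairs=n,
        mean_ref=float(ref.mean()), mean_ctrl=float(ctrl.mean()),
        mean_pct_diff=mean_pct, se_pct_diff=se_pct,
        wilcoxon_statistic=w, p_value=p,
        significant=bool(p < alpha), testable=True,
    )


def concordance_r2_vs_r2s(delta_r2, delta_r2s) -> float:
    """Coefficient of determination (R^2) of the per-chromosome mean
    percentage differences for r^2_s regressed on those for r^2 — high
    concordance indicates the matching removed MAF-driven scale effects."""
    x = np.asarray(delta_r2, dtype=float)
    y = np.asarray(delta_r2s, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise PairedTestError("concordance needs >= 3 paired chromosome means")
    if np.allclose(x, x[0]):
        raise PairedTestError("zero variance in predictor series")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot
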