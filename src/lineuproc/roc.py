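"""ROC construction, partial AUC with bootstrap CIs, and single-point
accuracy/bias statistics.

The ROC plots the correct-identification rate of guilty suspects (H) against
the false-identification rate of innocent suspects (F), one point per
response criterion or cumulative confidence level.  The partial area under
the curve up to a maximum false-alarm rate (pAUC) summarizes discrimination
free of response bias; single-point summaries computed here for comparison
are the detection-theoretic d' estimate z(H) - z(F), the bias statistic
c = -0.5 (z(H) + z(F)), and the diagnosticity ratio D = H / F, whose
theoretical equal-value ROC is the straight line H = D * F.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import TrialPool, as_generator
from .procedures import (
    DecisionRule,
    RateTable,
    ThresholdSet,
    default_sweep,
    response_thresholds,
)

__all__ = [
    "ROCCurve",
    "PAUCResult",
    "BiasAccuracyStats",
    "empirical_roc",
    "pauc",
    "bootstrap_pauc",
    "analytic_roc_from_auc",
    "bias_stats",
    "diagnosticity_bias_curves",
    "NonmonotoneROCWarning",
]


class NonmonotoneROCWarning(UserWarning):
    """Raised when a folding (non-monotone) ROC is reduced to its upper
    envelope before integration."""


@dataclass
class ROCCurve:
    """Ordered ROC operating points.

    Points are ordered from conservative to liberal criteria, i.e. from the
    origin outward.  ``criterion`` holds the generating criterion (or a
    confidence level) for each point; ``monotone`` is True iff F never
    decreases along the ordering, which fails for the first-ID sequential
    procedure at liberal criteria.
    """

    f: np.ndarray
    h: np.ndarray
    criterion: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if self.f.shape != self.h.shape or self.f.ndim != 1:
            raise ValueError("f and h must be 1-D arrays of equal length")
        if self.f.size == 0:
            raise ValueError("an ROC needs at least one point")
        for name, arr in (("f", self.f), ("h", self.h)):
            if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} coordinates must lie in [0, 1]")
        if self.criterion is not None:
            self.criterion = np.atleast_1d(np.asarray(self.criterion, dtype=float))
            if self.criterion.shape != self.f.shape:
                raise ValueError("criterion must align with the points")

    @property
    def n_points(self) -> int:
        return self.f.size

    @property
    def monotone(self) -> bool:
        return bool(np.all(np.diff(self.f) >= 0))

    @classmethod
    def from_rate_table(cls, rt: RateTable) -> "ROCCurve":
        """Order a rate table's operating points conservative -> liberal."""
        tab = rt.table.sort_values("criterion", ascending=False)
        return cls(f=tab["F"].to_numpy(), h=tab["H"].to_numpy(),
                   criterion=tab["criterion"].to_numpy(),
                   provenance=dict(rt.meta, n_tp=rt.n_tp, n_ta=rt.n_ta))

    def upper_envelope(self) -> "ROCCurve":
        """Monotone hull in F: for each false-alarm rate keep the largest hit
        rate reached at or before it.  Identity for monotone curves up to
        point ordering."""
        idx = np.argsort(self.f, kind="stable")
        f = self.f[idx]
        h = np.maximum.accumulate(self.h[idx])
        keep = np.ones(f.size, dtype=bool)
        keep[:-1] = (np.diff(f) > 0) | (np.diff(h) > 0)
        crit = self.criterion[idx][keep] if self.criterion is not None else None
        return ROCCurve(f=f[keep], h=h[keep], criterion=crit,
                        provenance=dict(self.provenance, envelope=True))

    def auc(self) -> float:
        """Full trapezoidal area, extending the curve horizontally to F = 1."""
        return pauc(self, 1.0)

    def to_frame(self) -> pd.DataFrame:
        data = {"F": self.f, "H": self.h}
        if self.criterion is not None:
            data = {"criterion": self.criterion, **data}
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def empirical_roc(tp_counts, ta_counts, n_tp: int, n_ta: int,
                  levels=None) -> ROCCurve:
    """Cumulative ROC from confidence-binned identification counts.

    ``tp_counts`` and ``ta_counts`` list positive-response counts per
    confidence level ordered from the highest (most confident) level down.
    Point j accumulates all responses at levels >= j; the origin (0, 0) is
    prepended.  All-zero tables yield the single point (0, 0).
    """
    tp = np.asarray(tp_counts, dtype=float)
    ta = np.asarray(ta_counts, dtype=float)
    if tp.shape != ta.shape or tp.ndim != 1:
        raise ValueError("count vectors must be 1-D and aligned")
    if np.any(tp < 0) or np.any(ta < 0):
        raise ValueError("counts must be non-negative")
    if tp.sum() > n_tp or ta.sum() > n_ta:
        raise ValueError("counts exceed the number of trials")
    if n_tp < 1 or n_ta < 1:
        raise ValueError("trial totals must be positive")
    h = np.concatenate([[0.0], np.cumsum(tp) / n_tp])
    f = np.concatenate([[0.0], np.cumsum(ta) / n_ta])
    if levels is None:
        levels = np.arange(tp.size, 0, -1)
    crit = np.concatenate([[np.inf], np.asarray(levels, dtype=float)])
    keep = np.ones(h.size, dtype=bool)
    keep[1:] = (np.diff(f) > 0) | (np.diff(h) > 0)
    return ROCCurve(f=f[keep], h=h[keep], criterion=crit[keep],
                    provenance={"procedure": "empirical", "n_tp": n_tp, "n_ta": n_ta})


def _pauc_xy(f: np.ndarray, h: np.ndarray, f_max: float) -> float:
    """Trapezoidal area under a monotone polyline from F = 0 to f_max.

    Assumes f is non-decreasing.  The origin is prepended; a curve ending
    short of f_max is extended horizontally at its final hit rate.
    """
    f = np.concatenate([[0.0], f])
    h = np.concatenate([[0.0], h])
    if f_max >= f[-1]:
        f = np.append(f, f_max)
        h = np.append(h, h[-1])
    else:
        j = int(np.searchsorted(f, f_max, side="right"))
        f0, f1, h0, h1 = f[j - 1], f[j], h[j - 1], h[j]
        ht = h0 if f1 == f0 else h0 + (h1 - h0) * (f_max - f0) / (f1 - f0)
        f = np.concatenate([f[:j], [f_max]])
        h = np.concatenate([h[:j], [ht]])
    return float(np.trapezoid(h, f))


def pauc(curve: ROCCurve, f_max: float) -> float:
    """Partial area under the ROC between F = 0 and F = f_max.

    Raw (unstandardized) area with linear interpolation at ``f_max``.
    Curves that never reach ``f_max`` are extended horizontally at their
    last hit rate.  Non-monotone curves are reduced to their upper envelope
    first, with a :class:`NonmonotoneROCWarning`.
    """
    if not (0 < f_max <= 1):
        raise ValueError(f"f_max must lie in (0, 1], got {f_max!r}")
    # first-ID sequential curves droop: H falls at liberal criteria even
    # though F keeps rising, so check both coordinates before integrating
    if not curve.monotone or np.any(np.diff(curve.h) < 0):
        warnings.warn(
            "ROC is not monotone (H or F decreases along the criterion "
            "ordering); integrating its upper envelope instead",
            NonmonotoneROCWarning, stacklevel=2)
        curve = curve.upper_envelope()
    return _pauc_xy(curve.f, curve.h, float(f_max))


@dataclass(frozen=True)
class PAUCResult:
    """Partial AUC with a bootstrap percentile confidence interval."""

    pauc: float
    f_max: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_tp: int
    n_ta: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pauc <= self.f_max + 1e-12):
            raise ValueError("pauc must lie in [0, f_max]")
        if self.ci_low > self.ci_high:
            raise ValueError("confidence bounds out of order")

    def to_dict(self) -> dict:
        return {"pauc": self.pauc, "f_max": self.f_max, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_boot": self.n_boot,
                "n_tp": self.n_tp, "n_ta": self.n_ta, "seed": self.seed}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _pauc_from_thresholds(tp_hit: np.ndarray, ta_pos: np.ndarray,
                          sweep: np.ndarray, divisor: float,
                          f_max: float) -> float:
    """pAUC of the threshold-form ROC evaluated on a criterion sweep."""
    cs = np.sort(sweep)[::-1]  # conservative -> liberal, so F ascends
    tp_sorted = np.sort(tp_hit)
    ta_sorted = np.sort(ta_pos)
    h = 1.0 - np.searchsorted(tp_sorted, cs, side="right") / tp_sorted.size
    f = (1.0 - np.searchsorted(ta_sorted, cs, side="right") / ta_sorted.size) / divisor
    return _pauc_xy(f, h, f_max)


def bootstrap_pauc(pool: TrialPool, f_max: float, *,
                   procedure: str = "simultaneous",
                   rule: DecisionRule | None = None,
                   ta_convention: str = "divide_by_n",
                   sweep=None, n_boot: int = 2000,
                   percentiles: tuple[float, float] = (2.5, 97.5),
                   rng=None) -> PAUCResult:
    """Percentile-bootstrap confidence interval for a procedure's pAUC.

    TP and TA trials are resampled with replacement, independently of each
    other, and the ROC and its partial area are rebuilt for each replicate;
    the interval takes the requested percentiles (95% CI by default).  The
    point estimate comes from the full, unresampled pool.
    """
    if not (0 < f_max <= 1):
        raise ValueError(f"f_max must lie in (0, 1], got {f_max!r}")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if pool.n_tp < 1 or pool.n_ta < 1:
        raise ValueError("both trial pools must be non-empty")
    rng = as_generator(rng)
    thr = response_thresholds(pool, procedure=procedure, rule=rule,
                              ta_convention=ta_convention, rng=rng)
    sweep = default_sweep(pool.model) if sweep is None else np.asarray(sweep, float)
    point = _pauc_from_thresholds(thr.tp_hit, thr.ta_positive, sweep,
                                  thr.ta_divisor, f_max)
    n_tp, n_ta = thr.tp_hit.size, thr.ta_positive.size
    reps = np.empty(n_boot)
    for b in range(n_boot):
        tp_b = thr.tp_hit[rng.integers(0, n_tp, n_tp)]
        ta_b = thr.ta_positive[rng.integers(0, n_ta, n_ta)]
        reps[b] = _pauc_from_thresholds(tp_b, ta_b, sweep, thr.ta_divisor, f_max)
    lo, hi = np.percentile(reps, percentiles)
    return PAUCResult(pauc=point, f_max=float(f_max), ci_low=float(lo),
                      ci_high=float(hi), n_boot=n_boot, n_tp=n_tp, n_ta=n_ta,
                      seed=pool.seed)


def analytic_roc_from_auc(auc: float, f_grid) -> ROCCurve:
    """Equal-variance Gaussian ROC with a prescribed full area:
    H = Phi(sqrt(2) z(AUC) + z(F)).

    ``auc`` and every grid value must lie strictly inside (0, 1).
    """
    if not (0 < auc < 1):
        raise ValueError(f"auc must lie strictly inside (0, 1), got {auc!r}")
    f = np.atleast_1d(np.asarray(f_grid, dtype=float))
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("f_grid values must lie strictly inside (0, 1)")
    f = np.sort(f)
    h = stats.norm.cdf(np.sqrt(2.0) * stats.norm.ppf(auc) + stats.norm.ppf(f))
    return ROCCurve(f=f, h=h, criterion=-stats.norm.ppf(f),
                    provenance={"procedure": "analytic_fixed_auc", "auc": auc})


@dataclass(frozen=True)
class BiasAccuracyStats:
    """Single-point accuracy and bias summaries of one (H, F) pair."""

    h: float
    f: float
    d_prime_est: float     # z(H) - z(F)
    c: float               # -0.5 (z(H) + z(F)); positive = conservative
    diagnosticity: float   # H / F; NaN when F = 0


def bias_stats(h: float, f: float, *, n: int | None = None) -> BiasAccuracyStats:
    """Compute d' = z(H) - z(F), c = -0.5 (z(H) + z(F)) and D = H / F.

    When ``n`` is given, empirical rates are clamped to
    [1/(2n), 1 - 1/(2n)] before the quantile transform — the standard
    correction that keeps c and d' finite at observed rates of 0 or 1.
    Without clamping, boundary rates yield infinite z-statistics, and F = 0
    leaves the diagnosticity ratio undefined (NaN, with a warning) rather
    than silently infinite.
    """
    if not (0 <= h <= 1 and 0 <= f <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n is not None:
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        h = float(np.clip(h, lo, hi))
        f = float(np.clip(f, lo, hi))
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    if f == 0:
        warnings.warn("diagnosticity undefined at F = 0", UserWarning, stacklevel=2)
        diag = float("nan")
    else:
        diag = h / f
    return BiasAccuracyStats(h=h, f=f, d_prime_est=float(zh - zf),
                             c=float(-0.5 * (zh + zf)), diagnosticity=diag)


def diagnosticity_bias_curves(auc_levels=(0.6, 0.7, 0.8, 0.9),
                              f_grid=None) -> pd.DataFrame:
    """Diagnosticity along fixed-AUC ROCs, as a function of F and of bias c.

    For each AUC level and each false-alarm rate on the grid (default 0.01
    to 0.99), the hit rate comes from the fixed-AUC analytic ROC and the
    table reports (auc, F, H, c, D).  Along any such curve discrimination is
    constant while D varies systematically with bias — the confounding of
    the diagnosticity ratio in tabular form.
    """
    if f_grid is None:
        f_grid = np.round(np.arange(0.01, 1.00, 0.01), 10)
    frames = []
    for auc in auc_levels:
        curve = analytic_roc_from_auc(auc, f_grid)
        stats_rows = [bias_stats(h, f) for f, h in zip(curve.f, curve.h)]
        frames.append(pd.DataFrame({
            "auc": auc,
            "F": curve.f,
            "H": curve.h,
            "c": [s.c for s in stats_rows],
            "D": [s.diagnosticity for s in stats_rows],
        }))
    return pd.concat(frames, ignore_index=True)
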