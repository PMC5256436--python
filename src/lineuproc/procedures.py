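"""Identification procedures and decision rules.

Each simulator converts a shared pool of sampled memory strengths into
response rates (suspect identification, filler identification, rejection)
at every criterion of a sweep, for both target-present and target-absent
lineups.  Supported procedures:

* showup — a single photo; identify iff its strength exceeds the criterion.
* simultaneous lineup — all photos at once, under three decision rules:
  ``absolute`` (pick the strongest photo iff it exceeds the criterion),
  ``relative_reject`` (additionally require the winner to beat the runner-up
  by at least ``delta``, else reject), and ``relative_guess`` (as before, but
  when the margin is too small guess uniformly between the two strongest).
* sequential lineup — photos one at a time, either stopping at the first
  above-criterion photo (``first_id``) or flagging every above-criterion
  photo and keeping the strongest (``any_id``).
* 2AFC — target and lure shown together; the decision variable is the
  difference of the two strengths.

Target-absent suspect false-alarm rates follow the divide-by-N convention by
default: any positive response to a TA lineup is counted, and the rate is
divided by the lineup size because each filler is equally likely to play the
innocent suspect.  A ``designated_innocent`` convention (position 0 of every
TA lineup is the innocent suspect) is available for designs with a known
innocent suspect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import (
    CriterionSet,
    EvidenceModel,
    TrialPool,
    TrialRecord,
    as_generator,
    assign_confidence,
)

__all__ = [
    "DEFAULT_DELTA",
    "DecisionRule",
    "SequentialVariant",
    "RateTable",
    "ThresholdSet",
    "default_sweep",
    "run_showup",
    "run_simultaneous",
    "run_sequential",
    "run_2afc",
    "response_thresholds",
    "shared_size_pools",
    "analytic_showup_roc_points",
    "analytic_2afc_roc_points",
    "two_afc_auc",
    "record_trial",
]

#: Default minimum winning margin for the relative rules: one tenth of the
#: reference discriminability d' = 1.5.
DEFAULT_DELTA: float = 0.15

_TA_CONVENTIONS = ("divide_by_n", "designated_innocent")


@dataclass(frozen=True)
class DecisionRule:
    """Simultaneous-lineup decision rule.

    ``delta`` is the minimum amount by which the strongest photo must exceed
    the runner-up for the relative rules; the absolute rule ignores it.
    """

    kind: str = "absolute"   # absolute | relative_reject | relative_guess
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative_reject", "relative_guess"):
            raise ValueError(f"unknown decision rule {self.kind!r}")
        if not (np.isfinite(self.delta) and self.delta >= 0):
            raise ValueError("delta must be a non-negative real")


@dataclass(frozen=True)
class SequentialVariant:
    """Sequential stopping rule: stop at the first ID, or allow later,
    stronger identifications to supersede earlier ones."""

    kind: str  # first_id | any_id

    def __post_init__(self) -> None:
        if self.kind not in ("first_id", "any_id"):
            raise ValueError(f"unknown sequential variant {self.kind!r}")


@dataclass
class RateTable:
    """Response rates per criterion for one simulated procedure.

    ``table`` columns: criterion, H, F, filler_id_rate_tp, rejection_rate_tp,
    filler_id_rate_ta, rejection_rate_ta.  Within each trial type the
    category rates sum to one at every criterion.  ``meta`` carries the
    procedure name, rule, model parameters and seed for provenance.
    """

    table: pd.DataFrame
    n_tp: int
    n_ta: int
    meta: dict = field(default_factory=dict)

    def roc(self):
        """The (F, H) operating points of this table as a ROCCurve."""
        from .roc import ROCCurve

        return ROCCurve.from_rate_table(self)

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with provenance columns merged in, ready for CSV."""
        out = self.table.copy()
        for key in ("procedure", "rule", "variant", "lineup_size", "d_prime",
                    "sigma_guilty", "ta_convention", "seed"):
            out[key] = self.meta.get(key)
        out["n_tp"] = self.n_tp
        out["n_ta"] = self.n_ta
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_sweep(model: EvidenceModel, n_points: int = 161) -> np.ndarray:
    """Evenly spaced criterion grid covering both strength distributions.

    Spans [-3, d' + 3 * max(1, sigma_guilty)] so that the most liberal
    criterion admits essentially every sample and the most conservative
    rejects essentially all of them.
    """
    hi = model.d_prime + 3.0 * max(1.0, model.sigma_guilty)
    return np.linspace(-3.0, hi, n_points)


def _criteria_array(model: EvidenceModel, criteria) -> np.ndarray:
    if criteria is None:
        return default_sweep(model)
    if isinstance(criteria, CriterionSet):
        return np.asarray(criteria.criteria, dtype=float)
    arr = np.atleast_1d(np.asarray(criteria, dtype=float))
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("criteria must be a non-empty 1-D sequence")
    return arr


def _top_two(strengths: np.ndarray):
    """Per-row strongest and second-strongest strengths and their columns."""
    n, width = strengths.shape
    rows = np.arange(n)
    i1 = np.argmax(strengths, axis=1)
    s1 = strengths[rows, i1]
    if width == 1:
        return s1, np.full(n, -np.inf), i1, np.full(n, -1)
    masked = strengths.copy()
    masked[rows, i1] = -np.inf
    i2 = np.argmax(masked, axis=1)
    s2 = masked[rows, i2]
    return s1, s2, i1, i2


def _choices(strengths: np.ndarray, rule: DecisionRule, rng):
    """Reduce each lineup to (positive-response threshold, chosen position).

    The trial produces a positive identification at criterion c iff
    ``threshold > c``; the identified position is fixed across the whole
    sweep (common random numbers), so rates are exactly monotone in c.
    """
    s1, s2, i1, i2 = _top_two(strengths)
    if rule.kind == "absolute":
        return s1, i1
    margin_ok = (s1 - s2) >= rule.delta
    if rule.kind == "relative_reject":
        return np.where(margin_ok, s1, -np.inf), i1
    # relative_guess: one uniform per trial, drawn once and reused across
    # the criterion sweep
    u = as_generator(rng).random(s1.shape[0])
    chosen = np.where(margin_ok | (u < 0.5), i1, i2)
    return s1, chosen


def _rate_table(pool: TrialPool, criteria: np.ndarray, rule: DecisionRule,
                ta_convention: str, rng, meta: dict) -> RateTable:
    if ta_convention not in _TA_CONVENTIONS:
        raise ValueError(f"unknown ta_convention {ta_convention!r}")
    n = pool.lineup_size
    tp_thr, tp_choice = _choices(pool.tp, rule, rng)
    ta_thr, ta_choice = _choices(pool.ta, rule, rng)
    tp_hit = tp_choice == pool.tp_guilty_pos

    c = criteria[None, :]
    tp_pos = tp_thr[:, None] > c
    hit = (tp_pos & tp_hit[:, None]).mean(axis=0)
    filler_tp = (tp_pos & ~tp_hit[:, None]).mean(axis=0)
    rej_tp = 1.0 - hit - filler_tp

    ta_pos = ta_thr[:, None] > c
    ta_pos_rate = ta_pos.mean(axis=0)
    if ta_convention == "divide_by_n":
        fa = ta_pos_rate / n
        filler_ta = ta_pos_rate * (n - 1) / n
    else:  # designated_innocent: position 0 of each TA lineup
        fa = (ta_pos & (ta_choice == 0)[:, None]).mean(axis=0)
        filler_ta = ta_pos_rate - fa
    rej_ta = 1.0 - ta_pos_rate

    table = pd.DataFrame({
        "criterion": criteria,
        "H": hit,
        "F": fa,
        "filler_id_rate_tp": filler_tp,
        "rejection_rate_tp": rej_tp,
        "filler_id_rate_ta": filler_ta,
        "rejection_rate_ta": rej_ta,
    })
    meta = dict(meta, rule=rule.kind, delta=rule.delta,
                ta_convention=ta_convention, lineup_size=n,
                d_prime=pool.model.d_prime, sigma_guilty=pool.model.sigma_guilty,
                seed=pool.seed)
    return RateTable(table=table, n_tp=pool.n_tp, n_ta=pool.n_ta, meta=meta)


def run_showup(model: EvidenceModel, criteria=None, n_trials: int = 10_000, *,
               rng=None, pool: TrialPool | None = None) -> RateTable:
    """Simulate the showup (single-photo) procedure across a criterion sweep.

    One strength per trial; a positive identification occurs iff the strength
    exceeds the criterion.  ``criteria`` may be a CriterionSet, an explicit
    grid, or None for the default sweep.  A prebuilt ``pool`` (lineup_size 1)
    may be supplied to share evidence with other procedures.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = as_generator(rng)
    if pool is None:
        pool = TrialPool.sample(model, 1, n_trials, n_trials, rng)
    elif pool.lineup_size != 1:
        raise ValueError("showup pools must have lineup_size 1")
    crit = _criteria_array(model, criteria)
    return _rate_table(pool, crit, DecisionRule("absolute"), "divide_by_n",
                       rng, {"procedure": "showup", "variant": None})


def run_simultaneous(model: EvidenceModel, lineup_size: int = 6, criteria=None,
                     n_trials: int = 10_000, *, rule: DecisionRule | None = None,
                     ta_convention: str = "divide_by_n", rng=None,
                     pool: TrialPool | None = None) -> RateTable:
    """Simulate a simultaneous lineup under a decision rule.

    ``lineup_size`` 1 delegates to :func:`run_showup`.  The entire sweep runs
    on one trial pool, so rates are exactly non-increasing in the criterion.
    """
    rule = rule or DecisionRule()
    if lineup_size < 1:
        raise ValueError("lineup_size must be >= 1")
    rng = as_generator(rng)
    if pool is None:
        pool = TrialPool.sample(model, lineup_size, n_trials, n_trials, rng)
    if pool.lineup_size == 1:
        return run_showup(model, criteria, n_trials, rng=rng, pool=pool)
    crit = _criteria_array(model, criteria)
    return _rate_table(pool, crit, rule, ta_convention, rng,
                       {"procedure": "simultaneous", "variant": None})


def _permute_presentation(pool: TrialPool, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomize presentation order independently for every lineup."""
    rng = as_generator(rng)
    n_tp, width = pool.tp.shape
    order_tp = np.argsort(rng.random((n_tp, width)), axis=1)
    tp = np.take_along_axis(pool.tp, order_tp, axis=1)
    gpos = np.argmax(order_tp == pool.tp_guilty_pos[:, None], axis=1)
    order_ta = np.argsort(rng.random(pool.ta.shape), axis=1)
    ta = np.take_along_axis(pool.ta, order_ta, axis=1)
    return tp, gpos, ta


def run_sequential(model: EvidenceModel, lineup_size: int = 6, criteria=None,
                   n_trials: int = 10_000, *,
                   variant: SequentialVariant | str = "first_id",
                   ta_convention: str = "divide_by_n", rng=None,
                   pool: TrialPool | None = None) -> RateTable:
    """Simulate a sequential lineup (one photo at a time, yes/no decisions).

    ``first_id``: the first above-criterion photo is identified and the trial
    ends — a single lap, so a filler appearing before the guilty suspect can
    steal the identification, which makes the hit rate non-monotone in the
    criterion.  ``any_id``: every above-criterion photo is flagged and the
    strongest flagged photo is the final choice, which reproduces the
    absolute simultaneous rule outcome trial by trial.

    Presentation order is re-randomized for every simulated lineup.
    """
    if isinstance(variant, str):
        variant = SequentialVariant(variant)
    if ta_convention not in _TA_CONVENTIONS:
        raise ValueError(f"unknown ta_convention {ta_convention!r}")
    if lineup_size < 1:
        raise ValueError("lineup_size must be >= 1")
    rng = as_generator(rng)
    if pool is None:
        pool = TrialPool.sample(model, lineup_size, n_trials, n_trials, rng)
    crit = _criteria_array(model, criteria)
    tp, gpos, ta = _permute_presentation(pool, rng)
    n = pool.lineup_size

    hit = np.empty(crit.size)
    filler_tp = np.empty(crit.size)
    ta_pos_rate = np.empty(crit.size)
    ta_first_designated = np.empty(crit.size)
    for j, c in enumerate(crit):
        above_tp = tp > c
        any_tp = above_tp.any(axis=1)
        above_ta = ta > c
        any_ta = above_ta.any(axis=1)
        if variant.kind == "first_id":
            chosen_tp = above_tp.argmax(axis=1)
            chosen_ta = above_ta.argmax(axis=1)
        else:  # any_id: strongest among all flagged photos
            chosen_tp = np.where(above_tp, tp, -np.inf).argmax(axis=1)
            chosen_ta = np.where(above_ta, ta, -np.inf).argmax(axis=1)
        is_hit = any_tp & (chosen_tp == gpos)
        hit[j] = is_hit.mean()
        filler_tp[j] = (any_tp & ~is_hit).mean()
        ta_pos_rate[j] = any_ta.mean()
        ta_first_designated[j] = (any_ta & (chosen_ta == 0)).mean()

    if ta_convention == "divide_by_n":
        fa = ta_pos_rate / n
        filler_ta = ta_pos_rate * (n - 1) / n
    else:
        fa = ta_first_designated
        filler_ta = ta_pos_rate - fa

    table = pd.DataFrame({
        "criterion": crit,
        "H": hit,
        "F": fa,
        "filler_id_rate_tp": filler_tp,
        "rejection_rate_tp": 1.0 - hit - filler_tp,
        "filler_id_rate_ta": filler_ta,
        "rejection_rate_ta": 1.0 - ta_pos_rate,
    })
    meta = {"procedure": "sequential", "variant": variant.kind, "rule": None,
            "ta_convention": ta_convention, "lineup_size": n,
            "d_prime": pool.model.d_prime, "sigma_guilty": pool.model.sigma_guilty,
            "seed": pool.seed}
    return RateTable(table=table, n_tp=pool.n_tp, n_ta=pool.n_ta, meta=meta)


# ---------------------------------------------------------------------------
# Two-alternative forced choice
# ---------------------------------------------------------------------------

def _difference_sd(model: EvidenceModel) -> float:
    return math.hypot(1.0, model.sigma_guilty)


def run_2afc(model: EvidenceModel, criteria=None, n_trials: int = 10_000, *,
             rng=None) -> RateTable:
    """Simulate a 2AFC task: target and lure shown together.

    The decision variable on each trial is the difference between the target
    and lure strengths, distributed N(d', sqrt(1 + sigma_guilty^2)).  The
    rating ROC sweeps a criterion on the difference; the mirrored class
    (target in the other position) supplies the false-alarm axis.  The
    returned ``meta['auc_estimate']`` is the empirical probability that the
    target beats the lure, which by the area theorem estimates the full area
    under the underlying guilty-vs-innocent ROC,
    Phi(d' / sqrt(1 + sigma_guilty^2)).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = as_generator(rng)
    diff = model.sample_guilty(n_trials, rng) - model.sample_filler(n_trials, rng)
    sd = _difference_sd(model)
    if criteria is None:
        span = model.d_prime + 3.0 * sd
        crit = np.linspace(-span, span, 161)
    else:
        crit = _criteria_array(model, criteria)
    c = crit[None, :]
    hit = (diff[:, None] > c).mean(axis=0)
    fa = ((-diff)[:, None] > c).mean(axis=0)
    table = pd.DataFrame({
        "criterion": crit,
        "H": hit,
        "F": fa,
        "filler_id_rate_tp": np.zeros_like(hit),
        "rejection_rate_tp": 1.0 - hit,
        "filler_id_rate_ta": np.zeros_like(fa),
        "rejection_rate_ta": 1.0 - fa,
    })
    meta = {"procedure": "2afc", "rule": None, "variant": None,
            "ta_convention": None, "lineup_size": 2,
            "d_prime": model.d_prime, "sigma_guilty": model.sigma_guilty,
            "seed": None, "auc_estimate": float((diff > 0).mean())}
    return RateTable(table=table, n_tp=n_trials, n_ta=n_trials, meta=meta)


def two_afc_auc(model: EvidenceModel) -> float:
    """Analytic 2AFC accuracy: P(target draw > lure draw) =
    Phi(d' / sqrt(1 + sigma_guilty^2)).  By the area theorem this equals the
    full area under the guilty-vs-innocent yes/no ROC."""
    return float(stats.norm.cdf(model.d_prime / _difference_sd(model)))


def analytic_2afc_roc_points(model: EvidenceModel, f_grid) -> pd.DataFrame:
    """Closed-form rating ROC implied by the difference distribution:
    H = Phi(z(F) + 2 d' / sqrt(1 + sigma_guilty^2))."""
    f = np.asarray(f_grid, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("f_grid values must lie strictly inside (0, 1)")
    shift = 2.0 * model.d_prime / _difference_sd(model)
    return pd.DataFrame({"F": f, "H": stats.norm.cdf(stats.norm.ppf(f) + shift)})


def analytic_showup_roc_points(model: EvidenceModel, f_grid) -> pd.DataFrame:
    """Closed-form showup ROC: H = Phi((d' + z(F)) / sigma_guilty); with
    equal variance this is H = Phi(z(F) + d')."""
    f = np.asarray(f_grid, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("f_grid values must lie strictly inside (0, 1)")
    h = stats.norm.cdf((model.d_prime + stats.norm.ppf(f)) / model.sigma_guilty)
    return pd.DataFrame({"F": f, "H": h})


# ---------------------------------------------------------------------------
# Threshold reduction (for the pAUC bootstrap) and shared pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Per-trial step thresholds of a procedure whose response is a step
    function of the criterion.

    ``tp_hit[i] > c`` iff TP trial i yields a correct suspect identification
    at criterion c (``-inf`` when the trial can never be a hit).
    ``ta_positive[i] > c`` iff TA trial i yields the counted positive
    response; the resulting rate is divided by ``ta_divisor``.
    """

    tp_hit: np.ndarray
    ta_positive: np.ndarray
    ta_divisor: float


def response_thresholds(pool: TrialPool, *, procedure: str = "simultaneous",
                        rule: DecisionRule | None = None,
                        ta_convention: str = "divide_by_n",
                        rng=None) -> ThresholdSet:
    """Reduce a pool + procedure to per-trial response thresholds.

    Valid for the showup, the simultaneous lineup under any rule, and the
    any-ID sequential lineup (whose outcome matches the absolute rule).  The
    first-ID sequential procedure is refused: its hit indicator is not a step
    function of the criterion, so its folding ROC has no threshold form.
    """
    if procedure == "sequential_first_id":
        raise ValueError(
            "first-ID sequential responses are not monotone in the criterion; "
            "no per-trial threshold exists (use run_sequential directly)")
    if procedure not in ("showup", "simultaneous", "sequential_any_id"):
        raise ValueError(f"unknown procedure {procedure!r}")
    if ta_convention not in _TA_CONVENTIONS:
        raise ValueError(f"unknown ta_convention {ta_convention!r}")
    rule = rule or DecisionRule()
    if procedure in ("showup", "sequential_any_id"):
        rule = DecisionRule("absolute")
    tp_thr, tp_choice = _choices(pool.tp, rule, rng)
    ta_thr, ta_choice = _choices(pool.ta, rule, rng)
    tp_hit = np.where(tp_choice == pool.tp_guilty_pos, tp_thr, -np.inf)
    if ta_convention == "divide_by_n":
        return ThresholdSet(tp_hit, ta_thr, float(pool.lineup_size))
    ta_pos = np.where(ta_choice == 0, ta_thr, -np.inf)
    return ThresholdSet(tp_hit, ta_pos, 1.0)


def shared_size_pools(model: EvidenceModel, sizes, n_tp: int, n_ta: int,
                      rng=None) -> dict[int, TrialPool]:
    """Nested trial pools for comparing lineup sizes on common random numbers.

    The size-N pool reuses the same guilty draw and the first N - 1 (TP) or
    N (TA) filler draws of the largest pool, so size effects are evaluated on
    the very same evidence values.  The guilty sample's position is shuffled
    independently within each pool.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if sizes[0] < 1:
        raise ValueError("lineup sizes must be >= 1")
    rng = as_generator(rng)
    n_max = sizes[-1]
    guilty = model.sample_guilty(n_tp, rng)
    tp_fillers = model.sample_filler((n_tp, max(n_max - 1, 1)), rng)
    ta = model.sample_filler((n_ta, n_max), rng)
    pools: dict[int, TrialPool] = {}
    for n in sizes:
        tp = np.column_stack([guilty, tp_fillers[:, : n - 1]])
        order = np.argsort(rng.random((n_tp, n)), axis=1)
        tp = np.take_along_axis(tp, order, axis=1)
        gpos = np.argmax(order == 0, axis=1)
        pools[n] = TrialPool(model=model, lineup_size=n, tp=tp,
                             tp_guilty_pos=gpos, ta=ta[:, :n].copy())
    return pools


def record_trial(trial_type: str, strengths, guilty_position,
                 criteria: CriterionSet, rule: DecisionRule | None = None,
                 lineup_size: int | None = None, rng=None) -> TrialRecord:
    """Classify one sampled lineup into a :class:`TrialRecord`.

    The identification decision uses the lowest criterion of ``criteria`` as
    the positive-response threshold; confidence comes from binning the chosen
    strength on the full ladder.  Relative rules can reject a lineup whose
    strongest photo is above the lowest criterion; such trials are recorded
    as rejections with confidence 0.
    """
    rule = rule or DecisionRule()
    s = np.asarray(strengths, dtype=float).reshape(1, -1)
    n = s.shape[1]
    if lineup_size is not None and lineup_size != n:
        raise ValueError("lineup_size does not match strengths")
    thr, choice = _choices(s, rule, rng)
    positive = thr[0] > criteria.criteria[0]
    if not positive:
        response, confidence, chosen = "rejection", 0, None
    else:
        chosen = int(choice[0])
        if trial_type == "TP" and chosen == guilty_position:
            response = "suspect_id"
        else:
            response = "filler_id"
        confidence = int(assign_confidence(float(s[0, chosen]), criteria))
        if confidence == 0:
            # relative_guess can pick a runner-up that sits below c_1; treat
            # the outcome as a rejection so confidence stays consistent
            response, confidence, chosen = "rejection", 0, None
    return TrialRecord(trial_type=trial_type, lineup_size=n,
                       strengths=tuple(float(x) for x in s[0]),
                       guilty_position=guilty_position if trial_type == "TP" else None,
                       response=response, confidence=confidence,
                       chosen_position=chosen)
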