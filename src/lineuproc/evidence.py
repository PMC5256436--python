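"""Gaussian evidence model, confidence criteria, and trial sampling.

The world model is classic signal detection theory applied to eyewitness
identification: the memory-match signal elicited by the guilty suspect is a
draw from ``N(d', sigma_guilty)``, while fillers and innocent suspects draw
from the standard normal ``N(0, 1)``.  A target-present (TP) lineup of size N
holds one guilty draw (at a uniformly random position) and N - 1 filler
draws; a target-absent (TA) lineup holds N filler draws.  Confidence in a
positive identification is obtained by locating the chosen strength on a
fixed ladder of decision criteria.

Everything downstream (decision rules, ROC curves, Bayesian measures) is
built on the samples produced here, so this module is deliberately small and
heavily validated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LAMPINEN_CRITERIA",
    "FILLER_MEAN",
    "FILLER_SD",
    "EvidenceModel",
    "CriterionSet",
    "TrialRecord",
    "TrialPool",
    "assign_confidence",
    "sample_trial",
    "as_generator",
]

#: The fixed seven-criterion confidence ladder used in the published
#: showup/six-person-lineup replication.
LAMPINEN_CRITERIA: tuple[float, ...] = (0.18, 0.23, 0.27, 0.39, 0.67, 1.15, 1.53)

#: Filler / innocent-suspect strength distribution parameters (immutable).
FILLER_MEAN: float = 0.0
FILLER_SD: float = 1.0


def as_generator(rng) -> np.random.Generator:
    """Coerce ``rng`` (Generator, int seed, or None) into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class EvidenceModel:
    """Parameters of the Gaussian strength distributions.

    Parameters
    ----------
    d_prime:
        Mean of the guilty-suspect distribution, in SD units of the filler
        distribution.  The true discriminability of guilty from innocent.
    sigma_guilty:
        Standard deviation of the guilty-suspect distribution; 1 for
        equal-variance models, 1.2 for the standard unequal-variance case.

    The filler distribution is fixed at ``N(0, 1)`` and is not a parameter.
    """

    d_prime: float
    sigma_guilty: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_prime):
            raise ValueError(f"d_prime must be finite, got {self.d_prime!r}")
        if not (np.isfinite(self.sigma_guilty) and self.sigma_guilty > 0):
            raise ValueError(
                f"sigma_guilty must be a positive finite real, got {self.sigma_guilty!r}"
            )

    # -- sampling ---------------------------------------------------------
    def sample_guilty(self, size, rng) -> np.ndarray:
        """Draw guilty-suspect strengths from N(d', sigma_guilty)."""
        return as_generator(rng).normal(self.d_prime, self.sigma_guilty, size)

    def sample_filler(self, size, rng) -> np.ndarray:
        """Draw filler / innocent-suspect strengths from N(0, 1)."""
        return as_generator(rng).normal(FILLER_MEAN, FILLER_SD, size)

    # -- closed forms for the one-photo (showup) task ---------------------
    def showup_hit_rate(self, criterion) -> np.ndarray | float:
        """P(guilty strength > c) = Phi((d' - c) / sigma_guilty)."""
        return stats.norm.sf(np.asarray(criterion, dtype=float),
                             loc=self.d_prime, scale=self.sigma_guilty)

    def showup_false_alarm_rate(self, criterion) -> np.ndarray | float:
        """P(filler strength > c) = Phi(-c)."""
        return stats.norm.sf(np.asarray(criterion, dtype=float),
                             loc=FILLER_MEAN, scale=FILLER_SD)


@dataclass(frozen=True)
class CriterionSet:
    """A strictly increasing ladder of decision criteria c_1 < ... < c_k.

    Confidence levels are integers 0..k.  Level 0 means the strength did not
    exceed the lowest criterion (no identification); any level >= 1 is a
    positive identification.  See :func:`assign_confidence` for the exact
    level assignment.
    """

    criteria: tuple[float, ...]

    def __post_init__(self) -> None:
        crit = tuple(float(c) for c in self.criteria)
        if len(crit) < 1:
            raise ValueError("CriterionSet needs at least one criterion")
        if not all(np.isfinite(crit)):
            raise ValueError("criteria must be finite")
        if any(b <= a for a, b in zip(crit, crit[1:])):
            raise ValueError(f"criteria must be strictly increasing, got {crit}")
        object.__setattr__(self, "criteria", crit)

    @property
    def k(self) -> int:
        """Number of criteria (= the maximum confidence level)."""
        return len(self.criteria)

    @classmethod
    def lampinen(cls) -> "CriterionSet":
        """The fixed seven-criterion set from the published simulations."""
        return cls(LAMPINEN_CRITERIA)

    def assign(self, strength):
        return assign_confidence(strength, self)

    def __iter__(self):
        return iter(self.criteria)

    def __len__(self) -> int:
        return self.k


def assign_confidence(strength, criteria):
    """Map a memory strength to a confidence level 0..k.

    A strength at or below the lowest criterion c_1 yields level 0 (no
    identification).  Otherwise the level is the 1-based index of the lowest
    criterion at or above the strength, capped at k for strengths beyond the
    highest criterion.  With the standard seven-criterion ladder a strength
    of 1.0 sits between the fifth and sixth criteria (0.67 and 1.15) and is
    assigned confidence 6; strengths above 1.53 are assigned 7.  Note that
    level 1 is unreachable under this labelling: the whole region at or
    below c_1 is the no-identification level 0.

    Ties (strength exactly equal to a criterion) classify downward, so the
    mapping is total on the reals and non-decreasing in strength.

    Parameters
    ----------
    strength:
        Scalar or array of memory strengths.
    criteria:
        A :class:`CriterionSet` or any strictly increasing sequence.
    """
    cs = criteria if isinstance(criteria, CriterionSet) else CriterionSet(tuple(criteria))
    crit = np.asarray(cs.criteria, dtype=float)
    arr = np.asarray(strength, dtype=float)
    exceeded = np.searchsorted(crit, arr, side="left")  # #{j : c_j < s}
    level = np.where(exceeded == 0, 0, np.minimum(exceeded + 1, cs.k))
    if np.ndim(strength) == 0:
        return int(level)
    return level.astype(int)


def sample_trial(model: EvidenceModel, trial_type: str, lineup_size: int, rng):
    """Sample the strengths for one identification trial.

    Returns ``(strengths, guilty_position)`` where ``strengths`` is a float
    array of length ``lineup_size``.  For a TP trial exactly one entry, at a
    uniformly random position, is drawn from the guilty distribution and the
    rest from N(0, 1); ``guilty_position`` is its index.  For a TA trial all
    entries are fillers and ``guilty_position`` is None.
    """
    if trial_type not in ("TP", "TA"):
        raise ValueError(f"trial_type must be 'TP' or 'TA', got {trial_type!r}")
    if not (isinstance(lineup_size, (int, np.integer)) and lineup_size >= 1):
        raise ValueError(f"lineup_size must be a positive integer, got {lineup_size!r}")
    rng = as_generator(rng)
    strengths = model.sample_filler(lineup_size, rng)
    if trial_type == "TA":
        return strengths, None
    pos = int(rng.integers(lineup_size))
    strengths[pos] = model.sample_guilty((), rng)
    return strengths, pos


@dataclass(frozen=True)
class TrialRecord:
    """One simulated identification trial, after a decision rule has run."""

    trial_type: str                # "TP" | "TA"
    lineup_size: int
    strengths: tuple[float, ...]
    guilty_position: int | None    # defined iff trial_type == "TP"
    response: str                  # "suspect_id" | "filler_id" | "rejection"
    confidence: int                # 0..k; 0 iff rejection
    chosen_position: int | None    # defined iff response != "rejection"

    def __post_init__(self) -> None:
        if self.trial_type not in ("TP", "TA"):
            raise ValueError(f"invalid trial_type {self.trial_type!r}")
        if len(self.strengths) != self.lineup_size:
            raise ValueError("strengths length must equal lineup_size")
        if (self.trial_type == "TP") != (self.guilty_position is not None):
            raise ValueError("guilty_position is defined iff the trial is TP")
        if self.response not in ("suspect_id", "filler_id", "rejection"):
            raise ValueError(f"invalid response {self.response!r}")
        if (self.response == "rejection") != (self.confidence == 0):
            raise ValueError("rejection <=> confidence 0")
        if (self.response == "rejection") != (self.chosen_position is None):
            raise ValueError("chosen_position is defined iff a photo was identified")


@dataclass
class TrialPool:
    """A reusable pool of sampled trials (common random numbers).

    The entire criterion sweep of every procedure runs on one fixed pool, so
    operating points along an ROC differ only in the criterion, never in the
    evidence — the same convention the published simulations use.
    """

    model: EvidenceModel
    lineup_size: int
    tp: np.ndarray              # (n_tp, N) strengths of target-present trials
    tp_guilty_pos: np.ndarray   # (n_tp,) position of the guilty sample
    ta: np.ndarray              # (n_ta, N) strengths of target-absent trials
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp, dtype=float)
        self.ta = np.asarray(self.ta, dtype=float)
        self.tp_guilty_pos = np.asarray(self.tp_guilty_pos, dtype=np.int64)
        if self.tp.ndim != 2 or self.ta.ndim != 2:
            raise ValueError("tp and ta must be 2-D (trials x positions)")
        if self.tp.shape[1] != self.lineup_size or self.ta.shape[1] != self.lineup_size:
            raise ValueError("strength arrays must have lineup_size columns")
        if self.tp_guilty_pos.shape != (self.tp.shape[0],):
            raise ValueError("tp_guilty_pos must have one entry per TP trial")
        if self.tp.shape[0] and not (
            (self.tp_guilty_pos >= 0).all() and (self.tp_guilty_pos < self.lineup_size).all()
        ):
            raise ValueError("guilty positions out of range")

    @property
    def n_tp(self) -> int:
        return self.tp.shape[0]

    @property
    def n_ta(self) -> int:
        return self.ta.shape[0]

    @classmethod
    def sample(cls, model: EvidenceModel, lineup_size: int, n_tp: int, n_ta: int,
               rng=None) -> "TrialPool":
        """Sample a fresh pool of n_tp TP and n_ta TA lineups of a given size."""
        if lineup_size < 1:
            raise ValueError("lineup_size must be >= 1")
        if n_tp < 1 or n_ta < 1:
            raise ValueError("need at least one trial of each type")
        seed = rng if isinstance(rng, (int, np.integer)) else None
        rng = as_generator(rng)
        tp = model.sample_filler((n_tp, lineup_size), rng)
        gpos = rng.integers(lineup_size, size=n_tp)
        tp[np.arange(n_tp), gpos] = model.sample_guilty(n_tp, rng)
        ta = model.sample_filler((n_ta, lineup_size), rng)
        return cls(model=model, lineup_size=lineup_size, tp=tp,
                   tp_guilty_pos=gpos, ta=ta,
                   seed=int(seed) if seed is not None else None)

    # -- long-format CSV interchange --------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per photo position per trial."""
        n_tp, n = self.tp.shape
        n_ta = self.ta.shape[0]
        tp_ids = np.repeat(np.arange(n_tp), n)
        tp_pos = np.tile(np.arange(n), n_tp)
        ta_ids = np.repeat(np.arange(n_ta), n)
        ta_pos = np.tile(np.arange(n), n_ta)
        frame = pd.DataFrame({
            "trial_id": np.concatenate([tp_ids, ta_ids]),
            "trial_type": ["TP"] * (n_tp * n) + ["TA"] * (n_ta * n),
            "lineup_size": n,
            "position": np.concatenate([tp_pos, ta_pos]),
            "strength": np.concatenate([self.tp.ravel(), self.ta.ravel()]),
            "is_guilty": np.concatenate([
                tp_pos == np.repeat(self.tp_guilty_pos, n),
                np.zeros(n_ta * n, dtype=bool),
            ]),
        })
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, model: EvidenceModel, frame: pd.DataFrame) -> "TrialPool":
        n = int(frame["lineup_size"].iloc[0])
        tp_rows = frame[frame["trial_type"] == "TP"].sort_values(["trial_id", "position"])
        ta_rows = frame[frame["trial_type"] == "TA"].sort_values(["trial_id", "position"])
        tp = tp_rows["strength"].to_numpy().reshape(-1, n)
        ta = ta_rows["strength"].to_numpy().reshape(-1, n)
        guilty = tp_rows[tp_rows["is_guilty"]]
        gpos = guilty.sort_values("trial_id")["position"].to_numpy()
        return cls(model=model, lineup_size=n, tp=tp, tp_guilty_pos=gpos, ta=ta)

    @classmethod
    def from_csv(cls, model: EvidenceModel, path) -> "TrialPool":
        return cls.from_frame(model, pd.read_csv(path))
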