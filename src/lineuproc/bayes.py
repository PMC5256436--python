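"""Posterior probability of guilt and information-gain curves.

Given a base rate b (the prior probability that the lineup contains the
guilty suspect) and the hit and false-alarm rates of a procedure, Bayes'
rule gives the posterior probability of guilt after a suspect
identification,

    P(guilty | id) = b H / (b H + (1 - b) F),

and after a negative outcome (filler identification or lineup rejection,
merged),

    P(guilty | no id) = b (1 - H) / (b (1 - H) + (1 - b) (1 - F)).

Information gain is the posterior minus the base rate.  Because H and F
depend on both discriminability and criterion placement, these curves mix
discrimination, response bias, and the base rate: a low-d' witness with a
conservative criterion can out-gain a high-d' witness with a liberal one,
which is why information gain cannot stand in for a bias-free accuracy
measure.

Criterion placement here is parameterized as an offset k from the guilty
distribution's mean, in guilty-SD units: the criterion sits at
c = d' + k * sigma_guilty, so H = Phi(-k) and F = Phi(-c) under the
one-photo (showup-style) equal-variance closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import EvidenceModel

__all__ = [
    "BayesCurve",
    "posterior_guilt",
    "rates_at_criterion_offset",
    "information_gain_curve",
]


def posterior_guilt(base_rate, hit_rate, false_alarm_rate, response: str = "id"):
    """Posterior probability of guilt after an identification outcome.

    ``response`` is ``"id"`` for a suspect identification and ``"no_id"``
    for a filler identification or lineup rejection.  Vectorized over any
    argument; a 0/0 posterior (e.g. H = F = 0 after an identification)
    returns the prior unchanged.
    """
    if response not in ("id", "no_id"):
        raise ValueError(f"response must be 'id' or 'no_id', got {response!r}")
    b = np.asarray(base_rate, dtype=float)
    h = np.asarray(hit_rate, dtype=float)
    f = np.asarray(false_alarm_rate, dtype=float)
    for name, arr in (("base_rate", b), ("hit_rate", h), ("false_alarm_rate", f)):
        if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must lie in [0, 1]")
    if response == "id":
        num = b * h
        den = num + (1.0 - b) * f
    else:
        num = b * (1.0 - h)
        den = num + (1.0 - b) * (1.0 - f)
    with np.errstate(invalid="ignore"):
        post = np.where(den > 0, num / np.where(den > 0, den, 1.0), b)
    if post.ndim == 0:
        return float(post)
    return post


def rates_at_criterion_offset(model: EvidenceModel, offset: float):
    """(H, F, c) for a criterion k guilty-SDs above the guilty mean.

    c = d' + k * sigma_guilty; H = Phi(-k); F = Phi(-c).  Negative offsets
    place the criterion below the guilty mean (more liberal responding).
    """
    c = model.d_prime + float(offset) * model.sigma_guilty
    h = float(model.showup_hit_rate(c))
    f = float(model.showup_false_alarm_rate(c))
    return h, f, c


@dataclass
class BayesCurve:
    """Posterior-of-guilt and information-gain curves over a base-rate grid."""

    base_rate: np.ndarray
    posterior_id: np.ndarray
    posterior_no_id: np.ndarray
    gain_id: np.ndarray
    gain_no_id: np.ndarray
    d_prime: float
    offset: float
    hit_rate: float
    false_alarm_rate: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "base_rate": self.base_rate,
            "posterior_id": self.posterior_id,
            "posterior_no_id": self.posterior_no_id,
            "gain_id": self.gain_id,
            "gain_no_id": self.gain_no_id,
            "d_prime": self.d_prime,
            "offset": self.offset,
            "hit_rate": self.hit_rate,
            "false_alarm_rate": self.false_alarm_rate,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def information_gain_curve(model: EvidenceModel, offset: float = 0.0,
                           base_rates=None) -> BayesCurve:
    """Posterior and information-gain curves for one (d', bias) condition.

    The criterion sits ``offset`` guilty-SDs above the guilty mean (see
    :func:`rates_at_criterion_offset`); posteriors are evaluated across the
    base-rate grid (default 0..1 in steps of 0.01) for both a suspect
    identification and a negative outcome.  Gains are pinned to zero at base
    rates 0 and 1, where the evidence cannot move the prior.
    """
    if base_rates is None:
        base_rates = np.linspace(0.0, 1.0, 101)
    b = np.asarray(base_rates, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("base rates must lie in [0, 1]")
    h, f, c = rates_at_criterion_offset(model, offset)
    post_id = posterior_guilt(b, h, f, "id")
    post_no = posterior_guilt(b, h, f, "no_id")
    return BayesCurve(
        base_rate=b,
        posterior_id=np.asarray(post_id),
        posterior_no_id=np.asarray(post_no),
        gain_id=np.asarray(post_id) - b,
        gain_no_id=np.asarray(post_no) - b,
        d_prime=model.d_prime,
        offset=float(offset),
        hit_rate=h,
        false_alarm_rate=f,
        meta={"criterion": c, "sigma_guilty": model.sigma_guilty},
    )
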