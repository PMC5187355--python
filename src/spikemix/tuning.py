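"""Periodic Gaussian direction tuning and condition-dependent firing rates.

A direction-selective neuron's mean firing rate to a moving random-dot
pattern is modelled by a Gaussian bump over direction, made periodic by
wrapping the angular deviation from the preferred direction ``D`` into
``[-pi, pi)``:

    f(d | A, sigma, r0) = A * exp(-||d - D||_2pi^2 / (2 sigma^2)) + r0

with amplitude ``A`` (directional gain, spikes/s), tuning width ``sigma``
(radians), and spontaneous rate ``r0`` (spikes/s).  The preferred direction
is fixed to ``D = 0``: stimulus directions are measured as deviations from
the preferred direction, which was established in a separate mapping
session.

Two stimuli (apertures 1 and 2) have their own ``(A_l, sigma_l)`` but share
``r0``.  In the bidirectional attention conditions the two competing models
differ in how the two single-stimulus rates combine:

* probability-mixing -- on each trial the neuron responds to exactly one
  stimulus; stimulus 1 is chosen with probability ``p_c``;
* response-averaging -- the rate is the convex combination
  ``p_c * r1 + (1 - p_c) * r2`` on every trial.

Under attention toward aperture 1 (``attend-in``) the amplitudes are scaled
by attentional gains ``a_l``.  In the averaging model only the products
``b1 = p * a1`` and ``b2 = (1 - p) * a2`` are identifiable, which is why
that model has one parameter fewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TWO_PI = 2.0 * np.pi

#: Experimental conditions: unidirectional (one pattern in the receptive
#: field) and bidirectional (two patterns, attention on fixation spot or on
#: the aperture-1 pattern).
CONDITIONS = ("fix1", "fix2", "attend-fix", "attend-in")
UNIDIRECTIONAL = ("fix1", "fix2")
BIDIRECTIONAL = ("attend-fix", "attend-in")

#: Aperture-2 motion direction relative to aperture 1: 120 degrees
#: clockwise, encoded as -2*pi/3 (configurable in ExperimentDesign).
APERTURE2_OFFSET = -TWO_PI / 3.0


def wrap_angle(d, D: float = 0.0):
    """Wrap the angular deviation ``d - D`` into ``[-pi, pi)``.

    Implements ``||d - D||_2pi = mod(d - D + pi, 2 pi) - pi``, which makes
    the tuning curve periodic and symmetric around the preferred direction.
    """
    return np.mod(np.asarray(d) - D + np.pi, TWO_PI) - np.pi


def gauss_factor(d, sigma: float, D: float = 0.0):
    """Unit-amplitude periodic Gaussian factor ``exp(-||d-D||^2 / 2 sigma^2)``."""
    z = wrap_angle(d, D)
    return np.exp(-(z * z) / (2.0 * sigma * sigma))


def tuning_rate(d, A: float, sigma: float, r0: float, D: float = 0.0):
    """Firing rate (spikes/s) to a single stimulus moving in direction ``d``."""
    return A * gauss_factor(d, sigma, D) + r0


@dataclass(frozen=True)
class TuningParams:
    """Tuning-curve parameters for the two apertures (shared r0, D fixed 0)."""

    A1: float
    sigma1: float
    A2: float
    sigma2: float
    r0: float
    D: float = 0.0

    def __post_init__(self):
        if not (self.A1 > 0 and self.A2 > 0):
            raise ValueError("amplitudes A1, A2 must be > 0")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("tuning widths sigma1, sigma2 must be > 0")
        if self.r0 < 0:
            raise ValueError("spontaneous rate r0 must be >= 0")

    def rate(self, aperture: int, d, gain: float = 1.0):
        """Rate of stimulus ``aperture`` (1 or 2) with amplitude gain applied."""
        if aperture == 1:
            return tuning_rate(d, gain * self.A1, self.sigma1, self.r0, self.D)
        elif aperture == 2:
            return tuning_rate(d, gain * self.A2, self.sigma2, self.r0, self.D)
        raise ValueError(f"aperture must be 1 or 2, got {aperture}")


@dataclass(frozen=True)
class AttentionParams:
    """Stimulus weights and attentional gains.

    The mixing model uses ``(p_attend_fix, p_attend_in, a1, a2)``; the
    averaging model uses ``(p_attend_fix, b1, b2)`` with the correspondence
    ``b1 = p_attend_in * a1`` and ``b2 = (1 - p_attend_in) * a2``.  The
    attentional gains equal 1 outside the attend-in condition.
    """

    p_attend_fix: float
    p_attend_in: Optional[float] = None
    a1: Optional[float] = None
    a2: Optional[float] = None
    b1: Optional[float] = None
    b2: Optional[float] = None

    def __post_init__(self):
        for name in ("p_attend_fix", "p_attend_in"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("a1", "a2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"attentional gain {name} must be > 0")
        for name in ("b1", "b2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"composite gain {name} must be >= 0")

    @classmethod
    def for_mixing(cls, p_attend_fix, p_attend_in, a1, a2) -> "AttentionParams":
        return cls(p_attend_fix=p_attend_fix, p_attend_in=p_attend_in, a1=a1, a2=a2)

    @classmethod
    def for_averaging(cls, p_attend_fix, b1, b2) -> "AttentionParams":
        return cls(p_attend_fix=p_attend_fix, b1=b1, b2=b2)

    def as_averaging(self) -> "AttentionParams":
        """Map mixing parameters to the identifiable averaging pair (b1, b2)."""
        if self.b1 is not None and self.b2 is not None:
            return self
        if self.p_attend_in is None or self.a1 is None or self.a2 is None:
            raise ValueError("need (p_attend_in, a1, a2) to derive (b1, b2)")
        return AttentionParams(
            p_attend_fix=self.p_attend_fix,
            b1=self.p_attend_in * self.a1,
            b2=(1.0 - self.p_attend_in) * self.a2,
        )


@dataclass(frozen=True)
class ConditionRates:
    """Firing-rate prediction for one condition x direction configuration.

    ``components`` holds one rate for unidirectional conditions and for the
    averaging model in bidirectional conditions (already averaged), or the
    two single-stimulus rates ``(r1, r2)`` for the mixing model in
    bidirectional conditions, in which case ``p`` is the probability that
    the neuron responds to stimulus 1.
    """

    components: tuple
    p: Optional[float] = None

    @property
    def is_mixture(self) -> bool:
        return self.p is not None and len(self.components) == 2

    def mean_rate(self) -> float:
        """Trial-averaged expected rate (what a PSTH would estimate)."""
        if self.is_mixture:
            r1, r2 = self.components
            return self.p * r1 + (1.0 - self.p) * r2
        return self.components[0]


def direction_angles(direction_index: int, aperture2_offset: float = APERTURE2_OFFSET):
    """Aperture-1 and aperture-2 motion directions (rad) for configuration k.

    Configuration ``k`` in 1..12 sets aperture 1 to ``(k-1) * pi/6``;
    aperture 2 always moves 120 degrees clockwise of aperture 1.
    """
    if not 1 <= direction_index <= 12:
        raise ValueError(f"direction_index must be in 1..12, got {direction_index}")
    d1 = (direction_index - 1) * np.pi / 6.0
    d2 = np.mod(d1 + aperture2_offset, TWO_PI)
    return d1, d2


def condition_rates(
    condition: str,
    direction_index: int,
    tuning: TuningParams,
    attn: AttentionParams,
    model: str,
    aperture2_offset: float = APERTURE2_OFFSET,
) -> ConditionRates:
    """Predicted firing rate(s) for one condition and direction configuration.

    Unidirectional conditions return the single-stimulus rate (identical
    under both models).  Bidirectional conditions return either mixture
    components with their mixing probability (``model="mixing"``) or the
    weighted-average rate (``model="averaging"``).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if model not in ("mixing", "averaging"):
        raise ValueError(f"model must be 'mixing' or 'averaging', got {model!r}")
    d1, d2 = direction_angles(direction_index, aperture2_offset)

    if condition == "fix1":
        return ConditionRates((float(tuning.rate(1, d1)),))
    if condition == "fix2":
        return ConditionRates((float(tuning.rate(2, d2)),))

    p = attn.p_attend_fix
    if condition == "attend-fix":
        r1 = float(tuning.rate(1, d1))
        r2 = float(tuning.rate(2, d2))
        if model == "mixing":
            return ConditionRates((r1, r2), p=p)
        return ConditionRates((p * r1 + (1.0 - p) * r2,))

    # attend-in
    if model == "mixing":
        if attn.p_attend_in is None or attn.a1 is None or attn.a2 is None:
            raise ValueError("mixing model needs (p_attend_in, a1, a2) for attend-in")
        r1 = float(tuning.rate(1, d1, gain=attn.a1))
        r2 = float(tuning.rate(2, d2, gain=attn.a2))
        return ConditionRates((r1, r2), p=attn.p_attend_in)
    a = attn if (attn.b1 is not None and attn.b2 is not None) else attn.as_averaging()
    r = (
        a.b1 * tuning.A1 * float(gauss_factor(d1, tuning.sigma1, tuning.D))
        + a.b2 * tuning.A2 * float(gauss_factor(d2, tuning.sigma2, tuning.D))
        + tuning.r0
    )
    return ConditionRates((float(r),))
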