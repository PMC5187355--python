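"""Synthetic-data generator emulating the two-stimulus attention experiment.

The emulated design: single MT neurons probed with moving random-dot
patterns in two apertures inside the receptive field, under four
conditions -- two unidirectional (``fix1``, ``fix2``: one pattern, monkey
attends the fixation spot) and two bidirectional (``attend-fix``: both
patterns present, attention at fixation; ``attend-in``: both present,
attention on the aperture-1 pattern).  Twelve direction configurations
step aperture-1 motion around the circle in 30 degree increments with
aperture 2 always 120 degrees clockwise of aperture 1.  Spikes are
analysed in windows of at most 500 ms at 1 ms resolution.

Trains are sampled bin by bin as Bernoulli events with probability
``clamp(lambda dt, 0, 1 - 1e-12)``, with emitted spikes fed back into the
spike-history term, exactly matching the discrete likelihood that is later
fitted.  Under the mixing model each bidirectional trial first draws which
stimulus the neuron responds to (probability ``p_c`` for stimulus 1) and
keeps that latent label for the whole trial; under the averaging model the
trial runs at the weighted-average rate.  Default trial counts are the
median counts of the emulated experiment: 4 trials per direction for
fix1/fix2/attend-fix and 12 for attend-in.

Reproducibility: one root seed per dataset, with independent substreams
keyed by (neuron, condition, direction, trial), so regenerating any subset
of trials yields identical spikes regardless of iteration order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from ._kernels import simulate_bernoulli
from .likelihood import HistoryParams, ModelParams
from .spike_io import SpikeTrain, TrialRecord
from .tuning import (
    APERTURE2_OFFSET,
    AttentionParams,
    BIDIRECTIONAL,
    CONDITIONS,
    TWO_PI,
    TuningParams,
)

logger = logging.getLogger(__name__)

DEFAULT_TRIALS = {"fix1": 4, "fix2": 4, "attend-fix": 4, "attend-in": 12}

#: Longest window permitted (used by the boundary-effect study, which
#: simulates 2000 ms windows to make end-of-window censoring negligible).
MAX_WINDOW_MS = 2000.0


class DesignError(ValueError):
    """Inconsistent experiment-design specification."""


@dataclass(frozen=True)
class ExperimentDesign:
    """The condition x direction x trial grid and its timing parameters."""

    conditions: tuple = CONDITIONS
    n_directions: int = 12
    direction_step: float = TWO_PI / 12
    aperture2_offset: float = APERTURE2_OFFSET
    trials_per_cell: dict = field(default_factory=lambda: dict(DEFAULT_TRIALS))
    window_length: float = 500.0
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.conditions:
            raise DesignError("conditions: empty condition list")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise DesignError(f"conditions: unknown condition {c!r}")
        if abs(self.n_directions * self.direction_step - TWO_PI) > 1e-9:
            raise DesignError(
                "n_directions/direction_step: directions must tile the full circle"
            )
        n_bins = self.window_length / self.dt
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise DesignError("window_length: must be an integer multiple of dt")
        if not 0 < self.window_length <= MAX_WINDOW_MS:
            raise DesignError(
                f"window_length: must be in (0, {MAX_WINDOW_MS}] ms, got {self.window_length}"
            )
        for c in self.conditions:
            m = self.trials_per_cell.get(c, 0)
            if m < 2:
                raise DesignError(
                    f"trials_per_cell[{c}]: at least two trials per condition are "
                    f"required for analysis, got {m}"
                )

    @property
    def n_bins(self) -> int:
        return int(round(self.window_length / self.dt))

    def direction_indices(self) -> range:
        return range(1, self.n_directions + 1)


def build_design(**overrides) -> ExperimentDesign:
    """Construct a validated design from (partial) field overrides."""
    base = ExperimentDesign()
    if "trials_per_cell" in overrides:
        merged = dict(DEFAULT_TRIALS)
        merged.update(overrides["trials_per_cell"])
        overrides = {**overrides, "trials_per_cell": merged}
    try:
        return replace(base, **overrides)
    except TypeError as err:
        raise DesignError(str(err)) from err


@dataclass(frozen=True)
class GroundTruth:
    """Generating model and parameters; latent labels are filled at simulation."""

    generating_model: str
    params: ModelParams

    def __post_init__(self):
        if self.generating_model not in ("mixing", "averaging"):
            raise DesignError(
                f"generating_model must be 'mixing' or 'averaging', got {self.generating_model!r}"
            )
        if self.params.kind != self.generating_model:
            raise DesignError("params.kind must match generating_model")


def default_ground_truth(
    kind: str = "mixing",
    A1: float = 40.0,
    A2: float = 10.0,
    sigma1: float = 1.2,
    sigma2: float = 1.2,
    r0: float = 5.0,
    p_attend_fix: float = 0.5,
    p_attend_in: float = 0.7,
    a1: float = 1.5,
    a2: float = 0.8,
    gamma0: float = -0.0005,
    gamma1: float = -3.0,
    m: int = 10,
) -> GroundTruth:
    """A canonical neuron: strong, refractory, with well-separated rates.

    Amplitudes 40 vs 10 spikes/s give clearly different responses to the
    two stimuli (the regime where the two models are distinguishable);
    widths and spontaneous rate follow a typical MT tuning curve
    (sigma = 1.2 rad, r0 = 5 spikes/s).  ``gamma1 = -3`` imposes strong
    relative refractoriness in the first millisecond after a spike and
    ``gamma0 = -5e-4``/ms a mild within-trial rate decay.
    """
    gammas = np.zeros(m)
    gammas[0] = gamma1
    tuning = TuningParams(A1=A1, sigma1=sigma1, A2=A2, sigma2=sigma2, r0=r0)
    if kind == "mixing":
        attn = AttentionParams.for_mixing(p_attend_fix, p_attend_in, a1, a2)
    else:
        attn = AttentionParams.for_mixing(p_attend_fix, p_attend_in, a1, a2).as_averaging()
    params = ModelParams(
        kind=kind, tuning=tuning, attn=attn, history=HistoryParams(gamma0, gammas)
    )
    return GroundTruth(generating_model=kind, params=params)


def sample_ground_truth(rng: np.random.Generator, kind: str = "mixing", m: int = 10) -> GroundTruth:
    """Draw heterogeneous neuron parameters from a documented prior.

    Amplitudes are log-normal around typical MT values (A1 ~ 30, A2 ~ 12
    spikes/s), widths uniform in [0.8, 1.6] rad, spontaneous rate uniform
    in [2, 8] spikes/s, stimulus weights uniform in [0.3, 0.7]
    (attend-fix) and [0.5, 0.85] (attend-in), attentional gains around
    1.4 (attended) and 0.8 (unattended), and a refractory first history
    weight gamma1 in [-4, -2].
    """
    tuning = TuningParams(
        A1=float(np.exp(rng.normal(np.log(30.0), 0.3))),
        sigma1=float(rng.uniform(0.8, 1.6)),
        A2=float(np.exp(rng.normal(np.log(12.0), 0.3))),
        sigma2=float(rng.uniform(0.8, 1.6)),
        r0=float(rng.uniform(2.0, 8.0)),
    )
    attn = AttentionParams.for_mixing(
        p_attend_fix=float(rng.uniform(0.3, 0.7)),
        p_attend_in=float(rng.uniform(0.5, 0.85)),
        a1=float(np.exp(rng.normal(np.log(1.4), 0.15))),
        a2=float(np.exp(rng.normal(np.log(0.8), 0.15))),
    )
    if kind == "averaging":
        attn = attn.as_averaging()
    gammas = np.zeros(m)
    gammas[0] = float(rng.uniform(-4.0, -2.0))
    if m > 1:
        gammas[1] = float(rng.uniform(-1.0, 0.0))
    history = HistoryParams(gamma0=float(rng.uniform(-0.001, 0.0)), gammas=gammas)
    params = ModelParams(kind=kind, tuning=tuning, attn=attn, history=history)
    return GroundTruth(generating_model=kind, params=params)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _trial_rate_and_label(truth, condition, direction_index, rng, aperture2_offset):
    """Resolve the base rate for one trial, drawing the latent label if mixing."""
    cr = truth.params.rates(condition, direction_index, aperture2_offset)
    if cr.is_mixture:
        label = 1 if rng.random() < cr.p else 2
        return cr.components[label - 1], label
    return cr.components[0], None


def simulate_trial(
    design: ExperimentDesign,
    truth: GroundTruth,
    condition: str,
    direction_index: int,
    rng: np.random.Generator,
):
    """Sample one spike train; returns ``(SpikeTrain, latent_label_or_None)``.

    The latent label (1 or 2) is drawn once per trial under the mixing
    model in bidirectional conditions and is fixed for the whole train;
    otherwise it is ``None``.
    """
    rate, label = _trial_rate_and_label(
        truth, condition, direction_index, rng, design.aperture2_offset
    )
    hist = truth.params.history
    u = rng.random((1, design.n_bins))
    spikes, n_clamped = simulate_bernoulli(
        u, np.array([rate]), hist.gamma0, hist.gammas, design.dt
    )
    if n_clamped > 0.001 * design.n_bins:
        logger.warning(
            "lambda*dt clamped in %d/%d bins (rate %.1f spikes/s): check rate units",
            n_clamped, design.n_bins, rate,
        )
    idx = np.flatnonzero(spikes[0])
    train = SpikeTrain(times=(idx + 1) * design.dt, T=design.window_length, dt=design.dt)
    return train, label


def _trial_rng(seed: int, neuron: int, condition: str, k: int, j: int) -> np.random.Generator:
    """Independent substream for one trial, stable under reordering."""
    c = CONDITIONS.index(condition)
    return np.random.default_rng(np.random.SeedSequence([int(seed), neuron, c, k, j]))


def simulate_dataset(
    design: ExperimentDesign,
    truth,
    n_neurons: int = 1,
    seed: Optional[int] = None,
):
    """Simulate the full condition x direction x trial grid.

    ``truth`` may be a single :class:`GroundTruth` (shared by all neurons)
    or a sequence of length ``n_neurons``.  Returns ``(records, log)``
    where ``log`` maps ``(neuron_id, condition, direction_index,
    trial_index)`` to the latent stimulus label for mixing-generated
    bidirectional trials (used by label-recovery analyses).
    """
    if n_neurons < 1:
        raise DesignError("n_neurons must be >= 1")
    truths = list(truth) if isinstance(truth, (list, tuple)) else [truth] * n_neurons
    if len(truths) != n_neurons:
        raise DesignError(f"got {len(truths)} ground truths for {n_neurons} neurons")
    root = design.seed if seed is None else seed

    records: list[TrialRecord] = []
    labels: dict = {}
    for neuron in range(n_neurons):
        nid = f"n{neuron:03d}"
        for condition in design.conditions:
            for k in design.direction_indices():
                for j in range(1, design.trials_per_cell[condition] + 1):
                    rng = _trial_rng(root, neuron, condition, k, j)
                    train, label = simulate_trial(design, truths[neuron], condition, k, rng)
                    records.append(TrialRecord(nid, condition, k, j, train))
                    if label is not None:
                        labels[(nid, condition, k, j)] = label
    return records, labels


def simulate_paired_neurons(
    design: ExperimentDesign,
    truth_a: GroundTruth,
    truth_b: GroundTruth,
    coupling: float,
    seed: Optional[int] = None,
    pair_id: str = "pair0",
):
    """Simulate two simultaneously recorded mixing neurons.

    On each bidirectional trial, with probability ``coupling`` the two
    neurons share one latent stimulus label (drawn with neuron A's
    ``p_c``); otherwise each draws its own label independently.  Models
    the question whether neurons in a population select the same stimulus
    on a given trial.  Returns ``(records_a, records_b, labels)`` with
    labels keyed ``(neuron_id, condition, k, j)``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise DesignError(f"coupling must be in [0, 1], got {coupling}")
    for t in (truth_a, truth_b):
        if t.generating_model != "mixing":
            raise DesignError("paired simulation requires mixing ground truths "
                              "(label coupling is undefined under averaging)")
    root = design.seed if seed is None else seed
    ids = (f"{pair_id}_a", f"{pair_id}_b")
    out_a: list[TrialRecord] = []
    out_b: list[TrialRecord] = []
    labels: dict = {}
    for condition in design.conditions:
        for k in design.direction_indices():
            for j in range(1, design.trials_per_cell[condition] + 1):
                rng = _trial_rng(root, 0, condition, k, j)
                if condition in BIDIRECTIONAL:
                    share = rng.random() < coupling
                    pa = truth_a.params.rates(condition, k, design.aperture2_offset)
                    pb = truth_b.params.rates(condition, k, design.aperture2_offset)
                    la = 1 if rng.random() < pa.p else 2
                    lb = la if share else (1 if rng.random() < pb.p else 2)
                    rates = (pa.components[la - 1], pb.components[lb - 1])
                    labs = (la, lb)
                else:
                    rates = tuple(
                        t.params.rates(condition, k, design.aperture2_offset).components[0]
                        for t in (truth_a, truth_b)
                    )
                    labs = (None, None)
                for nid, rate, lab, out, t in zip(
                    ids, rates, labs, (out_a, out_b), (truth_a, truth_b)
                ):
                    hist = t.params.history
                    u = rng.random((1, design.n_bins))
                    spikes, _ = simulate_bernoulli(
                        u, np.array([rate]), hist.gamma0, hist.gammas, design.dt
                    )
                    idx = np.flatnonzero(spikes[0])
                    out.append(
                        TrialRecord(
                            nid, condition, k, j,
                            SpikeTrain((idx + 1) * design.dt, design.window_length, design.dt),
                        )
                    )
                    if lab is not None:
                        labels[(nid, condition, k, j)] = lab
    return out_a, out_b, labels
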