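"""Discrete point-process likelihoods for the two competing models.

The conditional intensity of a neuron responding to stimulus ``l`` is

    lambda(t | H_t) = r_l * exp(gamma0 * t + sum_{i=1..m} gamma_i * dN_{t - i dt})

where ``r_l`` is the tuning-curve rate (spikes/s), ``gamma0`` a linear
trend (per ms, expected negative because rates decay within a trial), and
``gamma_1..gamma_m`` spike-response weights capturing refractoriness and
other history effects over the past ``m = 10`` ms.  With 1 ms bins the
log-likelihood of a train is approximated by the discrete sum

    log L = sum_spikes log lambda(t_i | H)  -  sum_bins lambda(n dt | H) dt,

which agrees with the conditional-Bernoulli mass function to second order
in ``lambda * dt``.

The intensity is evaluated at bin start times ``t_n = n * dt`` (0-based)
using history up to but excluding bin ``n``; bins before the window start
are assumed spike-free.  Rates are in spikes/s and ``dt`` is converted to
seconds inside every ``lambda * dt`` product.

Per-trial likelihoods combine into the two model likelihoods:

* mixing -- each bidirectional trial contributes
  ``log(p_c exp(l1) + (1 - p_c) exp(l2))`` (computed with log-sum-exp);
* averaging -- each trial contributes the single-component likelihood at
  the weighted-average rate.

Unidirectional trials contribute their single-stimulus likelihood to both
models (``p_c = 1`` under fix1, ``p_c = 0`` under fix2), so on
unidirectional data the two models coincide exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .spike_io import SpikeTrain, TrialRecord
from .tuning import (
    AttentionParams,
    ConditionRates,
    TuningParams,
    condition_rates,
    CONDITIONS,
    APERTURE2_OFFSET,
    TWO_PI,
)

#: Seconds per 1 ms bin: converts rate (spikes/s) x dt to a per-bin mass.
MS_TO_S = 1e-3

#: Rate floor (spikes/s) inside logarithms, to keep the objective finite
#: while the optimizer explores extreme parameter values.
RATE_FLOOR = 1e-10


@dataclass(frozen=True)
class HistoryParams:
    """Linear trend and spike-history filter of the log-intensity."""

    gamma0: float = 0.0
    gammas: np.ndarray = field(default_factory=lambda: np.zeros(10))

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.gammas, dtype=float))
        object.__setattr__(self, "gammas", g)
        if not np.all(np.isfinite(g)) or not np.isfinite(self.gamma0):
            raise ValueError("history weights must be finite")

    @property
    def m(self) -> int:
        return int(self.gammas.size)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector theta for either model.

    At memory length m = 10 the mixing model has 20 free parameters
    (A1, sigma1, A2, sigma2, r0, p_attend_fix, p_attend_in, a1, a2,
    gamma0, gamma1..gamma10) and the averaging model 19 (p_attend_in, a1,
    a2 collapse to the identifiable b1, b2).
    """

    kind: str
    tuning: TuningParams
    attn: AttentionParams
    history: HistoryParams

    def __post_init__(self):
        if self.kind not in ("mixing", "averaging"):
            raise ValueError(f"kind must be 'mixing' or 'averaging', got {self.kind!r}")
        if self.kind == "mixing":
            if self.attn.p_attend_in is None or self.attn.a1 is None or self.attn.a2 is None:
                raise ValueError("mixing model requires p_attend_in, a1, a2")
        else:
            a = self.attn
            if (a.b1 is None or a.b2 is None) and (
                a.p_attend_in is None or a.a1 is None or a.a2 is None
            ):
                raise ValueError("averaging model requires (b1, b2) or values to derive them")

    @property
    def n_params(self) -> int:
        base = 5 + 1 + 1 + self.history.m  # tuning (5) + p_af + gamma0 + gammas
        return base + (3 if self.kind == "mixing" else 2)

    def rates(self, condition: str, direction_index: int,
              aperture2_offset: float = APERTURE2_OFFSET) -> ConditionRates:
        return condition_rates(
            condition, direction_index, self.tuning, self.attn, self.kind,
            aperture2_offset,
        )


@dataclass(frozen=True)
class LogLik:
    """A natural-log likelihood value with the data size it was computed on."""

    value: float
    n_spikes: int
    n_bins: int


def conditional_intensity(
    base_rate: float,
    history: HistoryParams,
    binned: np.ndarray,
    n: int,
    dt: float = 1.0,
) -> float:
    """Intensity (spikes/s) at bin ``n`` given the binned train's past.

    Reference implementation evaluating the model definition term by term;
    the vectorized :class:`NeuronData` path is used for fitting.
    """
    if base_rate <= 0:
        raise ValueError("base rate must be > 0")
    t_n = n * dt
    h = 0.0
    for i in range(1, history.m + 1):
        if n - i >= 0:
            h += history.gammas[i - 1] * float(binned[n - i])
    return float(base_rate * np.exp(history.gamma0 * t_n + h))


def intensity_per_bin(
    train: SpikeTrain, base_rate: float, history: HistoryParams
) -> np.ndarray:
    """Vector of lambda (spikes/s) over all bins of one train."""
    n_bins = train.n_bins
    dt = train.dt
    log_base = np.log(max(base_rate, RATE_FLOOR))
    g = history.gamma0 * np.arange(n_bins) * dt
    h = np.zeros(n_bins)
    bins = train.spike_bins()
    for i in range(1, history.m + 1):
        tgt = bins + i
        tgt = tgt[tgt < n_bins]
        np.add.at(h, tgt, history.gammas[i - 1])
    return np.exp(log_base + g + h)


def train_loglik(
    train: SpikeTrain, base_rate: float, history: Optional[HistoryParams] = None
) -> LogLik:
    """Discrete-sum log-likelihood of a single train at a fixed base rate."""
    if history is None:
        history = HistoryParams(0.0, np.zeros(0))
    lam = intensity_per_bin(train, base_rate, history)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite intensity encountered")
    bins = train.spike_bins()
    value = float(np.sum(np.log(np.maximum(lam[bins], RATE_FLOOR))) - np.sum(lam) * train.dt * MS_TO_S)
    return LogLik(value=value, n_spikes=train.n_spikes, n_bins=train.n_bins)


# ---------------------------------------------------------------------------
# Fast per-neuron likelihood evaluation
# ---------------------------------------------------------------------------

_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}


class NeuronData:
    """Precomputed sufficient structure for one neuron's trials.

    Caches, per trial: the spike-bin indices, the spike-pair lag counts
    feeding the history term at spike times, and flattened scatter indices
    for rebuilding the per-bin history field, so that a full model
    log-likelihood costs one ``exp`` over all bins plus O(spikes) work.
    Handles variable trial lengths (early stimulus changes) via masking.
    """

    def __init__(self, records: Sequence[TrialRecord], m: int = 10,
                 aperture2_offset: float = APERTURE2_OFFSET):
        if not records:
            raise ValueError("no trial records supplied")
        neuron_ids = {r.neuron_id for r in records}
        if len(neuron_ids) > 1:
            raise ValueError(f"records span multiple neurons: {sorted(neuron_ids)}")
        self.neuron_id = records[0].neuron_id
        self.records = list(records)
        self.m = int(m)
        self.aperture2_offset = aperture2_offset
        n_tr = len(self.records)
        self.dt = self.records[0].train.dt

        self.T_bins = np.array([r.train.n_bins for r in self.records])
        self.max_T = int(self.T_bins.max())
        self.N = np.array([r.train.n_spikes for r in self.records])
        self.cond = np.array([_COND_CODE[r.condition] for r in self.records])
        self.k = np.array([r.direction_index for r in self.records])
        lagcount = np.zeros((n_tr, self.m))
        sum_t_spk = np.zeros(n_tr)
        flat_idx, lag_idx = [], []
        for j, rec in enumerate(self.records):
            bins = rec.train.spike_bins()
            sum_t_spk[j] = np.sum(bins) * self.dt
            present = np.zeros(rec.train.n_bins, dtype=bool)
            present[bins] = True
            for i in range(1, self.m + 1):
                tgt = bins + i
                ok = tgt < rec.train.n_bins
                tgt = tgt[ok]
                flat_idx.append(j * self.max_T + tgt)
                lag_idx.append(np.full(tgt.size, i - 1))
                lagcount[j, i - 1] = np.count_nonzero(present[tgt])
        self.lagcount = lagcount
        self.sum_t_spikes = sum_t_spk
        flat = np.concatenate(flat_idx) if flat_idx else np.zeros(0, dtype=np.int64)
        lags = np.concatenate(lag_idx).astype(np.int64) if lag_idx else np.zeros(0, dtype=np.int64)
        # The history field is nonzero only in the m bins after a spike;
        # deduplicate those (trial, bin) entries so a likelihood eval only
        # exponentiates at affected bins plus a closed-form geometric base.
        self.entry_flat, self.entry_inverse = np.unique(flat, return_inverse=True)
        self.lag_idx = lags
        self.entry_trial = self.entry_flat // self.max_T
        self.entry_t = (self.entry_flat % self.max_T) * self.dt  # ms
        self.n_entries = int(self.entry_flat.size)
        self.total_spikes = int(self.N.sum())
        self.total_bins = int(self.T_bins.sum())
        self.total_time_s = self.total_bins * self.dt * MS_TO_S

    # -- core per-trial quantities ------------------------------------------

    def _history_sums(self, history: HistoryParams):
        """(spike-bin history sums, masked integral of exp(history field))."""
        if history.m != self.m:
            raise ValueError(f"history has m={history.m}, cache built with m={self.m}")
        n_tr = len(self.records)
        # sum_{n=0}^{T-1} exp(gamma0 * n * dt): geometric series per trial
        a = history.gamma0 * self.dt
        if abs(a) < 1e-14:
            base_sum = self.T_bins.astype(float)
        else:
            r = np.exp(a)
            base_sum = (1.0 - np.exp(a * self.T_bins)) / (1.0 - r)
        if self.n_entries:
            c = np.bincount(
                self.entry_inverse,
                weights=history.gammas[self.lag_idx],
                minlength=self.n_entries,
            )
            corr = np.exp(history.gamma0 * self.entry_t) * np.expm1(c)
            E = base_sum + np.bincount(self.entry_trial, weights=corr, minlength=n_tr)
        else:
            E = base_sum
        spike_g = history.gamma0 * self.sum_t_spikes + self.lagcount @ history.gammas
        return spike_g, E

    def component_logliks(self, history: HistoryParams, rates_1: np.ndarray,
                          rates_2: Optional[np.ndarray] = None):
        """Per-trial log-likelihood under component rate(s) (spikes/s)."""
        spike_g, E = self._history_sums(history)

        def ll(r):
            r = np.maximum(r, RATE_FLOOR)
            return self.N * np.log(r) + spike_g - r * MS_TO_S * self.dt * E

        if rates_2 is None:
            return ll(rates_1)
        return ll(rates_1), ll(rates_2)

    def _rate_tables(self, params: ModelParams):
        """Rate lookup per (condition, direction): single rates and mixture parts.

        Vectorized equivalent of calling ``params.rates`` on every
        (condition, direction) pair; tested against that scalar path.
        Table columns are 1-based direction indices (column 0 unused).
        """
        from .tuning import gauss_factor

        t, a = params.tuning, params.attn
        d1 = np.arange(12) * (TWO_PI / 12.0)
        d2 = d1 + self.aperture2_offset
        g1 = gauss_factor(d1, t.sigma1, t.D)
        g2 = gauss_factor(d2, t.sigma2, t.D)
        r1 = t.A1 * g1 + t.r0
        r2 = t.A2 * g2 + t.r0

        single = np.full((4, 13), np.nan)
        comp1 = np.full((4, 13), np.nan)
        comp2 = np.full((4, 13), np.nan)
        pmix = np.full(4, np.nan)
        single[0, 1:] = r1  # fix1
        single[1, 1:] = r2  # fix2
        p = a.p_attend_fix
        if params.kind == "mixing":
            comp1[2, 1:] = r1
            comp2[2, 1:] = r2
            pmix[2] = p
            comp1[3, 1:] = a.a1 * t.A1 * g1 + t.r0
            comp2[3, 1:] = a.a2 * t.A2 * g2 + t.r0
            pmix[3] = a.p_attend_in
        else:
            single[2, 1:] = p * r1 + (1.0 - p) * r2
            aa = a if a.b1 is not None else a.as_averaging()
            single[3, 1:] = aa.b1 * t.A1 * g1 + aa.b2 * t.A2 * g2 + t.r0
        return single, comp1, comp2, pmix

    def trial_logliks(self, params: ModelParams):
        """Per-trial log-likelihoods and, for mixture trials, the parts.

        Returns ``(ll, parts)`` where ``ll`` is the per-trial log-likelihood
        under ``params`` and ``parts`` is ``None`` for the averaging model
        or ``(l1, l2, logp1, logp2, is_mix)`` arrays for the mixing model.
        """
        single, comp1, comp2, pmix = self._rate_tables(params)
        is_mix = ~np.isnan(comp1[self.cond, self.k])
        spike_g, E = self._history_sums(params.history)

        def ll(r, sel):
            r = np.maximum(r, RATE_FLOOR)
            return self.N[sel] * np.log(r) + spike_g[sel] - r * MS_TO_S * self.dt * E[sel]

        out = np.zeros(len(self.records))
        if np.any(~is_mix):
            out[~is_mix] = ll(single[self.cond[~is_mix], self.k[~is_mix]], ~is_mix)
        parts = None
        if np.any(is_mix):
            l1 = ll(comp1[self.cond[is_mix], self.k[is_mix]], is_mix)
            l2 = ll(comp2[self.cond[is_mix], self.k[is_mix]], is_mix)
            p = pmix[self.cond[is_mix]]
            p = np.clip(p, 1e-300, 1.0)
            with np.errstate(divide="ignore"):
                logp1 = np.log(p)
                logp2 = np.log1p(-np.clip(p, 0.0, 1.0 - 1e-16))
            x1 = logp1 + l1
            x2 = logp2 + l2
            hi = np.maximum(x1, x2)
            out[is_mix] = hi + np.log1p(np.exp(np.minimum(x1, x2) - hi))
            parts = (l1, l2, logp1, logp2, is_mix)
        return out, parts

    def loglik(self, params: ModelParams) -> LogLik:
        ll, _ = self.trial_logliks(params)
        return LogLik(value=float(ll.sum()), n_spikes=self.total_spikes, n_bins=self.total_bins)


def mixing_loglik(records: Sequence[TrialRecord], params: ModelParams) -> LogLik:
    """Total mixing-model log-likelihood of one neuron's trials."""
    if params.kind != "mixing":
        raise ValueError("params.kind must be 'mixing'")
    _check_probs(params)
    return NeuronData(records, m=params.history.m).loglik(params)


def averaging_loglik(records: Sequence[TrialRecord], params: ModelParams) -> LogLik:
    """Total response-averaging log-likelihood of one neuron's trials."""
    if params.kind != "averaging":
        raise ValueError("params.kind must be 'averaging'")
    _check_probs(params)
    return NeuronData(records, m=params.history.m).loglik(params)


def _check_probs(params: ModelParams):
    for name in ("p_attend_fix", "p_attend_in"):
        v = getattr(params.attn, name)
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")


def null_deviance(records: Sequence[TrialRecord]) -> float:
    """Deviance ``-2 log L0`` of the constant-rate (homogeneous) null model.

    The null model assumes every train of the neuron shares one firing
    rate; its MLE is total spikes over total observed time.  Used as a
    reference offset subtracted from both models' AIC/BIC (differences are
    unaffected).
    """
    total_spikes = sum(r.train.n_spikes for r in records)
    total_time_s = sum(r.train.n_bins * r.train.dt for r in records) * MS_TO_S
    if total_spikes == 0:
        warnings.warn("neuron has zero spikes; null rate floored", RuntimeWarning)
    rate = max(total_spikes / total_time_s, RATE_FLOOR)
    ll0 = sum(train_loglik(r.train, rate).value for r in records)
    return -2.0 * ll0


def constant_rate_mle(records: Sequence[TrialRecord]) -> float:
    """MLE of the homogeneous-rate null model (spikes/s)."""
    total_spikes = sum(r.train.n_spikes for r in records)
    total_time_s = sum(r.train.n_bins * r.train.dt for r in records) * MS_TO_S
    return total_spikes / total_time_s
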