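"""Per-neuron maximum-likelihood estimation for both models.

All parameters are estimated simultaneously by a two-stage search on an
unconstrained reparameterization: a global stage with the DIRECT
(dividing rectangles) algorithm inside a bounded box, whose best point --
together with a cheap data-driven initial guess -- seeds a local
Nelder-Mead simplex refinement.  Positive parameters (amplitudes, widths,
spontaneous rate, gains) are optimized on the log scale and probabilities
through a logistic map, so the local stage needs no constraints.

The optimizer is deterministic given the data and options; the returned
:class:`FitResult` records the evaluation counts and tolerances used.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import direct, minimize

from .likelihood import HistoryParams, LogLik, ModelParams, NeuronData, constant_rate_mle
from .spike_io import TrialRecord
from .tuning import AttentionParams, TuningParams, UNIDIRECTIONAL

_LOGIT_CLIP = 30.0


@dataclass(frozen=True)
class FitOptions:
    """Search box, budgets and tolerances of the two-stage optimization.

    The box covers the plausible physiological range: amplitudes in
    [0.1, 200] spikes/s, widths in [0.1, 3] rad, spontaneous rate in
    [0.1, 100] spikes/s, attentional gains in [0.05, 20], trend in
    [-0.02, 0.02] per ms and history weights in [-25, 5].
    """

    m: int = 10
    direct_maxfun: int = 2000
    nm_maxfev: int = 6000
    nm_fatol: float = 1e-8
    nm_xatol: float = 1e-6
    nm_restarts: int = 4
    nm_restart_tol: float = 0.01
    A_bounds: tuple = (0.1, 200.0)
    sigma_bounds: tuple = (0.1, 3.0)
    r0_bounds: tuple = (0.1, 100.0)
    gain_bounds: tuple = (0.05, 20.0)
    b_bounds: tuple = (0.01, 20.0)
    p_logit_bounds: tuple = (-6.0, 6.0)
    gamma0_bounds: tuple = (-0.02, 0.02)
    gamma_bounds: tuple = (-25.0, 5.0)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimates and optimization diagnostics."""

    params: ModelParams
    raw: np.ndarray
    loglik: LogLik
    n_params: int
    converged: bool
    n_evals: int
    runtime: float


def _sigmoid(z):
    z = np.clip(z, -_LOGIT_CLIP, _LOGIT_CLIP)
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    p = np.clip(p, _sigmoid(-_LOGIT_CLIP), _sigmoid(_LOGIT_CLIP))
    return float(np.clip(np.log(p / (1.0 - p)), -_LOGIT_CLIP, _LOGIT_CLIP))


def n_free_params(kind: str, m: int = 10) -> int:
    """20 for the mixing model, 19 for averaging, at memory length m=10."""
    return (7 + m) + (3 if kind == "mixing" else 2)


def params_to_raw(params: ModelParams) -> np.ndarray:
    """Map model parameters to the unconstrained optimization vector."""
    t, a, h = params.tuning, params.attn, params.history
    head = [np.log(t.A1), np.log(t.sigma1), np.log(t.A2), np.log(t.sigma2),
            np.log(t.r0), _logit(a.p_attend_fix)]
    if params.kind == "mixing":
        head += [_logit(a.p_attend_in), np.log(a.a1), np.log(a.a2)]
    else:
        aa = a if a.b1 is not None else a.as_averaging()
        head += [np.log(max(aa.b1, 1e-12)), np.log(max(aa.b2, 1e-12))]
    return np.array(head + [h.gamma0] + list(h.gammas), dtype=float)


def raw_to_params(kind: str, raw: np.ndarray, m: int = 10) -> ModelParams:
    """Inverse of :func:`params_to_raw` (round-trip identity to ~1e-12)."""
    raw = np.asarray(raw, dtype=float)
    expect = n_free_params(kind, m)
    if raw.size != expect:
        raise ValueError(f"raw vector has {raw.size} entries, expected {expect} for {kind}")
    tuning = TuningParams(
        A1=float(np.exp(raw[0])), sigma1=float(np.exp(raw[1])),
        A2=float(np.exp(raw[2])), sigma2=float(np.exp(raw[3])),
        r0=float(np.exp(raw[4])),
    )
    p_af = float(_sigmoid(raw[5]))
    if kind == "mixing":
        attn = AttentionParams.for_mixing(
            p_af, float(_sigmoid(raw[6])), float(np.exp(raw[7])), float(np.exp(raw[8]))
        )
        off = 9
    else:
        attn = AttentionParams.for_averaging(
            p_af, float(np.exp(raw[6])), float(np.exp(raw[7]))
        )
        off = 8
    history = HistoryParams(gamma0=float(raw[off]), gammas=raw[off + 1:].copy())
    return ModelParams(kind=kind, tuning=tuning, attn=attn, history=history)


def raw_bounds(kind: str, options: FitOptions) -> list:
    """Box for the global DIRECT stage, in raw (transformed) coordinates."""
    lo = np.log
    b = [
        (lo(options.A_bounds[0]), lo(options.A_bounds[1])),
        (lo(options.sigma_bounds[0]), lo(options.sigma_bounds[1])),
        (lo(options.A_bounds[0]), lo(options.A_bounds[1])),
        (lo(options.sigma_bounds[0]), lo(options.sigma_bounds[1])),
        (lo(options.r0_bounds[0]), lo(options.r0_bounds[1])),
        options.p_logit_bounds,
    ]
    if kind == "mixing":
        b += [options.p_logit_bounds,
              (lo(options.gain_bounds[0]), lo(options.gain_bounds[1])),
              (lo(options.gain_bounds[0]), lo(options.gain_bounds[1]))]
    else:
        b += [(lo(options.b_bounds[0]), lo(options.b_bounds[1])),
              (lo(options.b_bounds[0]), lo(options.b_bounds[1]))]
    b += [options.gamma0_bounds] + [options.gamma_bounds] * options.m
    return b


def _heuristic_init(data: NeuronData, kind: str, options: FitOptions) -> np.ndarray:
    """Moment-based starting point: empirical rates per condition/direction."""
    rate_trial = data.N / (data.T_bins * data.dt * 1e-3)  # spikes/s per trial
    overall = max(constant_rate_mle(data.records), 0.5)
    r0 = max(0.5, float(np.percentile(rate_trial, 5)))

    def cond_amp(code):
        sel = data.cond == code
        if not np.any(sel):
            return overall
        return max(float(np.max(rate_trial[sel])) - r0, 1.0)

    A1 = min(cond_amp(0), options.A_bounds[1] * 0.9)  # fix1
    A2 = min(cond_amp(1), options.A_bounds[1] * 0.9)  # fix2
    tuning = TuningParams(A1=A1, sigma1=1.0, A2=A2, sigma2=1.0, r0=min(r0, 90.0))
    if kind == "mixing":
        attn = AttentionParams.for_mixing(0.5, 0.6, 1.2, 0.9)
    else:
        attn = AttentionParams.for_averaging(0.5, 0.7, 0.35)
    gammas = np.zeros(options.m)
    gammas[0] = -1.0
    params = ModelParams(kind=kind, tuning=tuning, attn=attn,
                         history=HistoryParams(-1e-4, gammas))
    return params_to_raw(params)


def fit_neuron(
    records: Sequence[TrialRecord],
    model_kind: str,
    options: Optional[FitOptions] = None,
    data: Optional[NeuronData] = None,
    x0: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit one model to all of a neuron's trials by maximum likelihood.

    ``data`` may pass a prebuilt :class:`NeuronData` cache; ``x0`` skips
    the global stage and refines from the given raw vector (used by
    cross-validation refits).
    """
    options = options or FitOptions()
    if data is None:
        data = NeuronData(records, m=options.m)
    t0 = time.perf_counter()
    evals = 0

    def objective(raw):
        nonlocal evals
        evals += 1
        try:
            ll = data.loglik(raw_to_params(model_kind, raw, options.m)).value
        except (FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    candidates = []
    if x0 is not None:
        candidates.append(np.asarray(x0, dtype=float))
    else:
        res = direct(
            objective,
            raw_bounds(model_kind, options),
            maxfun=options.direct_maxfun,
            maxiter=10000,
        )
        candidates.append(np.asarray(res.x))
        candidates.append(_heuristic_init(data, model_kind, options))

    start = min(candidates, key=objective)
    best = None
    # Nelder-Mead with restarts: re-inflating the simplex at the incumbent
    # escapes premature shrinkage, which is common in ~20 dimensions.
    for _ in range(options.nm_restarts):
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxfev": options.nm_maxfev,
                "fatol": options.nm_fatol,
                "xatol": options.nm_xatol,
                "adaptive": True,
            },
        )
        improved = best is None or res.fun < best.fun - options.nm_restart_tol
        if best is None or res.fun < best.fun:
            best = res
        start = best.x
        if not improved:
            break
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"fit failed for neuron {data.neuron_id} ({model_kind}): "
            "objective non-finite at every probe"
        )
    params = raw_to_params(model_kind, best.x, options.m)
    return FitResult(
        params=params,
        raw=np.asarray(best.x),
        loglik=data.loglik(params),
        n_params=n_free_params(model_kind, options.m),
        converged=bool(best.success),
        n_evals=evals,
        runtime=time.perf_counter() - t0,
    )


def fit_both_models(
    records: Sequence[TrialRecord],
    options: Optional[FitOptions] = None,
) -> tuple[FitResult, FitResult]:
    """Fit the mixing and averaging models to the same data."""
    options = options or FitOptions()
    data = NeuronData(records, m=options.m)
    fit_mix = fit_neuron(records, "mixing", options, data=data)
    fit_avg = fit_neuron(records, "averaging", options, data=data)
    return fit_mix, fit_avg
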