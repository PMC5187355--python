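"""Model selection: information criteria, weights, decoding, CV-RMSD.

AIC and BIC are reported with the neuron's null deviance (twice the
negative log-likelihood of a single-rate model) subtracted from both
models, which leaves model differences untouched but makes the values
interpretable as explanatory evidence relative to the null.  The BIC
sample size is the total number of 1 ms observation bins.  Given the
criterion difference ``delta`` between the two models, the weight in
favor of the lower-criterion model is ``1 / (1 + exp(-delta / 2))``.

Stimulus decoding classifies each bidirectional trial to the stimulus
maximizing the posterior under the fitted mixing model; predictive
accuracy is measured by the cross-validated root-mean-squared deviation
(RMSD) between each held-out trial's empirical rate ``N/T`` and the model
rate ``(1/T) int lambda dt`` evaluated with that trial's own spike
history (using the decoded component for the mixing model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitOptions, FitResult, fit_neuron
from .likelihood import MS_TO_S, ModelParams, NeuronData, null_deviance
from .spike_io import TrialRecord
from .tuning import UNIDIRECTIONAL


@dataclass(frozen=True)
class SelectionResult:
    """Per-neuron model-selection summary (mixing minus averaging deltas)."""

    neuron_id: str
    aic_mix: float
    aic_avg: float
    bic_mix: float
    bic_avg: float
    delta_aic: float
    delta_bic: float
    weight_mixing_aic: float
    weight_mixing_bic: float
    rmsd_mix: Optional[float]
    rmsd_avg: Optional[float]
    diagnostic: bool
    n_spikes: int


def information_criteria(fit: FitResult, null_dev: float, n_obs: int) -> tuple[float, float]:
    """Null-deviance-referenced AIC and BIC of a fit.

    AIC = -2 ll + 2 k - null_dev;  BIC = -2 ll + k log(n_obs) - null_dev.
    Subtracting the same reference from both models preserves differences.
    """
    k = fit.n_params
    ll = fit.loglik.value
    aic = -2.0 * ll + 2.0 * k - null_dev
    bic = -2.0 * ll + k * np.log(n_obs) - null_dev
    return float(aic), float(bic)


def model_weight(delta: float) -> float:
    """Akaike-type weight for the lower-criterion model given its advantage.

    ``delta`` is the criterion difference (other model minus this model);
    the complementary weight is ``exp(-delta/2) / (1 + exp(-delta/2))``,
    so ``model_weight(d) + model_weight(-d) == 1``.
    """
    if not np.isfinite(delta):
        raise ValueError("criterion difference must be finite")
    return float(1.0 / (1.0 + np.exp(-np.clip(delta, -700, 700) / 2.0)))


@dataclass(frozen=True)
class DecodedTrial:
    """Posterior stimulus classification of one trial under the mixing fit."""

    neuron_id: str
    condition: str
    direction_index: int
    trial_index: int
    posterior_1: float
    label: int  # decoded stimulus, 1 or 2 (posterior ties go to 1)


def decode_trials(
    records: Sequence[TrialRecord],
    mixing_params: ModelParams,
    data: Optional[NeuronData] = None,
) -> list[DecodedTrial]:
    """Classify every trial to its most probable stimulus.

    Bidirectional trials get ``posterior_1 = p l1' / (p l1' + (1-p) l2')``
    computed with log-sum-exp; unidirectional trials decode to their known
    stimulus with posterior 1 or 0.
    """
    if mixing_params.kind != "mixing":
        raise ValueError("decoding requires mixing-model parameters")
    if data is None:
        data = NeuronData(records, m=mixing_params.history.m)
    _, parts = data.trial_logliks(mixing_params)
    out = []
    post_mix = None
    if parts is not None:
        l1, l2, logp1, logp2, is_mix = parts
        z = (logp1 + l1) - (logp2 + l2)
        post_mix = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        mix_rows = np.flatnonzero(is_mix)
        post_by_row = dict(zip(mix_rows.tolist(), post_mix.tolist()))
    else:
        post_by_row = {}
    for row, rec in enumerate(data.records):
        if row in post_by_row:
            p1 = post_by_row[row]
            # ties decode to stimulus 1; the tolerance absorbs float noise
            # when the two components are mathematically identical
            label = 1 if p1 >= 0.5 - 1e-9 else 2
        else:
            p1 = 1.0 if rec.condition == "fix1" else 0.0
            label = 1 if rec.condition == "fix1" else 2
        out.append(
            DecodedTrial(rec.neuron_id, rec.condition, rec.direction_index,
                         rec.trial_index, float(p1), label)
        )
    return out


def _predicted_rates(
    data: NeuronData, params: ModelParams, decoded: Optional[list[DecodedTrial]] = None
) -> np.ndarray:
    """Model rate (1/T) int lambda dt per trial, spikes/s, own history."""
    spike_g, E = data._history_sums(params.history)
    single, comp1, comp2, pmix = data._rate_tables(params)
    rates = np.empty(len(data.records))
    for row, rec in enumerate(data.records):
        c, k = data.cond[row], data.k[row]
        if np.isnan(comp1[c, k]):
            r = single[c, k]
        else:
            label = decoded[row].label if decoded is not None else 1
            r = comp1[c, k] if label == 1 else comp2[c, k]
        rates[row] = r * E[row] / data.T_bins[row]
    return rates


def empirical_rates(data: NeuronData) -> np.ndarray:
    """Observed rate N/T (spikes/s) per trial."""
    return data.N / (data.T_bins * data.dt * MS_TO_S)


def rmsd_cv(
    records: Sequence[TrialRecord],
    fit_mix: FitResult,
    fit_avg: FitResult,
    folds: int = 10,
    seed: int = 0,
    options: Optional[FitOptions] = None,
    refit_maxfev: int = 400,
) -> tuple[float, float]:
    """Cross-validated RMSD of predicted vs empirical per-trial rates.

    Trials are split into ``folds`` folds stratified by condition x
    direction; for each fold, both models are refitted on the remaining
    trials (a Nelder-Mead refinement warm-started at the full-data
    estimates) and each held-out trial's rate is predicted from its own
    spike history -- using the component decoded for it under the
    refitted mixing model.  Returns ``(rmsd_mix, rmsd_avg)`` over all
    trials.
    """
    options = options or FitOptions()
    n = len(records)
    if n < folds:
        warnings.warn(f"only {n} trials; reducing folds from {folds} to {n}")
        folds = n
    rng = np.random.default_rng(seed)
    # stratified fold assignment
    fold_of = np.empty(n, dtype=int)
    groups: dict = {}
    for i, rec in enumerate(records):
        groups.setdefault((rec.condition, rec.direction_index), []).append(i)
    offset = 0
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size

    sq_err = {"mixing": 0.0, "averaging": 0.0}
    for f in range(folds):
        train = [r for i, r in enumerate(records) if fold_of[i] != f]
        test = [r for i, r in enumerate(records) if fold_of[i] == f]
        if not test:
            continue
        test_data = NeuronData(test, m=options.m)
        emp = empirical_rates(test_data)
        cv_opts = FitOptions(
            m=options.m, nm_maxfev=refit_maxfev, nm_restarts=1,
            nm_fatol=options.nm_fatol, nm_xatol=options.nm_xatol,
        )
        for kind, fit in (("mixing", fit_mix), ("averaging", fit_avg)):
            refit = fit_neuron(train, kind, cv_opts, x0=fit.raw)
            decoded = decode_trials(test, refit.params, data=test_data) \
                if kind == "mixing" else None
            pred = _predicted_rates(test_data, refit.params, decoded)
            sq_err[kind] += float(np.sum((emp - pred) ** 2))
    return tuple(np.sqrt(sq_err[k] / n) for k in ("mixing", "averaging"))


def classify_diagnostic(fit_mix: FitResult, fit_avg: FitResult,
                        lo: float = 0.2, hi: float = 0.8) -> bool:
    """Whether the neuron's fitted weights make the two models separable.

    A neuron is diagnostic if both models' attend-fix stimulus weights lie
    in [0.2, 0.8], or if the mixing model's attend-in probability does.
    Non-diagnostic neurons (weights near 0 or 1, or equal single-stimulus
    rates) behave near-identically under both models.
    """
    p_af_mix = fit_mix.params.attn.p_attend_fix
    p_af_avg = fit_avg.params.attn.p_attend_fix
    p_ai = fit_mix.params.attn.p_attend_in
    both_af = lo <= p_af_mix <= hi and lo <= p_af_avg <= hi
    return bool(both_af or (p_ai is not None and lo <= p_ai <= hi))


def select_neuron(
    records: Sequence[TrialRecord],
    fit_mix: FitResult,
    fit_avg: FitResult,
    folds: int = 10,
    seed: int = 0,
    options: Optional[FitOptions] = None,
    compute_rmsd: bool = True,
) -> SelectionResult:
    """Full per-neuron selection summary from the two fits."""
    data = NeuronData(records, m=fit_mix.params.history.m)
    null_dev = null_deviance(records)
    n_obs = data.total_bins
    aic_mix, bic_mix = information_criteria(fit_mix, null_dev, n_obs)
    aic_avg, bic_avg = information_criteria(fit_avg, null_dev, n_obs)
    d_aic = aic_mix - aic_avg
    d_bic = bic_mix - bic_avg
    rmsd_mix = rmsd_avg = None
    if compute_rmsd:
        rmsd_mix, rmsd_avg = rmsd_cv(records, fit_mix, fit_avg, folds=folds,
                                     seed=seed, options=options)
    return SelectionResult(
        neuron_id=data.neuron_id,
        aic_mix=aic_mix, aic_avg=aic_avg, bic_mix=bic_mix, bic_avg=bic_avg,
        delta_aic=float(d_aic), delta_bic=float(d_bic),
        weight_mixing_aic=model_weight(-d_aic),
        weight_mixing_bic=model_weight(-d_bic),
        rmsd_mix=rmsd_mix, rmsd_avg=rmsd_avg,
        diagnostic=classify_diagnostic(fit_mix, fit_avg),
        n_spikes=data.total_spikes,
    )


def selection_table(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Tabulate per-neuron selection results (one row per neuron)."""
    return pd.DataFrame([r.__dict__ for r in results])
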