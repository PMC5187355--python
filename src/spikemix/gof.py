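"""Goodness of fit by time rescaling to uniform residuals.

If the fitted conditional intensity is the true one, the rescaled
interspike intervals ``Z_i = int_{t_i}^{t_{i+1}} lambda ds`` are unit
exponential, and the window total ``Z = int_0^T lambda ds`` is the length
of a unit-rate Poisson observation containing ``N`` events.  Mapping
through the corresponding distribution functions gives residuals that are
uniform on (0, 1) exactly when the model is correct:

* ISI level: ``u_i = 1 - exp(-Z_i)`` for i = 1..N-1 (the interval from
  the window start to the first spike is not an ISI and is excluded;
  window-end censoring enters only at the count level);
* count level: ``u = (F_pois(N | Z) + F_pois(N - 1 | Z)) / 2``, the mean
  of the discrete CDF at N and N-1 (with F_pois(-1) = 0), which
  de-discretizes the Poisson count.

For the mixing model the intensity of a bidirectional trial is the fitted
intensity of the stimulus decoded for that trial (an option uses the
posterior-weighted mixture instead, for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .likelihood import MS_TO_S, ModelParams, NeuronData, intensity_per_bin
from .selection import decode_trials
from .spike_io import SpikeTrain, TrialRecord
from .tuning import BIDIRECTIONAL


@dataclass(frozen=True)
class ResidualSet:
    """Pooled uniform residuals with provenance keys."""

    level: str  # "isi" or "count"
    values: np.ndarray
    neuron_ids: np.ndarray
    conditions: np.ndarray

    def qq(self) -> tuple[np.ndarray, np.ndarray]:
        """(uniform quantiles, sorted residuals) for a QQ plot."""
        n = self.values.size
        return (np.arange(1, n + 1) - 0.5) / n, np.sort(self.values)

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.values, bins=bins, range=(0.0, 1.0))

    def ks_uniform(self) -> tuple[float, float]:
        """KS statistic and p-value against the standard uniform."""
        res = stats.kstest(self.values, "uniform")
        return float(res.statistic), float(res.pvalue)


def rescale_isis(
    train: SpikeTrain,
    lam: np.ndarray,
    correction: str = "randomized",
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescaled ISIs ``Z_i`` and their uniform residuals.

    ``lam`` is the fitted intensity per bin (spikes/s).  Each ``Z_i``
    integrates the intensity over the bins in ``(t_i, t_{i+1}]``; the
    residual is the unit-exponential CDF ``1 - exp(-Z_i)``.  Empty output
    for trains with fewer than two spikes.

    At 1 ms resolution a rescaled ISI is a discrete quantity whose
    residuals cannot be exactly uniform under any deterministic map (the
    probability atoms are a few percent at physiological rates), so three
    treatments are offered:

    * ``"randomized"`` (default): exact per-bin hazard
      ``-log(1 - lambda dt)`` and a uniform draw within each observed
      ISI's probability atom;
    * ``"truncated"``: as ``"randomized"``, additionally conditioning on
      the ISI being observed before the window end -- given the previous
      spike, an observed rescaled ISI is truncated-Exp(1) on
      ``(0, Z_max]``, so dividing the CDF by ``F(Z_max)`` removes the
      finite-window (censoring) bias and is exactly uniform under the
      true model at any window length;
    * ``"midpoint"``: deterministic midpoint of the atom (the same
      de-discretization the count-level residual applies to the Poisson
      CDF);
    * ``"none"``: the plain integral ``sum lambda dt``, the continuous
      formula applied verbatim to binned data.

    The uncorrected variants retain the boundary effect of short windows
    (too many small residuals, since long ISIs are preferentially
    censored); that miscalibration shrinks as the window grows and is
    itself an object of study.
    """
    if correction not in ("randomized", "truncated", "midpoint", "none"):
        raise ValueError(
            "correction must be 'randomized', 'truncated', 'midpoint' or 'none'"
        )
    bins = train.spike_bins()
    if bins.size < 2:
        return np.zeros(0), np.zeros(0)
    mass = lam * train.dt * MS_TO_S
    if correction == "none":
        cum = np.concatenate([[0.0], np.cumsum(mass)])
        # sum over bins b_i+1 .. b_{i+1} inclusive = cum[b_{i+1}+1] - cum[b_i+1]
        Z = cum[bins[1:] + 1] - cum[bins[:-1] + 1]
        return Z, -np.expm1(-Z)
    q = -np.log1p(-np.minimum(mass, 1.0 - 1e-12))
    cum = np.concatenate([[0.0], np.cumsum(q)])
    Z = cum[bins[1:] + 1] - cum[bins[:-1] + 1]
    q_last = q[bins[1:]]
    lo = -np.expm1(-(Z - q_last))  # CDF just below the observed ISI
    hi = -np.expm1(-Z)             # CDF at the observed ISI
    if correction == "midpoint":
        return Z, 0.5 * (lo + hi)
    if rng is None:
        rng = np.random.default_rng(0)
    u = lo + rng.random(Z.size) * (hi - lo)
    if correction == "truncated":
        z_max = cum[-1] - cum[bins[:-1] + 1]  # integrated hazard to window end
        u = u / np.maximum(-np.expm1(-z_max), 1e-300)
    return Z, u


def rescale_counts(
    train: SpikeTrain,
    lam: np.ndarray,
    correction: str = "midpoint",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Count-level uniform residual of one trial.

    ``"midpoint"`` (default) averages the Poisson CDF at ``N`` and
    ``N - 1``; ``"randomized"`` draws uniformly within the atom instead,
    removing the residual discreteness of the midpoint rule.
    """
    if correction not in ("randomized", "midpoint"):
        raise ValueError("correction must be 'randomized' or 'midpoint'")
    Z = float(np.sum(lam) * train.dt * MS_TO_S)
    N = train.n_spikes
    upper = stats.poisson.cdf(N, Z)
    lower = stats.poisson.cdf(N - 1, Z) if N >= 1 else 0.0
    if correction == "midpoint":
        return float(0.5 * (upper + lower))
    if rng is None:
        rng = np.random.default_rng(0)
    return float(lower + rng.random() * (upper - lower))


def trial_intensities(
    records: Sequence[TrialRecord],
    params: ModelParams,
    component: str = "decoded",
) -> list[np.ndarray]:
    """Fitted intensity per bin for every trial.

    ``component`` applies to the mixing model on bidirectional trials:
    ``"decoded"`` uses the posterior-classified stimulus's intensity,
    ``"posterior"`` the posterior-weighted mixture of both intensities.
    """
    if component not in ("decoded", "posterior"):
        raise ValueError("component must be 'decoded' or 'posterior'")
    data = NeuronData(records, m=params.history.m)
    decoded = decode_trials(records, params, data=data) \
        if params.kind == "mixing" else None
    single, comp1, comp2, _ = data._rate_tables(params)
    out = []
    for row, rec in enumerate(records):
        c, k = data.cond[row], data.k[row]
        if np.isnan(comp1[c, k]):
            lam = intensity_per_bin(rec.train, single[c, k], params.history)
        else:
            lam1 = intensity_per_bin(rec.train, comp1[c, k], params.history)
            lam2 = intensity_per_bin(rec.train, comp2[c, k], params.history)
            if component == "decoded":
                lam = lam1 if decoded[row].label == 1 else lam2
            else:
                p1 = decoded[row].posterior_1
                lam = p1 * lam1 + (1.0 - p1) * lam2
        out.append(lam)
    return out


def residuals_for_neuron(
    records: Sequence[TrialRecord],
    params: ModelParams,
    level: str = "isi",
    component: str = "decoded",
    correction: str = "randomized",
    seed: int = 0,
) -> ResidualSet:
    """Uniform residuals of all trials of one neuron under one model."""
    if level not in ("isi", "count"):
        raise ValueError("level must be 'isi' or 'count'")
    lams = trial_intensities(records, params, component)
    rng = np.random.default_rng(seed)
    vals, nids, conds = [], [], []
    for rec, lam in zip(records, lams):
        if level == "isi":
            _, u = rescale_isis(rec.train, lam, correction=correction, rng=rng)
            vals.append(u)
            nids += [rec.neuron_id] * u.size
            conds += [rec.condition] * u.size
        else:
            c = correction if correction != "none" else "midpoint"
            vals.append(np.array([rescale_counts(rec.train, lam, correction=c, rng=rng)]))
            nids.append(rec.neuron_id)
            conds.append(rec.condition)
    values = np.concatenate(vals) if vals else np.zeros(0)
    return ResidualSet(level, values, np.array(nids), np.array(conds))


def pooled_residuals(
    items: Iterable[tuple[Sequence[TrialRecord], ModelParams]],
    level: str = "isi",
    subset: Optional[Sequence[str]] = None,
    component: str = "decoded",
    correction: str = "randomized",
    seed: int = 0,
) -> ResidualSet:
    """Merge residuals across neurons, optionally restricted to conditions.

    ``subset`` filters by condition (e.g. ``("attend-fix", "attend-in")``
    pools bidirectional data only).  Raises on an empty result.
    """
    parts = []
    for i, (records, params) in enumerate(items):
        recs = list(records)
        if subset is not None:
            recs = [r for r in recs if r.condition in subset]
        if recs:
            parts.append(
                residuals_for_neuron(recs, params, level, component, correction,
                                     seed=seed + i)
            )
    if not parts or sum(p.values.size for p in parts) == 0:
        raise ValueError("no residuals in the requested subset")
    return ResidualSet(
        level,
        np.concatenate([p.values for p in parts]),
        np.concatenate([p.neuron_ids for p in parts]),
        np.concatenate([p.conditions for p in parts]),
    )
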