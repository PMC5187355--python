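"""Auxiliary statistics: ISI dip tests, pair correlations, split-half check.

The dip test probes whether interspike-interval distributions become
multimodal when two stimuli share the receptive field: probability-mixing
with well-separated component rates produces a mixture of short and long
ISIs (multimodal), whereas response-averaging predicts a single-rate ISI
distribution (unimodal).  Dip p-values are calibrated by bootstrap
against the uniform null -- the least favorable unimodal distribution --
with a fixed seed, rather than by interpolation tables.

Firing-rate dip tests are deliberately not offered: empirical rates from
short windows take only a few discrete values, which defeats the test;
only ISI-level tests are meaningful at these sample sizes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import dip_many, dip_sorted
from .likelihood import MS_TO_S
from .spike_io import TrialRecord, group_by_neuron
from .tuning import BIDIRECTIONAL, UNIDIRECTIONAL

MIN_DIP_SAMPLE = 4


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its bootstrap p-value (NaN = not testable)."""

    statistic: float
    p_value: float
    n: int

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p_value)


def dip_statistic(sample: Sequence[float]) -> float:
    """Hartigan & Hartigan's dip statistic of a sample."""
    x = np.sort(np.asarray(sample, dtype=float))
    return float(dip_sorted(x))


def dip_test(
    sample: Sequence[float],
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> DipResult:
    """Dip test of unimodality with bootstrap-calibrated p-value.

    The null distribution of the dip is simulated from ``n_boot`` uniform
    samples of the same size; ``p = (1 + #{dip_boot >= dip_obs}) /
    (n_boot + 1)``.  Samples smaller than 4 or with a single distinct
    value are not testable and get a NaN p-value marker.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < MIN_DIP_SAMPLE or np.unique(x).size < 2:
        return DipResult(np.nan, np.nan, n)
    obs = dip_statistic(x)
    if rng is None:
        rng = np.random.default_rng(seed)
    boot = np.sort(rng.random((n_boot, n)), axis=1)
    null = dip_many(boot)
    p = (1.0 + np.count_nonzero(null >= obs)) / (n_boot + 1.0)
    return DipResult(obs, float(p), n)


# ---------------------------------------------------------------------------
# ISI dip grid over neurons x direction configurations
# ---------------------------------------------------------------------------


def _cell_isis(records: Sequence[TrialRecord]) -> np.ndarray:
    """Pool ISIs (ms) across the trials of one cell."""
    parts = [r.train.isis() for r in records if r.train.n_spikes >= 2]
    return np.concatenate(parts) if parts else np.zeros(0)


def _mean_rate(records: Sequence[TrialRecord]) -> float:
    """Mean firing rate (spikes/ms) of a cell, spikes over observed time."""
    n = sum(r.train.n_spikes for r in records)
    t_ms = sum(r.train.T for r in records)
    return n / t_ms if t_ms > 0 else 0.0


def normalized_unidirectional_isis(records: Sequence[TrialRecord]) -> np.ndarray:
    """fix1 + fix2 ISIs of one neuron x direction cell, rate-normalized.

    Each condition's ISIs are multiplied by that condition's mean firing
    rate before pooling, so both contribute mean-1 ISIs; this avoids
    artificial bimodality caused merely by different response strengths in
    the two apertures.
    """
    parts = []
    for cond in UNIDIRECTIONAL:
        recs = [r for r in records if r.condition == cond]
        isis = _cell_isis(recs)
        if isis.size:
            parts.append(isis * _mean_rate(recs))
    return np.concatenate(parts) if parts else np.zeros(0)


def dip_grid(
    records: Sequence[TrialRecord],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dip tests per (neuron, direction configuration, stimulus group).

    Groups: ``uni`` pools rate-normalized fix1+fix2 ISIs; ``attend-fix``
    and ``attend-in`` are tested raw (bidirectional conditions are not
    normalized).  Returns one row per cell with the dip statistic,
    bootstrap p-value, significance at ``alpha`` and sample size;
    untestable cells keep NaN p-values.
    """
    rows = []
    ss_root = np.random.SeedSequence(seed)
    for nid, nrecs in group_by_neuron(records).items():
        ks = sorted({r.direction_index for r in nrecs})
        for k in ks:
            cell = [r for r in nrecs if r.direction_index == k]
            groups = {}
            uni = [r for r in cell if r.condition in UNIDIRECTIONAL]
            if uni:
                groups["uni"] = normalized_unidirectional_isis(uni)
            for cond in BIDIRECTIONAL:
                recs = [r for r in cell if r.condition == cond]
                if recs:
                    groups[cond] = _cell_isis(recs)
            for gname, isis in groups.items():
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, zlib.crc32(nid.encode()), k,
                                            ("uni", "attend-fix", "attend-in").index(gname)])
                )
                res = dip_test(isis, n_boot=n_boot, rng=rng)
                rows.append({
                    "neuron_id": nid, "direction_index": k, "group": gname,
                    "n_isis": res.n, "dip": res.statistic, "p_value": res.p_value,
                    "significant": bool(res.testable and res.p_value < alpha),
                    "testable": res.testable,
                })
    return pd.DataFrame(rows)


def dip_grid_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Fraction of significant dip tests per stimulus group."""
    out = []
    for gname, sub in grid.groupby("group"):
        testable = sub[sub["testable"]]
        out.append({
            "group": gname,
            "n_tests": len(testable),
            "n_significant": int(testable["significant"].sum()),
            "fraction_significant": float(testable["significant"].mean())
            if len(testable) else np.nan,
        })
    return pd.DataFrame(out)


def dip_transition_map(grid: pd.DataFrame) -> pd.DataFrame:
    """Significance transitions from unidirectional to bidirectional cells.

    For each (neuron, direction, bidirectional group) with a testable
    unidirectional counterpart, classifies the pair into sig->sig,
    sig->ns, ns->sig or ns->ns.
    """
    uni = grid[(grid["group"] == "uni") & grid["testable"]]
    uni_sig = {(r.neuron_id, r.direction_index): r.significant
               for r in uni.itertuples()}
    rows = []
    for r in grid[grid["group"].isin(BIDIRECTIONAL) & grid["testable"]].itertuples():
        key = (r.neuron_id, r.direction_index)
        if key not in uni_sig:
            continue
        a, b = uni_sig[key], r.significant
        cat = ("sig" if a else "ns") + "->" + ("sig" if b else "ns")
        rows.append({"neuron_id": r.neuron_id, "direction_index": r.direction_index,
                     "group": r.group, "transition": cat})
    return pd.DataFrame(rows)


def dip_type_i_calibration(
    n_neurons: int = 1000,
    rate: float = 20.0,
    n_trials: int = 16,
    window_ms: float = 500.0,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I rate of the dip test under a unimodal null.

    Simulates ``n_neurons`` constant-rate neurons (no history effects),
    each contributing ``n_trials`` unidirectional trains of
    ``window_ms``; pools each neuron's rate-normalized ISIs and runs the
    bootstrap-calibrated dip test per neuron.  Under the single-rate null
    the ISI distribution is unimodal (geometric at 1 ms resolution), so
    the fraction of rejections at ``alpha`` estimates the test's level.

    Returns a dict with ``rejection_rate``, ``n_tested``, ``alpha`` and
    the 95% binomial band around ``alpha`` for ``n_tested`` tests.
    """
    from ._kernels import simulate_bernoulli

    n_bins = int(round(window_ms))
    n_sig = 0
    n_tested = 0
    root = np.random.SeedSequence(seed)
    for i in range(n_neurons):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, i]))
        u = rng.random((n_trials, n_bins))
        spikes, _ = simulate_bernoulli(
            u, np.full(n_trials, rate), 0.0, np.zeros(1), 1.0
        )
        isis = []
        for j in range(n_trials):
            t = np.flatnonzero(spikes[j]) + 1.0  # spike times, ms
            if t.size >= 2:
                isis.append(np.diff(t))
        if not isis:
            continue
        isis = np.concatenate(isis)
        total_spikes = int(spikes.sum())
        mean_rate = total_spikes / (n_trials * n_bins)  # spikes/ms
        sample = isis * mean_rate
        res = dip_test(sample, n_boot=n_boot, rng=rng)
        if res.testable:
            n_tested += 1
            if res.p_value < alpha:
                n_sig += 1
    rej = n_sig / n_tested if n_tested else np.nan
    se = np.sqrt(alpha * (1 - alpha) / n_tested) if n_tested else np.nan
    return {
        "rejection_rate": rej,
        "n_tested": n_tested,
        "n_significant": n_sig,
        "alpha": alpha,
        "binomial_band": (alpha - 1.96 * se, alpha + 1.96 * se),
    }


# ---------------------------------------------------------------------------
# Pairwise trial-by-trial correlations
# ---------------------------------------------------------------------------


def pair_correlations(
    records_a: Sequence[TrialRecord],
    records_b: Sequence[TrialRecord],
    min_trials: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of two neurons' per-trial firing rates.

    Trials are aligned by (condition, direction, trial index); the two
    attention conditions are pooled per direction configuration to
    enlarge the sample.  If both neurons tend to respond to the same
    stimulus on the same trial the rates correlate positively (or
    negatively when their preferred directions make the rate orderings
    oppose).  Cells with fewer than ``min_trials`` aligned trials are
    marked untestable.
    """
    by_key_b = {(r.condition, r.direction_index, r.trial_index): r for r in records_b}
    cells: dict = {}
    for ra in records_a:
        if ra.condition not in BIDIRECTIONAL:
            continue
        rb = by_key_b.get((ra.condition, ra.direction_index, ra.trial_index))
        if rb is None:
            continue
        cells.setdefault(ra.direction_index, []).append((ra, rb))
    rows = []
    for k in sorted(cells):
        pairs = cells[k]
        x = np.array([ra.train.n_spikes / (ra.train.T * MS_TO_S) for ra, _ in pairs])
        y = np.array([rb.train.n_spikes / (rb.train.T * MS_TO_S) for _, rb in pairs])
        if len(pairs) < min_trials or np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"direction_index": k, "n_trials": len(pairs),
                         "rho": np.nan, "p_value": np.nan,
                         "significant": False, "testable": False})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"direction_index": k, "n_trials": len(pairs),
                     "rho": float(rho), "p_value": float(p),
                     "significant": bool(p < alpha), "testable": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split-half stationarity comparison
# ---------------------------------------------------------------------------


def split_half_comparison(records: Sequence[TrialRecord], fit_options=None,
                          seed: int = 0) -> dict:
    """Re-run fitting and selection on each half-window; paired test of deltas.

    Splits every train into its 0-250 ms and 250-500 ms halves, fits both
    models per neuron on each half, and applies a paired two-sided
    Wilcoxon signed-rank test to the per-neuron differences
    ``delta_AIC`` (and ``delta_BIC``) between halves; under stationarity
    the criterion differences should not change between halves.  Neurons
    with a spikeless half are dropped from the paired test.
    """
    from .fitting import fit_both_models
    from .selection import select_neuron
    from .spike_io import split_half_records

    first, second = split_half_records(records)
    rows = []
    dropped = []
    for nid in group_by_neuron(records):
        halves = {}
        ok = True
        for name, recs in (("first", first), ("second", second)):
            nrecs = [r for r in recs if r.neuron_id == nid]
            if sum(r.train.n_spikes for r in nrecs) == 0:
                ok = False
                break
            fm, fa = fit_both_models(nrecs, fit_options)
            sel = select_neuron(nrecs, fm, fa, compute_rmsd=False)
            halves[name] = sel
        if not ok:
            dropped.append(nid)
            continue
        rows.append({
            "neuron_id": nid,
            "delta_aic_first": halves["first"].delta_aic,
            "delta_aic_second": halves["second"].delta_aic,
            "delta_bic_first": halves["first"].delta_bic,
            "delta_bic_second": halves["second"].delta_bic,
        })
    table = pd.DataFrame(rows)
    out = {"table": table, "dropped_neurons": dropped,
           "p_aic": np.nan, "p_bic": np.nan}
    if len(table) >= 2:
        for crit in ("aic", "bic"):
            d1 = table[f"delta_{crit}_first"].to_numpy()
            d2 = table[f"delta_{crit}_second"].to_numpy()
            diff = d1 - d2
            if np.allclose(diff, 0.0):
                out[f"p_{crit}"] = 1.0
            else:
                # exact null distribution for small cohorts
                method = "exact" if len(diff) < 26 else "auto"
                res = stats.wilcoxon(d1, d2, alternative="two-sided", method=method)
                out[f"p_{crit}"] = float(res.pvalue)
    return out
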