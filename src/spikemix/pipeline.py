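"""Orchestration: simulate/load -> fit -> select -> GOF -> auxiliary stats.

Drives the full analysis on a spike table (simulated or measured) and
collects machine-readable outputs: per-neuron fits and selection rows,
pooled uniform residuals, the ISI dip grid, and cross-neuron parameter
summaries.  Failures are isolated per neuron -- one pathological neuron
is tabulated and skipped rather than aborting the cohort.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import design as design_mod
from .aux_stats import dip_grid, dip_grid_summary, dip_transition_map
from .fitting import FitOptions, FitResult, fit_both_models, params_to_raw
from .gof import pooled_residuals
from .selection import SelectionResult, select_neuron, selection_table
from .spike_io import TrialRecord, group_by_neuron, read_spike_table, write_spike_table
from .tuning import BIDIRECTIONAL

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """What to run and where to put it; serialized alongside the outputs."""

    table_path: Optional[str] = None     # load data from a spike table ...
    simulate: Optional[dict] = None      # ... or simulate: {model, neurons, seed, window}
    out_dir: Optional[str] = None
    seed: int = 0
    stages: tuple = ("fit", "select", "gof", "dip")
    fit_options: FitOptions = field(default_factory=FitOptions)
    rmsd_folds: int = 10
    dip_n_boot: int = 2000
    compute_rmsd: bool = True


def _simulate_from_config(cfg: RunConfig):
    sim = dict(cfg.simulate or {})
    model = sim.get("model", "mixing")
    n_neurons = int(sim.get("neurons", 1))
    seed = int(sim.get("seed", cfg.seed))
    overrides = {}
    if "window" in sim:
        overrides["window_length"] = float(sim["window"])
    if "trials_scale" in sim:
        s = int(sim["trials_scale"])
        overrides["trials_per_cell"] = {
            c: m * s for c, m in design_mod.DEFAULT_TRIALS.items()
        }
    des = design_mod.build_design(seed=seed, **overrides)
    if sim.get("heterogeneous", True) and n_neurons > 1:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
        truths = [design_mod.sample_ground_truth(rng, model) for _ in range(n_neurons)]
    else:
        truths = [design_mod.default_ground_truth(model)] * n_neurons
    records, labels = design_mod.simulate_dataset(des, truths, n_neurons, seed=seed)
    return records, labels, truths


def fit_params_record(fit: FitResult) -> dict:
    """JSON-serializable summary of one fit."""
    p = fit.params
    rec = {
        "kind": p.kind,
        "loglik": fit.loglik.value,
        "n_params": fit.n_params,
        "converged": fit.converged,
        "n_evals": fit.n_evals,
        "A1": p.tuning.A1, "sigma1": p.tuning.sigma1,
        "A2": p.tuning.A2, "sigma2": p.tuning.sigma2, "r0": p.tuning.r0,
        "p_attend_fix": p.attn.p_attend_fix,
        "gamma0": p.history.gamma0,
        "gammas": list(map(float, p.history.gammas)),
    }
    if p.kind == "mixing":
        rec.update(p_attend_in=p.attn.p_attend_in, a1=p.attn.a1, a2=p.attn.a2)
    else:
        rec.update(b1=p.attn.b1, b2=p.attn.b2)
    return rec


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the report bundle as a dict.

    Keys (when their stage ran): ``records``, ``fits`` (neuron ->
    (mixing, averaging) FitResult), ``selection`` (DataFrame),
    ``residuals_all`` / ``residuals_bidirectional`` (count-level pooled
    ResidualSet), ``dip_grid`` / ``dip_summary`` / ``dip_transitions``,
    ``parameter_summaries``, ``summary`` (aggregate dict), ``failures``.
    """
    t_start = time.perf_counter()
    if (config.table_path is None) == (config.simulate is None):
        raise ValueError("exactly one of table_path or simulate must be given")
    if config.table_path is not None:
        records, report = read_spike_table(config.table_path)
        labels = {}
    else:
        records, labels, _ = _simulate_from_config(config)
        report = {}
    out: dict = {"records": records, "latent_labels": labels, "io_report": report}
    by_neuron = group_by_neuron(records)
    failures: list = []

    fits: dict = {}
    if "fit" in config.stages:
        for nid, nrecs in by_neuron.items():
            try:
                fits[nid] = fit_both_models(nrecs, config.fit_options)
            except Exception as err:  # per-neuron isolation
                logger.exception("fit failed for neuron %s", nid)
                failures.append({"neuron_id": nid, "stage": "fit", "error": str(err)})
        out["fits"] = fits

    if "select" in config.stages and fits:
        rows = []
        for nid, (fm, fa) in fits.items():
            try:
                rows.append(
                    select_neuron(by_neuron[nid], fm, fa, folds=config.rmsd_folds,
                                  seed=config.seed, options=config.fit_options,
                                  compute_rmsd=config.compute_rmsd)
                )
            except Exception as err:
                logger.exception("selection failed for neuron %s", nid)
                failures.append({"neuron_id": nid, "stage": "select", "error": str(err)})
        sel = selection_table(rows)
        out["selection"] = sel
        out["summary"] = {
            "n_neurons": len(by_neuron),
            "n_fitted": len(fits),
            "aggregate_delta_aic": float(sel["delta_aic"].sum()) if len(sel) else np.nan,
            "aggregate_delta_bic": float(sel["delta_bic"].sum()) if len(sel) else np.nan,
            "fraction_delta_aic_negative": float((sel["delta_aic"] < 0).mean())
            if len(sel) else np.nan,
            "n_diagnostic": int(sel["diagnostic"].sum()) if len(sel) else 0,
        }
        if len(sel):
            from .selection import model_weight
            d = out["summary"]["aggregate_delta_aic"]
            out["summary"]["aggregate_weight_mixing_aic"] = model_weight(-d)

    if "gof" in config.stages and fits:
        items_mix = [(by_neuron[nid], fits[nid][0].params) for nid in fits]
        items_avg = [(by_neuron[nid], fits[nid][1].params) for nid in fits]
        for label, items in (("mixing", items_mix), ("averaging", items_avg)):
            out[f"residuals_count_{label}"] = pooled_residuals(items, level="count")
            out[f"residuals_isi_{label}"] = pooled_residuals(items, level="isi")
            out[f"residuals_count_bidirectional_{label}"] = pooled_residuals(
                items, level="count", subset=BIDIRECTIONAL
            )

    if "dip" in config.stages:
        grid = dip_grid(records, n_boot=config.dip_n_boot, seed=config.seed)
        out["dip_grid"] = grid
        out["dip_summary"] = dip_grid_summary(grid)
        out["dip_transitions"] = dip_transition_map(grid)

    if fits:
        out["parameter_summaries"] = report_parameter_summaries(fits)
    out["failures"] = failures
    out["runtime_s"] = time.perf_counter() - t_start

    if config.out_dir is not None:
        _write_bundle(out, config)
    return out


def report_parameter_summaries(fits: dict) -> dict:
    """Cross-neuron parameter tables from both models' fits.

    Returns a dict of DataFrames: ``history`` (median and central 50%/80%
    intervals of gamma_1..gamma_m across neurons, per model),
    ``amplitudes`` (A + r0 per aperture and model), ``attention``
    (p_attend_fix vs p_attend_in, a1 vs a2, mixing only) and
    ``b_consistency`` (averaging b1, b2 vs the values implied by the
    mixing estimates).
    """
    hist_rows, amp_rows, attn_rows, b_rows = [], [], [], []
    for nid, (fm, fa) in fits.items():
        for fit in (fm, fa):
            p = fit.params
            for lag, g in enumerate(p.history.gammas, start=1):
                hist_rows.append({"neuron_id": nid, "model": p.kind,
                                  "lag": lag, "gamma": float(g)})
            amp_rows.append({"neuron_id": nid, "model": p.kind,
                             "A1_plus_r0": p.tuning.A1 + p.tuning.r0,
                             "A2_plus_r0": p.tuning.A2 + p.tuning.r0})
        pm = fm.params.attn
        attn_rows.append({"neuron_id": nid, "p_attend_fix": pm.p_attend_fix,
                          "p_attend_in": pm.p_attend_in, "a1": pm.a1, "a2": pm.a2})
        pa = fa.params.attn
        b_rows.append({"neuron_id": nid,
                       "b1_averaging": pa.b1, "b2_averaging": pa.b2,
                       "b1_from_mixing": pm.p_attend_in * pm.a1,
                       "b2_from_mixing": (1.0 - pm.p_attend_in) * pm.a2})
    hist = pd.DataFrame(hist_rows)
    history_summary = (
        hist.groupby(["model", "lag"])["gamma"]
        .agg(median="median",
             q10=lambda s: s.quantile(0.10), q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75), q90=lambda s: s.quantile(0.90))
        .reset_index()
    )
    return {
        "history": history_summary,
        "history_raw": hist,
        "amplitudes": pd.DataFrame(amp_rows),
        "attention": pd.DataFrame(attn_rows),
        "b_consistency": pd.DataFrame(b_rows),
    }


def _write_bundle(out: dict, config: RunConfig) -> None:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_spike_table(out["records"], d / "spike_table.csv")
    if out.get("latent_labels"):
        with open(d / "latent_labels.json", "w") as fh:
            json.dump({" ".join(map(str, k)): v for k, v in out["latent_labels"].items()}, fh)
    if "fits" in out:
        with open(d / "fits.json", "w") as fh:
            json.dump(
                {nid: {"mixing": fit_params_record(fm), "averaging": fit_params_record(fa)}
                 for nid, (fm, fa) in out["fits"].items()},
                fh, indent=1,
            )
    for key in ("selection", "dip_grid", "dip_summary", "dip_transitions"):
        if key in out and isinstance(out[key], pd.DataFrame):
            out[key].to_csv(d / f"{key}.csv", index=False)
    if "parameter_summaries" in out:
        for name, df in out["parameter_summaries"].items():
            df.to_csv(d / f"params_{name}.csv", index=False)
    for key in list(out):
        if key.startswith("residuals_"):
            rs = out[key]
            pd.DataFrame({"residual": rs.values, "neuron_id": rs.neuron_ids,
                          "condition": rs.conditions}).to_csv(d / f"{key}.csv", index=False)
    if "summary" in out:
        with open(d / "summary.json", "w") as fh:
            json.dump(out["summary"], fh, indent=1, sort_keys=True)
    with open(d / "run_config.json", "w") as fh:
        cfg = asdict(config)
        cfg["fit_options"] = asdict(config.fit_options)
        json.dump(cfg, fh, indent=1, sort_keys=True, default=str)
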