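"""Pipeline orchestration: simulate -> behavior -> selectivity ->
decoding -> temporal, from one config, with provenance and a
JSON/markdown report.

Stages run in dependency order; disabling the selectivity stage makes
decoding fall back to all included neurons (noted in the report).  All
outputs land under one run directory with a manifest; reruns with the
same config and seed produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import summarize_behavior, test_above_chance
from .datasets import read_dataset, write_dataset
from .decoding import DecodingProtocol, decode_population, sampler_for
from .selectivity import analyze_selectivity
from .simulate import PopulationPriors, TaskConfig, generate_experiment
from .temporal import cluster_permutation_test, cross_temporal_matrix, \
    pev_timecourse
from .datasets import BinScheme


@dataclass
class RunConfig:
    """One config object driving every stage.

    Round-trips through YAML/JSON (``to_dict``/``from_dict``); every
    stochastic stage derives its seed from ``seed``.
    """

    out_dir: str = "numopop_run"
    seed: int = 0
    data_dir: str | None = None            # None -> simulate
    stages: list = field(default_factory=lambda: [
        "simulate", "behavior", "selectivity", "decoding", "temporal"])
    task: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    alpha: float = 0.01
    min_run: int = 11
    chance: float = 12.5
    decoding: dict = field(default_factory=lambda: dict(
        trials_per_class=20, folds=10, resamples=100, n_null=100))
    temporal: dict = field(default_factory=lambda: dict(
        n_resamples=10, n_shuffles=5, n_redraws=2, n_bins=30))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(),
                    "version": __version__,
                    "config_hash": hashlib.sha256(
                        json.dumps(config.to_dict(), sort_keys=True)
                        .encode()).hexdigest()[:16],
                    "stages": {}, "notes": []}

    # -- data --------------------------------------------------------------
    if "simulate" in config.stages or config.data_dir is None:
        task = TaskConfig(rng_seed=config.seed, **config.task)
        priors = PopulationPriors(**config.priors)
        ds, truth = generate_experiment(task, priors)
        write_dataset(ds, out / "dataset")
        (out / "ground_truth.json").write_text(truth.to_json())
        report["stages"]["simulate"] = {
            "n_trials": int(len(ds.trials)),
            "n_neurons": int(len(ds.neurons)),
            "n_spikes": int(len(ds.spikes))}
    else:
        ds = read_dataset(config.data_dir)
        report["stages"]["simulate"] = {"source": config.data_dir}

    # -- behavior ----------------------------------------------------------
    if "behavior" in config.stages:
        summary = summarize_behavior(ds.trials, chance=config.chance)
        above = test_above_chance(ds.trials, chance=config.chance)
        report["stages"]["behavior"] = {
            "percent_correct": summary.per_session.to_dict(orient="records"),
            "included_sessions": summary.included_sessions,
            "chance_level": summary.chance_level,
            "n_strata_above_chance": int(
                (above["p"] < 0.05).sum()) if len(above) else 0,
            "n_strata": int(len(above))}

    # -- selectivity -------------------------------------------------------
    selective_ids = None
    if "selectivity" in config.stages:
        sel = analyze_selectivity(ds, alpha=config.alpha,
                                  min_run=config.min_run)
        sel.to_csv(out / "selectivity.csv", index=False)
        selective_ids = sel.loc[sel["selective"], "neuron_id"].tolist()
        report["stages"]["selectivity"] = {
            "n_neurons": int(len(sel)),
            "n_included": int(sel["included"].sum()),
            "n_selective": int(sel["selective"].sum()),
            "n_excited": int((sel["sign"] == "excited").sum()),
            "n_inhibited": int((sel["sign"] == "inhibited").sum())}

    # -- decoding ----------------------------------------------------------
    if "decoding" in config.stages:
        dcfg = dict(config.decoding)
        n_null = dcfg.pop("n_null", 100)
        protocol = DecodingProtocol(rng_seed=config.seed + 1, **dcfg)
        window = (ds.meta["instruction_ms"] + 100.0,
                  ds.meta["instruction_ms"] + ds.meta["planning_ms"])
        ids = selective_ids
        if not ids:
            ids = list(ds.neuron_ids)
            report["notes"].append(
                "decoding used all neurons (selectivity stage disabled "
                "or no selective neurons)")
        sampler = sampler_for(ds, window, ids,
                              min_trials_per_class=protocol.trials_per_class)
        res = decode_population(sampler, protocol, n_null=n_null)
        report["stages"]["decoding"] = {
            "accuracy": res.accuracy, "sem": res.sem,
            "per_class": res.per_class.tolist(),
            "confusion": res.confusion.tolist(),
            "null_mean": float(np.mean(res.null_accuracies))
            if res.null_accuracies is not None else None,
            "null_95": res.null_95,
            "n_neurons": len(sampler.neuron_ids)}

    # -- temporal ----------------------------------------------------------
    if "temporal" in config.stages:
        tcfg = config.temporal
        rng = np.random.default_rng(config.seed + 2)
        end = ds.meta["instruction_ms"] + ds.meta["planning_ms"] + 100.0
        step = max(20.0, (end + 300.0 - 200.0) / max(tcfg["n_bins"] - 1, 1))
        scheme = BinScheme(start_ms=-300.0, end_ms=end, width_ms=200.0,
                           step_ms=step)
        trace = pev_timecourse(ds, scheme=scheme,
                               n_resamples=tcfg["n_resamples"],
                               n_shuffles=tcfg["n_shuffles"], rng=rng)
        mat = cross_temporal_matrix(
            ds, scheme=scheme, n_redraws=tcfg["n_redraws"],
            n_shuffles=max(tcfg["n_shuffles"], 20 // max(
                tcfg["n_redraws"], 1)), rng=rng)
        clusters = cluster_permutation_test(mat.accuracy, mat.null) \
            if mat.null is not None and len(mat.null) >= 20 else []
        report["stages"]["temporal"] = {
            "times": trace.times.tolist(),
            "pev_number": trace.mean["number"].tolist(),
            "pev_format": trace.mean["format"].tolist(),
            "pev_threshold_number":
                trace.null_threshold["number"].tolist(),
            "xt_accuracy": mat.accuracy.tolist(),
            "n_significant_clusters": len(clusters),
            "cluster_sizes": [c.size for c in clusters]}

    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_json_default))
    (out / "report.md").write_text(make_report(report))
    return report


def make_report(report: dict) -> str:
    """Render the stage outputs as a small markdown summary."""
    lines = ["# numopop run report", "",
             f"config hash: `{report.get('config_hash', '')}`  ",
             f"package version: {report.get('version', '')}", ""]
    stages = report.get("stages", {})
    if "behavior" in stages:
        b = stages["behavior"]
        lines += ["## Behavior",
                  f"- chance level: {b['chance_level']:.1f}%",
                  f"- sessions included: {len(b['included_sessions'])}",
                  f"- strata above chance (p<0.05): "
                  f"{b['n_strata_above_chance']}/{b['n_strata']}", ""]
    if "selectivity" in stages:
        s = stages["selectivity"]
        lines += ["## Selectivity",
                  f"- neurons: {s['n_neurons']} "
                  f"(included {s['n_included']})",
                  f"- numerosity-selective: {s['n_selective']} "
                  f"({s['n_excited']} excited, {s['n_inhibited']} "
                  "inhibited)", ""]
    if "decoding" in stages:
        d = stages["decoding"]
        lines += ["## Decoding",
                  f"- accuracy: {100 * d['accuracy']:.1f}% "
                  f"(+- {100 * d['sem']:.2f} SEM, "
                  f"{d['n_neurons']} neurons)",
                  f"- shuffle null 95th pct: "
                  f"{100 * (d['null_95'] or 0):.1f}%", ""]
    if "temporal" in stages:
        t = stages["temporal"]
        lines += ["## Temporal population",
                  f"- peak number PEV: {max(t['pev_number']):.2f}%",
                  f"- significant cross-temporal clusters: "
                  f"{t['n_significant_clusters']}", ""]
    for note in report.get("notes", []):
        lines.append(f"> note: {note}")
    return "\n".join(lines) + "\n"
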