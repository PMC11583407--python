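"""End-to-end pipeline: simulate -> annotate -> reliability -> bias ->
match -> ewas -> clocks -> report, driven by a YAML configuration.

Each stage consumes the synthetic dataset (or previously written inputs),
writes its outputs under the configured directory, and logs its timing.
Stages not named in the configuration are skipped; a stage failure halts
the run with the stage name.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationConfig, generate_dataset, write_dataset
from .manifests import intersect_probes, detect_snp_mismatches, base_id
from .reliability import reliability_table
from .array_bias import array_bias_table, summarize_bias
from .sample_match import (call_genotypes, match_samples,
                           recommend_exclusions, assignment_accuracy)
from .ewas import fit_ewas, cross_array_overlap, compare_effects
from .clocks import estimate_age, compare_estimates
from .report import build_report, write_report, classify_mqtl

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "annotate", "reliability", "bias", "match",
              "ewas", "clocks", "report")


def run_pipeline(config: Mapping | str | Path, outdir=None) -> Path:
    """Execute the configured stages in dependency order; returns the outdir."""
    if not isinstance(config, Mapping):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"pipeline config not found: {path}")
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
    out = Path(outdir or config.get("outdir", "methcompare_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = int(config.get("seed", 0))

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, seed, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %-12s done in %.2fs", stage,
                    time.perf_counter() - t0)
    with open(out / "provenance.json", "w") as fh:
        json.dump({"version": __version__, "seed": seed, "stages": stages},
                  fh, indent=1)
    return out


def _stage_simulate(config, seed, out, state):
    sim_cfg = dict(config.get("simulate", {}))
    sim_cfg.setdefault("seed", seed)
    cfg = SimulationConfig(**sim_cfg)
    ds = generate_dataset(cfg)
    state["dataset"] = ds
    write_dataset(ds, out / "simulated")


def _require_dataset(state):
    if "dataset" not in state:
        raise ValueError("this stage requires the simulate stage")
    return state["dataset"]


def _stage_annotate(config, seed, out, state):
    ds = _require_dataset(state)
    overlap = intersect_probes(ds.manifests)
    with open(out / "overlap.json", "w") as fh:
        json.dump({"+".join(sorted(k)): v for k, v in overlap["counts"].items()},
                  fh, indent=1)
    report = detect_snp_mismatches(ds.manifests)
    report.to_csv(out / "snp_mismatches.csv")
    state["overlap"] = overlap
    state["mismatch"] = report


def _primary_beta(ds, array):
    """Beta matrix restricted to primary (non-replicate) donor columns,
    indexed by donor id and base probe id (replicate probes averaged)."""
    sheet = ds.samples[array]
    prim = sheet[~sheet["is_replicate"].astype(bool)]
    beta = ds.betas[array][prim["position_id"].tolist()].copy()
    beta.columns = prim["donor_id"].tolist()
    beta.index = [base_id(p) for p in beta.index]
    return beta.groupby(level=0, sort=False).mean()


def _stage_reliability(config, seed, out, state):
    ds = _require_dataset(state)
    tables = {}
    for a in ds.betas:
        tab = reliability_table(ds.betas[a], ds.samples[a])
        tab.to_csv(out / f"reliability_{a}.csv", index_label="probe_id")
        tables[a] = tab
    state["reliability"] = tables


def _stage_bias(config, seed, out, state):
    ds = _require_dataset(state)
    betas = {a: _primary_beta(ds, a) for a in ds.betas}
    sheets = {a: ds.samples[a] for a in ds.betas}
    shared = list(ds.truth.shared_probes)
    table = array_bias_table(betas, sheets, probes=shared)
    table.to_csv(out / "array_bias.csv", index_label="probe_id")
    with open(out / "bias_summary.json", "w") as fh:
        json.dump(summarize_bias(table), fh, indent=1)
    state["bias"] = table


def _stage_match(config, seed, out, state):
    ds = _require_dataset(state)
    calls = {}
    for a in ds.betas:
        rs_rows = [p for p in ds.betas[a].index if base_id(p).startswith("rs")]
        calls[a] = call_genotypes(ds.betas[a].loc[rs_rows])
    mismatch = state.get("mismatch")
    if mismatch is None:
        mismatch = detect_snp_mismatches(ds.manifests)
    exclude = recommend_exclusions(mismatch)
    result = match_samples(calls, exclude=exclude)
    result.pairwise.to_csv(out / "match_pairs.csv", index=False)
    result.assignment.to_csv(out / "match_assignment.csv", index=False)
    (out / "match_dendrogram.nwk").write_text(result.newick + "\n")
    donor_of = {}
    for a in ds.samples:
        for _, row in ds.samples[a].iterrows():
            donor_of[row["position_id"]] = row["donor_id"]
    state["match"] = result
    state["match_accuracy"] = assignment_accuracy(result.assignment, donor_of)


def _stage_ewas(config, seed, out, state):
    ds = _require_dataset(state)
    results = {}
    for a in ds.betas:
        beta = _primary_beta(ds, a).loc[ds.truth.shared_probes]
        res = fit_ewas(beta, ds.truth.sample_sex, group_levels=("M", "F"))
        res.to_csv(out / f"ewas_{a}.csv", index_label="probe_id")
        results[a] = res
    report = cross_array_overlap(results)
    arrays = list(results)
    sig = set()
    for a in arrays:
        sig |= set(results[a].index[results[a]["p_value"] < 1e-8])
    report["pairs"] = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            if len(sig) >= 3:
                cmp = compare_effects(results[a], results[b], sorted(sig))
                cmp.pop("discordant")
                report["pairs"][f"{a}|{b}"] = cmp
    with open(out / "ewas_concordance.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    state["ewas"] = results


def _stage_clocks(config, seed, out, state):
    ds = _require_dataset(state)
    rows = []
    per_clock: dict = {}
    for name, clock in ds.truth.clock_truth.items():
        per_clock[name] = {}
        for a in ds.betas:
            beta = _primary_beta(ds, a)
            est = estimate_age(beta, clock)
            est["array"] = a
            rows.append(est.reset_index())
            per_clock[name][a] = est["estimate"]
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(out / "clock_estimates.csv",
                                                  index=False)
        cmp = pd.concat([compare_estimates(v).assign(clock=k)
                         for k, v in per_clock.items()], ignore_index=True)
        cmp.to_csv(out / "clock_comparison.csv", index=False)
        state["clock_comparison"] = cmp
    state["clock_estimates"] = per_clock


def _stage_report(config, seed, out, state):
    ds = _require_dataset(state)
    all_cg = sorted({base_id(p) for a in ds.manifests
                     for p in ds.manifests[a]["IlmnID"]
                     if base_id(p).startswith("cg")})
    presence = pd.DataFrame(
        {a: [base_id(p) in set(ds.manifests[a]["IlmnID"].map(base_id))
             for p in all_cg] for a in ds.manifests}, index=all_cg)
    reliability = state.get("reliability")
    if reliability is not None:
        reliability = {a: t[t.index.map(base_id).isin(all_cg)]
                       .rename(index=base_id)
                       .groupby(level=0).first()
                       for a, t in reliability.items()}
    report = build_report(
        all_cg, presence=presence, reliability=reliability,
        bias=state.get("bias"),
        provenance={"seed": seed, "version": __version__})
    write_report(report, out / "probe_report.csv", out / "probe_report.jsonl")
    state["report"] = report


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "reliability": _stage_reliability,
    "bias": _stage_bias,
    "match": _stage_match,
    "ewas": _stage_ewas,
    "clocks": _stage_clocks,
    "report": _stage_report,
}
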