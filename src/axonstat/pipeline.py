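"""End-to-end orchestration: simulate -> parse -> measure -> classify ->
null-test -> compare, with one reproducible report.

All machine outputs (CSV/JSON) are deterministic under a fixed config and
master seed; the report embeds the config hash and seed.  Logs go to standard
error and are never interleaved with machine outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__, group_stats, morphometry, null_model, skeleton_io, synthetic
from .types import ValidationError, VoxelScale
from .varicosity import classify_axon, exceedance_counts, pool_frequencies

log = logging.getLogger("axonstat")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def default_config() -> dict:
    return {
        "study": synthetic.default_study_config(),
        "detector": {"fold": 2.0, "window_um": 1.0, "min_separation_um": 0.5},
        "null": {"trials": 100_000, "tail": "geq", "min_varicosities": 3, "k_max": 5},
        "compare_metrics": [
            "branch_density_per_um",
            "contact_density_per_um",
            "swelling_density_per_um",
            "mito_density_per_um",
            "mito_length_um",
        ],
    }


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    config = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except (ValidationError, skeleton_io.ParseError, FileNotFoundError) as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return run
    return wrap


@_stage("input")
def _load_inputs(config: dict, seed: int, outdir: Path):
    if "inputs" in config:
        records = []
        scale = VoxelScale(*config.get("scale_nm", [20.0, 20.0, 40.0]))
        manifest = None
        if config.get("manifest"):
            mpath = Path(config["manifest"])
            if not mpath.exists():
                raise FileNotFoundError(f"manifest file not found: {mpath}")
            manifest = skeleton_io.load_manifest(mpath)
            if "axons" in manifest:
                manifest = manifest["axons"]
        for path in config["inputs"]:
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
            records.extend(skeleton_io.parse_nml(path.read_text(), scale, manifest=manifest))
        log.info("parsed %d axons from %d files", len(records), len(config["inputs"]))
        return records
    study_dir = outdir / "study"
    synthetic.generate_study(config["study"], seed, study_dir)
    records = synthetic.load_study(study_dir)
    log.info("simulated %d axons", len(records))
    return records


@_stage("measure")
def _measure(records, outdir: Path):
    rows = [morphometry.measure_axon(a) for a in records]
    import pandas as pd

    per_axon = pd.DataFrame(rows)
    per_axon.to_csv(outdir / "per_axon.csv", index=False)
    nodes, annotations = skeleton_io.to_table(records)
    annotations.to_csv(outdir / "annotations.csv", index=False)
    return per_axon


@_stage("classify")
def _classify(records, outdir: Path):
    for a in records:
        classify_axon(a)
    import pandas as pd

    rows = [
        {
            "axon_id": v.axon_id, "index": v.index, "node_id": v.node_id,
            "n_vesicles": len(v.vesicle_diameters), "vtype": v.vtype,
            "mito_within_1um": v.mito_within_1um,
        }
        for a in records
        for v in a.varicosities
    ]
    pd.DataFrame(rows).to_csv(outdir / "varicosities.csv", index=False)
    return records


@_stage("nulltest")
def _nulltest(records, config: dict, seed: int, outdir: Path):
    cfg = config["null"]
    with_varic = [a for a in records if a.varicosities]
    if not with_varic:
        log.info("no varicosities; null-model stage skipped")
        return None
    freqs = pool_frequencies(with_varic)
    observed = exceedance_counts(
        with_varic, k_max=cfg["k_max"], min_varicosities=cfg["min_varicosities"]
    )
    observed.as_frame().to_csv(outdir / "exceedance.csv", index=False)
    result = null_model.pvalue_table(
        observed,
        null_model.NullConfig(
            trials=cfg["trials"], tail=cfg["tail"],
            min_varicosities=cfg["min_varicosities"], seed=seed,
        ),
        f=freqs,
    )
    result.table.to_csv(outdir / "null_model.csv", index=False)
    return {"frequencies": freqs, "observed": observed, "result": result}


@_stage("compare")
def _compare(records, config: dict, outdir: Path):
    groups = sorted({a.group for a in records} - {"none"})
    if len(groups) != 2:
        log.info("need exactly two groups for comparisons, found %s", groups)
        return []
    gx, gy = groups[::-1] if groups == ["cocaine", "saline"] else groups
    comparisons = []
    for compartment in sorted({a.compartment for a in records}):
        ax = [a for a in records if a.group == gx and a.compartment == compartment]
        ay = [a for a in records if a.group == gy and a.compartment == compartment]
        if not ax or not ay:
            continue
        for metric in config["compare_metrics"]:
            try:
                x = group_stats.metric_values(ax, metric)
                y = group_stats.metric_values(ay, metric)
            except ValidationError:
                continue
            if x.size < 2 or y.size < 2:
                continue
            comp = group_stats.compare_groups(
                f"{compartment}:{metric}", x, y, group_names=(gx, gy)
            )
            comparisons.append(comp)
    with open(outdir / "comparisons.json", "w") as fh:
        json.dump([c.summary() for c in comparisons], fh, indent=1, sort_keys=True)
    return comparisons


def run_pipeline(config: dict, outdir, seed: int = 0) -> dict:
    """Run every stage and assemble the report (written to report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _load_inputs(config, seed, outdir)
    per_axon = _measure(records, outdir)
    records = _classify(records, outdir)
    null_out = _nulltest(records, config, seed, outdir)
    comparisons = _compare(records, config, outdir)

    report = {
        "version": __version__,
        "seed": int(seed),
        "config_hash": synthetic.config_hash(config),
        "n_axons": len(records),
        "total_cable_um": float(per_axon.cable_length_um.sum()),
        "varicosity_type_counts": (
            {t: int(c) for t, c in zip("I II III IV".split(), null_out["frequencies"].counts)}
            if null_out else {}
        ),
        "null_model": (
            null_out["result"].table.to_dict(orient="records") if null_out else None
        ),
        "comparisons": [c.summary() for c in comparisons],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
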