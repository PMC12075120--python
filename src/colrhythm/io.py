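"""Run-directory writers and the reproducibility manifest.

Experiment outputs are plain columnar text: spikes as
(neuron_id, time_ms, group_label) CSV, rate traces and analysis
summaries as tidy tables, weight snapshots in the synapse-table format.
The manifest records the configuration hash, resolved seeds, package
version and a SHA-256 checksum of every written file, so a re-run from
the same provenance can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import ExperimentResult


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_experiment(result: ExperimentResult, directory: str | Path) -> Path:
    """Write all outputs of one experiment plus its manifest; returns the
    manifest path."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "spikes.csv"
    result.spikes.to_dataframe().to_csv(p, index=False)
    written.append(p)

    rows = []
    for label, tr in result.rate_traces.items():
        rows.append(pd.DataFrame(
            {"group": label, "time_ms": tr.times, "rate_hz": tr.rate}))
    if rows:
        p = out / "rates.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    p = out / "summaries.json"
    with open(p, "w") as fh:
        json.dump(_jsonable(result.summaries), fh, indent=1, sort_keys=True)
    written.append(p)

    for t, tab in result.weight_snapshots:
        p = out / f"weights_t{int(round(t))}ms.csv"
        tab.save(p)
        written.append(p)
    if result.final_table is not None:
        p = out / "weights_final.csv"
        result.final_table.save(p)
        written.append(p)

    return write_run_manifest(result, out, written)


def write_run_manifest(
    result: ExperimentResult, directory: str | Path, files: list[Path] | None = None
) -> Path:
    """Write manifest.json for a completed run.

    Lists the experiment name, config hash, seeds, software version and
    per-file checksums. Missing optional outputs are marked absent.
    """
    out = Path(directory)
    if not out.is_dir():
        raise OSError(f"{out} is not a writable directory")
    if files is None:
        files = sorted(p for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    optional = {"v_traces": result.v_traces is not None,
                "weight_snapshots": bool(result.weight_snapshots)}
    manifest = {
        "experiment": result.name,
        "provenance": _jsonable(result.provenance),
        "optional_outputs": optional,
        "checksums": {p.name: _sha256(p) for p in files},
    }
    mp = out / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mp


def verify_manifest(directory: str | Path) -> dict[str, bool]:
    """Recompute checksums against manifest.json; True means intact."""
    out = Path(directory)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    status = {}
    for name, digest in manifest["checksums"].items():
        p = out / name
        status[name] = p.is_file() and _sha256(p) == digest
    return status
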