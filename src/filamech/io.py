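"""Trace CSV dialect, configuration files and reproducibility plumbing.

Trace files are UTF-8 CSV with the header ``cycle,branch,t_s,d_nm,F_pN``,
period decimal separator, one row per sample; ``branch`` is ``stretch`` or
``relax``.  Run configurations are YAML (JSON is accepted as a fallback);
every run directory gets a manifest holding the seed, the configuration
and its hash so outputs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Branch, ForceExtensionRecord

TRACE_COLUMNS = ["cycle", "branch", "t_s", "d_nm", "F_pN"]


class SchemaError(ValueError):
    """A trace or config file does not match the expected schema."""


def write_trace_csv(records, path) -> None:
    """Write ForceExtensionRecords for one filament to a trace CSV."""
    frames = []
    for r in records:
        frames.append(pd.DataFrame({
            "cycle": r.cycle_index,
            "branch": r.branch.value,
            "t_s": r.t,
            "d_nm": r.d,
            "F_pN": r.F,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6g")


def read_trace_csv(path):
    """Read a trace CSV back into a list of ForceExtensionRecords.

    Malformed rows raise :class:`SchemaError` naming the line; missing
    columns raise :class:`SchemaError` naming the columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path.name}: parse error: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path.name}: empty file") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    for col in ("t_s", "d_nm", "F_pN"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path.name}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["t_s", "d_nm", "F_pN"])

    records = []
    for (cycle, branch), g in df.groupby(["cycle", "branch"], sort=False):
        try:
            b = Branch(branch)
        except ValueError as exc:
            raise SchemaError(f"{path.name}: unknown branch {branch!r}") from exc
        records.append(ForceExtensionRecord(
            g["t_s"].to_numpy(), g["d_nm"].to_numpy(), g["F_pN"].to_numpy(),
            b, int(cycle)))
    records.sort(key=lambda r: (r.cycle_index, r.branch is Branch.RELAX))
    return records


def read_trace_dir(dirpath):
    """All filament traces in a directory, sorted by file name."""
    dirpath = Path(dirpath)
    files = sorted(dirpath.glob("*.csv"))
    files = [f for f in files if f.name != "events.csv"
             and not f.name.startswith("metrics")]
    if not files:
        raise SchemaError(f"no trace CSV files found in {dirpath}")
    return [read_trace_csv(f) for f in files], files


def write_events_csv(events, path) -> None:
    pd.DataFrame(events, columns=["t_s", "cycle", "branch", "kind",
                                  "element", "F_pN"]).to_csv(path, index=False)


def default_config() -> dict:
    """The packaged default configuration (defaults.yaml) as a mapping."""
    from importlib import resources

    text = resources.files("filamech").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path) -> dict:
    """Load a YAML configuration (JSON accepted as a fallback)."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError:
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: neither valid YAML nor JSON") from exc
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: top-level mapping expected")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_manifest(outdir, config: dict, seed: int) -> Path:
    """Record seed, config, config hash and versions alongside the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config": config,
        "config_hash": config_hash(config),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
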