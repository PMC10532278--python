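"""Table/config loading and deterministic output writing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["load_table", "load_model_syntax", "load_config",
           "write_curves", "write_summary", "write_metadata"]


def load_table(path) -> pd.DataFrame:
    """Read a CSV data table; empty cells become missing values, row order is
    preserved."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty data table")
    return df


def load_model_syntax(path) -> str:
    return Path(path).read_text()


def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_curves(results, path) -> None:
    """Curve table CSV with the documented column order."""
    cols = ["parameter", "focal_index", "a_t", "estimate", "standardized",
            "is_invariant", "is_dif"]
    results.curves[cols].to_csv(path, index=False)


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def write_metadata(path, *, config: dict | None = None, seed=None,
                   results=None, extra: dict | None = None) -> None:
    """Run metadata JSON: config echo, seeds, versions, convergence log."""
    from . import __version__
    meta = {"localsem_version": __version__, "seed": _jsonable(seed),
            "config": _jsonable(config or {})}
    if results is not None:
        m = results.model
        meta["run"] = {
            "n_subjects": int(m.N),
            "moderator": m.moderator,
            "kernel": m.kernel.kernel,
            "h": m.kernel.h,
            "bw": m.kernel.bw,
            "grid": m.grid.points.tolist(),
            "mode": results.mode,
            "par_invariant": list(m.par_invariant),
            "par_linear": list(m.par_linear),
            "par_quadratic": list(m.par_quadratic),
            "converged": (bool(results.fit.converged) if results.fit is not None
                          else _jsonable(results.pointwise_converged)),
        }
    if extra:
        meta.update(_jsonable(extra))
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
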