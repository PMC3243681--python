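"""Deterministic tabular output for scenario results and equilibrium curves.

All files are plain delimiter-separated text with a fixed column order and
fixed float formatting, so reruns of the same configuration produce
byte-identical files.  A run manifest (YAML) records the fully resolved
configuration, the schema and code versions, and a partial-result flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

import glioswitch
from glioswitch.config import SCHEMA_VERSION, dump_config
from glioswitch.metrics import ScenarioResult
from glioswitch.switch_network import EquilibriumBranch

__all__ = ["write_series", "write_branch", "read_table"]

_FMT = "%.10g"
_FIELD_ORDER = ("n", "rho", "P", "G", "M", "A")


def _format_row(values) -> str:
    return "\t".join(_FMT % v for v in values)


def write_branch(branch: EquilibriumBranch, destination: str | Path) -> Path:
    """Write an equilibrium curve as TSV: G, M, A, stability."""
    dest = Path(destination)
    dest.parent.mkdir(parents=True, exist_ok=True)
    lines = ["G\tM\tA\tstability"]
    for G, M, A, s in zip(branch.G, branch.M, branch.A, branch.stability):
        lines.append(f"{_FMT % G}\t{_FMT % M}\t{_FMT % A}\t{s}")
    dest.write_text("\n".join(lines) + "\n")
    return dest


def write_series(result: ScenarioResult, destination: str | Path) -> dict[str, Path]:
    """Write a scenario result under ``destination``.

    Produces ``totals.tsv`` (t, per-field domain totals, tumor-weighted
    mean M, phase), ``snapshots.tsv`` (t, x, the six fields) and
    ``manifest.yaml`` (resolved config, versions, partial flag).
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)

    totals_path = dest / "totals.tsv"
    header = "t\t" + "\t".join(f"total_{f}" for f in _FIELD_ORDER) + "\tmean_M\tphase"
    phases = result.phase
    lines = [header]
    for i, t in enumerate(result.times):
        row = [t] + [result.totals[f][i] for f in _FIELD_ORDER] + [result.mean_M[i]]
        lines.append(_format_row(row) + "\t" + phases[i])
    totals_path.write_text("\n".join(lines) + "\n")

    snap_path = dest / "snapshots.tsv"
    lines = ["t\tx\t" + "\t".join(_FIELD_ORDER)]
    grid = result.config.grid if result.config is not None else None
    for snap in result.snapshots:
        fields = snap.fields.as_dict()
        ncell = fields["n"].size
        x = grid.centers if grid is not None else (np.arange(ncell) + 0.5) / ncell
        for j in range(ncell):
            lines.append(_format_row([snap.t, x[j]] + [fields[f][j] for f in _FIELD_ORDER]))
    snap_path.write_text("\n".join(lines) + "\n")

    manifest_path = dest / "manifest.yaml"
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "code_version": glioswitch.__version__,
        "partial": bool(result.partial),
        "config": dump_config(result.config) if result.config is not None else None,
    }
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return {"totals": totals_path, "snapshots": snap_path, "manifest": manifest_path}


def read_table(path: str | Path):
    """Read back a TSV written by this module as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")
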