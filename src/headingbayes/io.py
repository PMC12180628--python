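"""Delimited-text round-tripping for trials, curves, fits and predictions.

Every table written by the package starts with a provenance comment line
(`# headingbayes <version> command=<cmd> seed=<seed>`) followed by a
plain CSV with header; readers skip comment lines, so the files also
accommodate externally produced trial tables after column mapping.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import REQUIRED_TRIAL_COLUMNS, FitResult

__all__ = [
    "write_table",
    "read_table",
    "read_trials",
    "write_fit_result",
    "read_fit_result",
]


def provenance_line(command: str, seed=None) -> str:
    line = f"# headingbayes {__version__} command={command}"
    if seed is not None:
        line += f" seed={seed}"
    return line


def write_table(df: pd.DataFrame, path, command: str, seed=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(command, seed) + "\n")
        df.to_csv(fh, index=False)
    return path

def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table, reporting bad rows by line number."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    n_leading_comments = 0
    for line in lines:
        if line.startswith("#"):
            n_leading_comments += 1
        else:
            break
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing columns: {missing}")
    bad_mask = np.zeros(len(df), dtype=bool)
    for col in ("true_heading_deg", "reported_heading_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_mask |= ~np.isfinite(vals.to_numpy(dtype=float))
        df[col] = vals
    if bad_mask.any():
        # +1 for the header row, +1 for 1-based numbering
        file_lines = np.flatnonzero(bad_mask) + n_leading_comments + 2
        raise ValueError(
            f"trial table {path} has malformed rows at lines "
            f"{file_lines.tolist()} (non-numeric or missing headings)"
        )
    if len(df) == 0:
        raise ValueError(f"trial table {path} contains no trials")
    return df


def write_fit_result(fr: FitResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_written_by": f"headingbayes {__version__}"}
    payload.update(fr.to_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_fit_result(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data.pop("_written_by", None)
    return data
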