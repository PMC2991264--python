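"""CSV / TIFF I/O with provenance headers.

Tables are written as CSV preceded by ``# key: value`` comment lines
recording the package version, a configuration hash and the seed, so
that any output file can be traced back to the run that produced it.
Readers skip comment lines and validate required columns by name.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd
import tifffile

__all__ = [
    "SchemaError",
    "write_table",
    "read_table",
    "write_track_table",
    "read_track_table",
    "write_movie",
    "read_movie",
    "config_hash",
]

TRACK_COLUMNS = ["nucleus_id", "track_id", "frame", "t_s", "x_um", "y_um"]


class SchemaError(ValueError):
    """A table is missing required columns."""


def config_hash(config: object) -> str:
    """Stable short hash of a configuration object."""
    if hasattr(config, "__dict__"):
        payload = {k: repr(v) for k, v in sorted(vars(config).items())}
    else:
        payload = {"repr": repr(config)}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: dict[str, object] | None = None,
    float_format: str = "%.6f",
) -> None:
    """Write a CSV with ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a provenance-headed CSV, validating required columns."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: table has 0 rows", stacklevel=2)
    return df


def write_track_table(tracks: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a track table (lossless to 1e-6 µm; extra columns preserved)."""
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise SchemaError(f"track table missing required columns {missing}")
    write_table(tracks, path, provenance)


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a track table, requiring the documented schema columns."""
    return read_table(path, required=TRACK_COLUMNS)


def write_movie(stack, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.astype("float32"))


def read_movie(path: str | Path):
    return tifffile.imread(path)
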