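"""File I/O: CSV dialects, warp serialization, run manifests.

Everything on disk is in seconds and plain text; conversion to the
normalized internal domain happens only at this boundary.  Floats are
written with 17 significant digits so reader and writer are inverse up to
text round trip.

Two CSV dialects are accepted for raw ratings (comma delimiter, header
row required):

* **long** — columns ``time_seconds, rating, subject_id, stimulus_id, role``;
* **wide** — a ``time_seconds`` column plus one column of ratings per
  subject (column name = subject id).

Warps are two-column CSVs ``t_seconds, gamma_seconds``.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import RatingCurve, Warping, uniform_grid
from .errors import DataFormatError
from .prep import RawRatingSeries

__all__ = [
    "read_long_csv",
    "read_wide_csv",
    "write_curve_csv",
    "write_warp_csv",
    "read_warp_csv",
    "RunManifest",
]

_FLOAT_FMT = "%.17g"

LONG_COLUMNS = ["time_seconds", "rating", "subject_id", "stimulus_id", "role"]


def _package_version() -> str:
    try:
        return version("ea-align")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc


def read_long_csv(path: str | Path) -> list[RawRatingSeries]:
    """Long-format ratings -> one series per (subject, stimulus, role)."""
    df = _read_csv(path)
    missing = [c for c in LONG_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    for c in ("subject_id", "stimulus_id", "role"):
        if c not in df.columns:
            df[c] = ""
    out = []
    for (subj, stim, _role), grp in df.groupby(
        ["subject_id", "stimulus_id", "role"], sort=True
    ):
        grp = grp.sort_values("time_seconds")
        try:
            out.append(
                RawRatingSeries(
                    times_seconds=grp["time_seconds"].to_numpy(float),
                    ratings=grp["rating"].to_numpy(float),
                    subject_id=str(subj),
                    stimulus_id=str(stim),
                )
            )
        except Exception as exc:
            first = grp.index[0] + 2  # header is row 1
            raise DataFormatError(
                f"{path}: bad series starting at row {first}: {exc}"
            ) from exc
    return out


def read_wide_csv(path: str | Path) -> list[RawRatingSeries]:
    """Wide-format ratings: a time column plus one column per subject."""
    df = _read_csv(path)
    time_col = "time_seconds" if "time_seconds" in df.columns else df.columns[0]
    t = df[time_col].to_numpy(float)
    out = []
    for col in df.columns:
        if col == time_col:
            continue
        try:
            out.append(
                RawRatingSeries(
                    times_seconds=t,
                    ratings=df[col].to_numpy(float),
                    subject_id=str(col),
                )
            )
        except Exception as exc:
            raise DataFormatError(
                f"{path}: column {col!r} is not a valid series: {exc}"
            ) from exc
    return out


def write_curve_csv(path: str | Path, curve: RatingCurve) -> None:
    """Curve as two columns ``t_seconds, value``."""
    df = pd.DataFrame(
        {
            "t_seconds": curve.grid * curve.duration_seconds,
            "value": curve.values,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_warp_csv(path: str | Path, g: Warping, duration_seconds: float) -> None:
    """Warp as two columns ``t_seconds, gamma_seconds``."""
    df = pd.DataFrame(
        {
            "t_seconds": g.grid * duration_seconds,
            "gamma_seconds": g.gamma * duration_seconds,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_warp_csv(path: str | Path) -> tuple[Warping, float]:
    """Inverse of :func:`write_warp_csv`; returns (warping, duration)."""
    df = _read_csv(path)
    if not {"t_seconds", "gamma_seconds"} <= set(df.columns):
        raise DataFormatError(f"{path}: expected t_seconds, gamma_seconds")
    t = df["t_seconds"].to_numpy(float)
    gam = df["gamma_seconds"].to_numpy(float)
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise DataFormatError(f"{path}: non-positive time span")
    grid = (t - t[0]) / duration
    grid[0], grid[-1] = 0.0, 1.0
    boundary_fixed = (
        abs(gam[0] - t[0]) <= 1e-6 * duration
        and abs(gam[-1] - t[-1]) <= 1e-6 * duration
    )
    return (
        Warping(
            grid=grid,
            gamma=np.clip((gam - t[0]) / duration, 0.0, 1.0),
            boundary_fixed=boundary_fixed,
        ),
        duration,
    )


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    config: dict
    seed: int | None = None
    software_version: str = field(default_factory=_package_version)
    input_digests: dict = field(default_factory=dict)
    output_paths: list = field(default_factory=list)
    started_at: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    finished_at: str = ""

    def add_input(self, path: str | Path) -> None:
        self.input_digests[str(path)] = sha256_digest(path)

    def finish(self, out_path: str | Path) -> None:
        self.finished_at = _dt.datetime.now(_dt.timezone.utc).isoformat()
        with open(out_path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
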