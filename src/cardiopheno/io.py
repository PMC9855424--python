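"""Shared file I/O: TIFF images, trace CSVs and synthetic-truth sidecars.

Traces travel as CSV with a ``time_s`` column plus one column per cell
(single-signal mode) or paired ``<cell>_340`` / ``<cell>_380`` columns
(ratiometric mode). All CSV outputs start with a ``#`` comment line
recording the tool version and the parameters that produced them; readers
skip ``#`` lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calcium import Trace
from .synthetic import SyntheticSpec

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_traces_csv",
    "write_traces_csv",
    "save_spec",
    "load_spec",
    "write_table",
]

log = logging.getLogger(__name__)


def read_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single- or multi-frame TIFF; returns (array, metadata).

    Metadata reports width, height, number of frames and the stored
    dtype; 16-bit values are preserved unscaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TIFF not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt / non-TIFF
        raise ValueError(f"cannot read {path} as TIFF: {exc}") from exc
    n_frames = 1 if arr.ndim == 2 else int(arr.shape[0])
    meta = dict(
        width=int(arr.shape[-1]),
        height=int(arr.shape[-2]),
        n_frames=n_frames,
        dtype=str(arr.dtype),
    )
    return arr, meta


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image))


def _comment(params: dict | None) -> str:
    extra = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# cardiopheno v{__version__}" + (f" {extra}" if extra else "")


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a CSV with a leading version/parameter comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment(params) + "\n")
        df.to_csv(fh, index=False)


def write_traces_csv(
    path: str | Path,
    traces: list[Trace],
    params: dict | None = None,
    ratio_pairs: bool = False,
) -> None:
    """Write traces to CSV (``time_s`` + one value column per trace)."""
    if not traces:
        raise ValueError("no traces to write")
    data = {"time_s": traces[0].time_s}
    for i, tr in enumerate(traces):
        if not np.array_equal(tr.time_s, traces[0].time_s):
            raise ValueError("all traces must share one time grid")
        data[tr.name or f"cell{i + 1}"] = tr.values
    write_table(pd.DataFrame(data), path, params)


def read_traces_csv(path: str | Path, mode: str = "single") -> list:
    """Read traces from CSV.

    ``mode="single"`` returns a list of :class:`Trace`, one per value
    column. ``mode="ratio_pairs"`` pairs ``<cell>_340``/``<cell>_380``
    columns and returns ``[(cell, trace340, trace380), ...]``; a cell
    with only one of the pair is an error listing the offender. Columns
    that are entirely empty are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace CSV not found: {path}")
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    cols = [c for c in df.columns if c != "time_s"]

    def make(name: str, kind: str = "raw") -> Trace | None:
        v = df[name].to_numpy(dtype=float)
        if np.all(np.isnan(v)):
            log.warning("%s: column %r is empty, skipped", path, name)
            return None
        return Trace(t, v, signal_kind=kind, name=name)

    if mode == "single":
        out = [make(c) for c in cols]
        return [tr for tr in out if tr is not None]
    if mode != "ratio_pairs":
        raise ValueError("mode must be 'single' or 'ratio_pairs'")

    cells_340 = {c[: -len("_340")] for c in cols if c.endswith("_340")}
    cells_380 = {c[: -len("_380")] for c in cols if c.endswith("_380")}
    unmatched = sorted(cells_340 ^ cells_380) + sorted(
        c for c in cols if not (c.endswith("_340") or c.endswith("_380"))
    )
    if unmatched:
        raise ValueError(
            f"{path}: unpaired ratio columns (need matching _340/_380): {unmatched}"
        )
    out_pairs = []
    for cell in sorted(cells_340):
        t340, t380 = make(f"{cell}_340"), make(f"{cell}_380")
        if t340 is None or t380 is None:
            log.warning("%s: cell %r skipped (empty channel)", path, cell)
            continue
        out_pairs.append((cell, t340, t380))
    return out_pairs


def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    """Write a SyntheticSpec truth sidecar (JSON)."""
    Path(path).write_text(spec.to_json())


def load_spec(path: str | Path) -> SyntheticSpec:
    return SyntheticSpec.from_json(Path(path).read_text())
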