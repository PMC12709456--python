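"""File I/O, motion-scrubbing quality control, and run manifests.

All on-disk artefacts are delimited text (TSV with headers) or JSON so the
pipeline stays language-agnostic and diffable.  Time-series files carry a
header row of region IDs with one row per timepoint.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "ConfoundTable",
    "apply_scrubbing",
    "ScrubResult",
    "write_manifest",
]

FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD = 3.0
MIN_TIMEPOINTS = 150


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    """Read a TSV of BOLD signals; returns (regions x timepoints, region IDs).

    The file stores timepoints as rows under a header of region IDs
    (orientation auto-detected: if there are more header fields than data
    rows and the transpose is plausible the matrix is flipped — region
    count below timepoint count is the expected layout).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicated region IDs in {path}: {dupes}")
    if df.columns.str.match(r"^Unnamed").any() or df.isna().any().any():
        raise ValueError(f"missing header or ragged rows in {path}")
    return df.to_numpy(dtype=float).T, list(df.columns)


def write_timeseries(path, ts: np.ndarray, region_ids) -> None:
    """Write regions x timepoints to TSV (timepoints as rows), losslessly."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] != len(region_ids):
        raise ValueError("region_ids do not match the time-series rows")
    if len(set(region_ids)) != len(region_ids):
        raise ValueError("duplicated region IDs")
    pd.DataFrame(ts.T, columns=list(region_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


@dataclass
class ConfoundTable:
    """Per-volume motion / signal-change QC measures."""

    fd_mm: np.ndarray  # framewise displacement, mm
    dvars_std: np.ndarray  # standardized DVARS

    def __post_init__(self):
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        self.dvars_std = np.asarray(self.dvars_std, dtype=float)
        if self.fd_mm.shape != self.dvars_std.shape:
            raise ValueError("FD and DVARS lengths differ")
        if np.any(self.fd_mm < 0):
            raise ValueError("framewise displacement must be nonnegative")

    @property
    def n_volumes(self) -> int:
        return self.fd_mm.size


@dataclass
class ScrubResult:
    timeseries: np.ndarray | None
    kept: np.ndarray  # boolean mask over volumes
    excluded: bool
    reason: str = ""

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def apply_scrubbing(
    ts: np.ndarray,
    confounds: ConfoundTable,
    fd_thresh: float = FD_THRESHOLD_MM,
    dvars_thresh: float = DVARS_THRESHOLD,
    min_timepoints: int = MIN_TIMEPOINTS,
) -> ScrubResult:
    """Remove high-motion volumes; exclude subjects left too short.

    Volumes with FD > ``fd_thresh`` mm or standardized DVARS >
    ``dvars_thresh`` are dropped; a subject retaining fewer than
    ``min_timepoints`` volumes is excluded outright.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] != confounds.n_volumes:
        raise ValueError(
            f"time series has {ts.shape[1]} volumes but confounds have "
            f"{confounds.n_volumes}")
    kept = (confounds.fd_mm <= fd_thresh) & (confounds.dvars_std <= dvars_thresh)
    if kept.sum() < min_timepoints:
        return ScrubResult(
            timeseries=None, kept=kept, excluded=True,
            reason=f"{int(kept.sum())} volumes after scrubbing "
                   f"< {min_timepoints} required")
    return ScrubResult(timeseries=ts[:, kept], kept=kept, excluded=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, stage: str, config: dict, inputs=(), seeds=None,
                   exclusions=None) -> Path:
    """Write the run manifest of a pipeline stage (one per output dir)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = dict(
        stage=stage,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config=config,
        seeds=seeds or {},
        input_checksums={str(p): _checksum(Path(p)) for p in inputs},
        exclusions=exclusions or [],
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
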