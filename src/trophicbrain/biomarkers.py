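"""Amyloid-PET Centiloid conversion and positivity status.

Tracer-specific affine calibrations map cortical SUVR onto the common
Centiloid (CL) scale; subjects with a global cortical CL value strictly
above 24 are amyloid-positive (autopsy-anchored cutoff).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["suvr_to_centiloid", "centiloid_to_suvr", "amyloid_status",
           "CENTILOID_CALIBRATIONS", "ABETA_POSITIVITY_CUTOFF_CL"]

#: slope/intercept of CL = slope * SUVR + intercept per tracer
CENTILOID_CALIBRATIONS = {
    "FBB": (94.082, -94.772),    # Florbetaben
    "FBP": (110.982, -116.172),  # Florbetapir
}

ABETA_POSITIVITY_CUTOFF_CL = 24.0


def _calibration(tracer: str):
    key = str(tracer).upper()
    if key not in CENTILOID_CALIBRATIONS:
        raise ValueError(f"unknown tracer {tracer!r}; expected one of "
                         f"{sorted(CENTILOID_CALIBRATIONS)}")
    return CENTILOID_CALIBRATIONS[key]


def suvr_to_centiloid(suvr, tracer: str):
    """Convert SUVR to Centiloid units with the tracer's calibration."""
    slope, intercept = _calibration(tracer)
    suvr = np.asarray(suvr, dtype=float)
    if np.any(suvr <= 0):
        raise ValueError("SUVR must be positive")
    out = slope * suvr + intercept
    return float(out) if out.ndim == 0 else out


def centiloid_to_suvr(centiloid, tracer: str):
    """Invert the affine calibration (round-trip exact)."""
    slope, intercept = _calibration(tracer)
    cl = np.asarray(centiloid, dtype=float)
    out = (cl - intercept) / slope
    return float(out) if out.ndim == 0 else out


def amyloid_status(centiloid):
    """'positive' iff CL strictly above 24, else 'negative'."""
    cl = np.asarray(centiloid, dtype=float)
    if not np.all(np.isfinite(cl)):
        raise ValueError("non-finite Centiloid value")
    status = np.where(cl > ABETA_POSITIVITY_CUTOFF_CL, "positive", "negative")
    return str(status) if status.ndim == 0 else status


def centiloid_table(table: pd.DataFrame, suvr_col: str = "suvr",
                    tracer_col: str = "tracer") -> pd.DataFrame:
    """Per-subject conversion of a (subject, tracer, suvr) table."""
    out = table.copy()
    out["centiloid"] = [
        suvr_to_centiloid(s, t) for s, t in zip(table[suvr_col], table[tracer_col])
    ]
    out["status"] = amyloid_status(out["centiloid"].to_numpy())
    return out
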