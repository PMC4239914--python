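"""Raw-signal conditioning ahead of multivariate feature extraction.

Two modality-specific steps turn raw recordings into characteristic
values: per-sensor maximum response for the e-nose array, and standard
normal variate (SNV) correction for NIR spectra.  Both characteristic
matrices are then column z-scored with statistics taken from training
rows only, so that held-out samples never leak into the fit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DegenerateInputError,
    ENoseRecording,
    FeatureMatrix,
    Spectrum,
)

__all__ = [
    "snv_transform",
    "max_response",
    "standardize",
    "enose_feature_matrix",
    "spectra_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]


def snv_transform(spectrum: Spectrum, ddof: int = 1) -> Spectrum:
    """Standard normal variate correction of one spectrum.

    Each spectrum is centred to zero mean and scaled to unit standard
    deviation (``ddof=1`` by convention), which removes additive offsets
    and multiplicative scatter exactly: ``snv(a*x + b) == snv(x)`` for
    any ``a > 0``.

    Raises
    ------
    DegenerateInputError
        If the spectrum is constant (zero standard deviation).
    """
    x = spectrum.absorbance
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError(
            f"spectrum {spectrum.sample_id!r} is constant; SNV undefined"
        )
    return Spectrum(spectrum.sample_id, (x - x.mean()) / sd, spectrum.wavenumbers)


def max_response(recording: ENoseRecording) -> np.ndarray:
    """Characteristic value of the e-nose signal: per-sensor maximum.

    Returns the elementwise maximum over the time axis, one value per
    sensor in sensor order (a length-11 vector).  No absolute value is
    taken; the signed maximum is reported.
    """
    return recording.response.max(axis=1)


def standardize(features: FeatureMatrix, fit_rows=None, ddof: int = 1) -> FeatureMatrix:
    """Column z-score a feature matrix using statistics from ``fit_rows``.

    All rows are transformed, but the column mean and standard deviation
    are computed from ``fit_rows`` only (default: all rows).  The fitted
    statistics are stored on the returned matrix so they can be applied
    to further held-out data via :func:`apply_standardization`.

    Raises
    ------
    ValueError
        If ``fit_rows`` is empty or a column has zero variance within
        the fit rows (the offending column is named).
    """
    if fit_rows is None:
        fit_rows = list(features.sample_ids)
    else:
        fit_rows = list(fit_rows)
    if len(fit_rows) == 0:
        raise ValueError("fit_rows must be non-empty")
    fit_block = features.values.loc[fit_rows]
    center = fit_block.mean(axis=0)
    scale = fit_block.std(axis=0, ddof=ddof)
    dead = scale.index[(scale == 0) | ~np.isfinite(scale)]
    if len(dead):
        raise ValueError(
            f"zero-variance column(s) within fit rows: {list(dead)}"
        )
    out = (features.values - center) / scale
    return FeatureMatrix(
        out,
        center=center,
        scale=scale,
        provenance={**features.provenance, "standardized_on": fit_rows},
    )


def apply_standardization(features: FeatureMatrix, fitted: FeatureMatrix) -> FeatureMatrix:
    """Transform ``features`` with the stats stored on an already-standardized matrix."""
    if fitted.center is None or fitted.scale is None:
        raise ValueError("fitted matrix carries no standardization statistics")
    out = (features.values - fitted.center) / fitted.scale
    return FeatureMatrix(out, center=fitted.center, scale=fitted.scale)


def enose_feature_matrix(recordings: list[ENoseRecording]) -> FeatureMatrix:
    """Stack per-sensor maximum responses into a samples x 11 matrix."""
    rows = {rec.sample_id: max_response(rec) for rec in recordings}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"sensor_{i + 1}" for i in range(df.shape[1])]
    df.index.name = "sample_id"
    return FeatureMatrix(df, provenance={"modality": "enose", "feature": "max_response"})


def spectra_feature_matrix(spectra: list[Spectrum], snv: bool = True) -> FeatureMatrix:
    """Stack (optionally SNV-corrected) spectra into a samples x 1557 matrix."""
    processed = [snv_transform(s) if snv else s for s in spectra]
    rows = {s.sample_id: s.absorbance for s in processed}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"wn_{w:.3f}" for w in processed[0].wavenumbers]
    df.index.name = "sample_id"
    return FeatureMatrix(df, provenance={"modality": "nirs", "snv": snv})


def write_feature_matrix(features: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV with a JSON sidecar of fitted stats."""
    path = Path(path)
    features.values.to_csv(path)
    sidecar = {
        "provenance": {
            k: v for k, v in features.provenance.items() if _jsonable(v)
        },
    }
    if features.center is not None:
        sidecar["center"] = features.center.tolist()
        sidecar["scale"] = features.scale.tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    fm = FeatureMatrix(df)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fm.provenance = meta.get("provenance", {})
        if "center" in meta:
            fm.center = pd.Series(meta["center"], index=df.columns)
            fm.scale = pd.Series(meta["scale"], index=df.columns)
    return fm


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
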