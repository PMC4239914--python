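"""Core sample-level data containers shared across the toolkit.

An :class:`ENoseRecording` holds the raw response of the 11-sensor gas
array over the sampling window; a :class:`Spectrum` holds a single
near-infrared log(1/R) absorbance vector on its wavenumber grid; a
:class:`FeatureMatrix` is the samples x features table every
multivariate stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_SENSORS = 11
N_WAVENUMBERS = 1557


class DegenerateInputError(ValueError):
    """Raised when an input is constant or otherwise carries no information."""


@dataclass
class ENoseRecording:
    """Response time series of the gas-sensor array for one sample.

    Parameters
    ----------
    sample_id : str
        Manifest key of the sample.
    response : ndarray, shape (11, T)
        Sensor responses in ppm, one row per sensor, columns ordered in time.
    time_s : ndarray, shape (T,)
        Acquisition times in seconds from the start of the sampling stage.
    """

    sample_id: str
    response: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.response.ndim != 2 or self.response.shape[0] != N_SENSORS:
            raise ValueError(
                f"e-nose recording must have {N_SENSORS} sensor rows, "
                f"got shape {self.response.shape}"
            )
        if self.response.shape[1] < 1:
            raise ValueError("e-nose recording needs at least one time point")
        if self.time_s.shape != (self.response.shape[1],):
            raise ValueError("time grid length must match the response columns")


@dataclass
class Spectrum:
    """A near-infrared absorbance spectrum, log(1/R), on a fixed grid.

    The instrument convention stores wavenumbers descending
    (10,000 -> 4,000 cm^-1); downstream code must not rely on the order,
    only on strict monotonicity.
    """

    sample_id: str
    absorbance: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.absorbance.ndim != 1:
            raise ValueError("absorbance must be a vector")
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumber grid must match the absorbance vector")
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")


@dataclass
class FeatureMatrix:
    """Samples x features table with optional fitted standardization stats.

    ``center``/``scale`` are populated by :func:`fermfuse.preprocessing.standardize`
    from the fit rows only, so held-out rows can be transformed with
    training statistics.
    """

    values: pd.DataFrame
    center: pd.Series | None = None
    scale: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def rows(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.loc[list(sample_ids)],
            center=self.center,
            scale=self.scale,
            provenance=dict(self.provenance),
        )
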