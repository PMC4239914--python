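"""Synthetic solid-state-fermentation study generator.

Emulates the monitoring study the rest of the toolkit analyses: a
handful of latent volatile/chemical analytes follow logistic
trajectories over seven fermentation days (lag, exponential and
stationary phases in one parametric family), several independent
fermentation runs add between-run concentration shifts, and each
sampled replicate adds its own noise.  An 11-sensor gas array renders
the analyte mix as first-order rise curves over a 120 s sampling
window; a 1557-point NIR spectrometer renders it as Gaussian absorbance
bands on a descending 10,000 -> 4,000 cm^-1 grid with multiplicative
scatter.

The default logistic midpoints sit around days 2-3 with steepness
chosen so the day-5 -> day-6 increment is the smallest of all adjacent
days (the stationary-phase plateau): the two final classes are
near-identical by construction, which is the realistic hard case for
the classifier.

In *modality-split* mode the first half of the analytes is visible only
to the gas sensors (and saturates early, blurring late days) while the
second half is visible only to the spectrometer (and rises late,
blurring early days), so neither modality alone can separate all seven
classes but their fusion can.

All randomness flows from one master seed through named substreams
(run effects, per-sample replicate noise, per-sample e-nose and NIR
measurement noise), so regenerating any part of a study is
deterministic and modality-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ENoseRecording, N_SENSORS, N_WAVENUMBERS, Spectrum

__all__ = [
    "StudyDesign",
    "AnalyteTrajectory",
    "SensorModel",
    "SpectrumModel",
    "StudyConfig",
    "InvalidDesignError",
    "generate_study",
    "analyte_concentrations",
    "trajectory_value",
    "run_effects",
    "render_enose",
    "render_spectrum",
    "write_study",
    "read_study",
]


class InvalidDesignError(ValueError):
    """Raised for non-positive counts or otherwise impossible designs."""


# substream tags for the master seed
_SUB_RUN, _SUB_REP, _SUB_ENOSE, _SUB_NIR = 0, 1, 2, 3


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan: n_runs x n_days x n_reps samples."""

    n_runs: int = 4
    n_days: int = 7
    n_reps: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1 or self.n_days < 1 or self.n_reps < 1:
            raise InvalidDesignError(
                f"counts must be positive, got ({self.n_runs}, {self.n_days}, {self.n_reps})"
            )

    @property
    def n_samples(self) -> int:
        return self.n_runs * self.n_days * self.n_reps


@dataclass
class AnalyteTrajectory:
    """Logistic concentration trajectories of the latent analytes.

    value(day) = floor + (ceiling - floor) / (1 + exp(-steepness*(day - midpoint)))

    Midpoints default to days 2-3; at the default steepness the
    day-5 -> day-6 increment is under 5% of the trajectory range, which
    encodes the stationary-phase plateau.  ``run_effect_scale`` and
    ``rep_noise_scale`` are standard deviations of additive shifts in
    concentration units (trajectories are normalized to range ~1).
    """

    floor: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ceiling: np.ndarray = field(default_factory=lambda: np.ones(4))
    midpoint: np.ndarray = field(default_factory=lambda: np.array([2.0, 2.3, 2.6, 2.75]))
    steepness: np.ndarray = field(default_factory=lambda: np.array([2.0, 2.0, 2.0, 2.0]))
    run_effect_scale: float = 0.02
    rep_noise_scale: float = 0.02

    def __post_init__(self):
        self.floor = np.atleast_1d(np.asarray(self.floor, dtype=float))
        self.ceiling = np.atleast_1d(np.asarray(self.ceiling, dtype=float))
        self.midpoint = np.atleast_1d(np.asarray(self.midpoint, dtype=float))
        self.steepness = np.atleast_1d(np.asarray(self.steepness, dtype=float))
        n = len(self.floor)
        if not (len(self.ceiling) == len(self.midpoint) == len(self.steepness) == n):
            raise ValueError("per-analyte parameter arrays must share one length")
        if self.run_effect_scale < 0 or self.rep_noise_scale < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def n_analytes(self) -> int:
        return len(self.floor)

    @classmethod
    def modality_split(
        cls,
        run_effect_scale: float = 0.02,
        rep_noise_scale: float = 0.02,
    ) -> "AnalyteTrajectory":
        """Trajectories for the split study: early-saturating e-nose
        analytes (midpoints 1.2/1.6), late-rising NIR analytes
        (midpoints 2.88/2.92).  All four plateau by day 5: in both
        modalities the day-5 -> day-6 increment is strictly the
        smallest adjacent-day change.  The e-nose analytes saturate
        early, so the late days blur in the gas phase; the NIR
        analytes place both their lag-phase step (day 0 -> 1) and their
        stationary step (day 5 -> 6) at about one default-noise
        standard deviation, so the spectra blur at both ends while the
        mid-course days stay well separated — only the fusion sees all
        seven stages at the default noise level."""
        return cls(
            floor=np.zeros(4),
            ceiling=np.ones(4),
            midpoint=np.array([1.2, 1.6, 2.88, 2.92]),
            steepness=np.array([2.2, 2.2, 2.0, 1.95]),
            run_effect_scale=run_effect_scale,
            rep_noise_scale=rep_noise_scale,
        )


def trajectory_value(traj: AnalyteTrajectory, day: float) -> np.ndarray:
    """Noise-free logistic trajectory value per analyte."""
    z = traj.steepness * (day - traj.midpoint)
    return traj.floor + (traj.ceiling - traj.floor) / (1.0 + np.exp(-z))


def run_effects(traj: AnalyteTrajectory, n_runs: int, seed: int) -> np.ndarray:
    """Additive per-run concentration shifts, drawn once per run.

    Returns an (n_runs, n_analytes) array from the run substream of the
    master seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _SUB_RUN]))
    return traj.run_effect_scale * rng.standard_normal((n_runs, traj.n_analytes))


def analyte_concentrations(
    traj: AnalyteTrajectory,
    day: int,
    run: int,
    effects: np.ndarray,
    rng: np.random.Generator,
    max_day: int = 6,
) -> np.ndarray:
    """Concentration vector for one replicate: logistic + run shift + noise.

    Negative draws are clamped to zero (a concentration cannot be
    negative).  ``run`` is 1-based; ``effects`` comes from
    :func:`run_effects`; ``max_day`` is the last sampling day of the
    study design (6 under the default seven-day plan).
    """
    if not 0 <= day <= max_day:
        raise ValueError(f"day {day} out of range [0, {max_day}]")
    conc = trajectory_value(traj, day) + effects[run - 1]
    conc = conc + traj.rep_noise_scale * rng.standard_normal(traj.n_analytes)
    return np.clip(conc, 0.0, None)


@dataclass
class SensorModel:
    """First-order-rise gas-sensor array.

    Per sensor s the noiseless response to a concentration vector c is

        r_s(t) = baseline_s + (S c)_s * (1 - exp(-t / tau_s)) + drift * t

    with a non-negative sensitivity matrix S (11 x n_analytes) and rise
    time constants tau in seconds; the response is non-decreasing in t.
    Measurement noise (ppm) is added per time point.
    """

    sensitivity: np.ndarray
    tau: np.ndarray = field(default_factory=lambda: np.linspace(8.0, 30.0, N_SENSORS))
    baseline: np.ndarray = field(default_factory=lambda: np.full(N_SENSORS, 0.5))
    drift_scale: float = 0.0005
    noise_scale: float = 0.01
    time_s: np.ndarray = field(default_factory=lambda: np.arange(0.0, 121.0))

    def __post_init__(self):
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.sensitivity.shape[0] != N_SENSORS:
            raise ValueError(f"sensitivity must have {N_SENSORS} sensor rows")
        if np.any(self.sensitivity < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.any(self.tau <= 0):
            raise ValueError("rise time constants must be positive")

    @property
    def n_analytes(self) -> int:
        return self.sensitivity.shape[1]

    @classmethod
    def default(cls, n_analytes: int = 4, visible=None, **kw) -> "SensorModel":
        """Cross-sensitive array: every sensor responds to every visible
        analyte with a distinct fixed pattern.  ``visible`` masks the
        analytes the gas phase exposes (modality-split mode)."""
        rng = np.random.default_rng(71)  # fixed instrument fingerprint
        S = 0.3 + rng.uniform(0.0, 1.7, size=(N_SENSORS, n_analytes))
        if visible is not None:
            mask = np.zeros(n_analytes)
            mask[list(visible)] = 1.0
            S = S * mask
        return cls(sensitivity=S, **kw)


def render_enose(
    conc: np.ndarray,
    sensors: SensorModel,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> ENoseRecording:
    """Render one analyte mix as an 11-sensor recording over 0-120 s."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    gain = sensors.sensitivity @ conc  # (11,)
    t = sensors.time_s
    rise = 1.0 - np.exp(-t[None, :] / sensors.tau[:, None])  # (11, T)
    resp = sensors.baseline[:, None] + gain[:, None] * rise + sensors.drift_scale * t[None, :]
    if sensors.noise_scale > 0:
        resp = resp + sensors.noise_scale * rng.standard_normal(resp.shape)
    return ENoseRecording(sample_id, resp, t.copy())


@dataclass
class SpectrumModel:
    """Beer-Lambert NIR spectrum on the instrument's fixed grid.

    Each analyte contributes a few Gaussian bands; the noiseless
    spectrum is the concentration-weighted sum of the pure-component
    band profiles plus a linear baseline.  Scatter enters as the affine
    distortion alpha*x + beta with alpha ~ 1 + N(0, alpha_spread) and
    beta ~ N(0, beta_spread) per sample, which SNV removes exactly.

    ``band_centers``/``band_widths``/``band_heights`` are
    (n_analytes, n_bands) arrays in cm^-1 / cm^-1 / absorbance units.
    """

    band_centers: np.ndarray
    band_widths: np.ndarray
    band_heights: np.ndarray
    baseline_offset: float = 0.25
    # solid-sample log(1/R) spectra carry a large scatter-driven sloping
    # baseline; it anchors the SNV normalization so band amplitudes stay
    # quasi-linear in concentration after correction
    baseline_slope: float = 1.2e-4  # absorbance per cm^-1
    alpha_spread: float = 0.05
    beta_spread: float = 0.02
    noise_scale: float = 0.001
    wavenumbers: np.ndarray = field(
        default_factory=lambda: np.linspace(10000.0, 4000.0, N_WAVENUMBERS)
    )

    def __post_init__(self):
        self.band_centers = np.atleast_2d(np.asarray(self.band_centers, dtype=float))
        self.band_widths = np.atleast_2d(np.asarray(self.band_widths, dtype=float))
        self.band_heights = np.atleast_2d(np.asarray(self.band_heights, dtype=float))
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if len(self.wavenumbers) != N_WAVENUMBERS:
            raise ValueError(f"wavenumber grid must have {N_WAVENUMBERS} points")
        if self.band_centers.shape != self.band_widths.shape or (
            self.band_centers.shape != self.band_heights.shape
        ):
            raise ValueError("band parameter arrays must share one shape")
        if np.any(self.band_heights < 0) or np.any(self.band_widths <= 0):
            raise ValueError("band heights must be >= 0 and widths > 0")

    @property
    def n_analytes(self) -> int:
        return self.band_centers.shape[0]

    @classmethod
    def default(cls, n_analytes: int = 4, visible=None, **kw) -> "SpectrumModel":
        """Two overtone-region bands per visible analyte, spread over
        the 4,500-9,000 cm^-1 range."""
        rng = np.random.default_rng(72)  # fixed band library
        centers = rng.uniform(4500.0, 9000.0, size=(n_analytes, 2))
        widths = rng.uniform(60.0, 160.0, size=(n_analytes, 2))
        heights = rng.uniform(0.15, 0.5, size=(n_analytes, 2))
        if visible is not None:
            mask = np.zeros(n_analytes)
            mask[list(visible)] = 1.0
            heights = heights * mask[:, None]
        return cls(band_centers=centers, band_widths=widths, band_heights=heights, **kw)

    def pure_components(self) -> np.ndarray:
        """Noise-free unit-concentration spectrum of each analyte,
        shape (n_analytes, 1557)."""
        wn = self.wavenumbers[None, None, :]
        g = self.band_heights[:, :, None] * np.exp(
            -0.5 * ((wn - self.band_centers[:, :, None]) / self.band_widths[:, :, None]) ** 2
        )
        return g.sum(axis=1)


def render_spectrum(
    conc: np.ndarray,
    spectra: SpectrumModel,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> Spectrum:
    """Render one analyte mix as a scatter-distorted NIR spectrum."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if len(conc) != spectra.n_analytes:
        raise ValueError("concentration length must match the band library")
    signal = conc @ spectra.pure_components()  # Beer-Lambert additivity
    baseline = spectra.baseline_offset + spectra.baseline_slope * spectra.wavenumbers
    alpha = 1.0 + spectra.alpha_spread * rng.standard_normal()
    beta = spectra.beta_spread * rng.standard_normal()
    x = alpha * (signal + baseline) + beta
    if spectra.noise_scale > 0:
        x = x + spectra.noise_scale * rng.standard_normal(len(x))
    return Spectrum(sample_id, x, spectra.wavenumbers.copy())


@dataclass
class StudyConfig:
    """Bundle of the four generator blocks, YAML round-trippable."""

    design: StudyDesign = field(default_factory=StudyDesign)
    trajectories: AnalyteTrajectory = field(default_factory=AnalyteTrajectory)
    sensors: SensorModel | None = None
    spectra: SpectrumModel | None = None
    modality_split: bool = False

    def __post_init__(self):
        n = self.trajectories.n_analytes
        if self.modality_split:
            half = n // 2
            enose_vis = range(half)
            nir_vis = range(half, n)
        else:
            enose_vis = nir_vis = None
        if self.sensors is None:
            self.sensors = SensorModel.default(n, visible=enose_vis)
        if self.spectra is None:
            self.spectra = SpectrumModel.default(n, visible=nir_vis)

    @classmethod
    def split_study(
        cls,
        seed: int = 0,
        rep_noise_scale: float = 0.02,
        run_effect_scale: float = 0.02,
    ) -> "StudyConfig":
        """The canonical modality-split study at the default design."""
        return cls(
            design=StudyDesign(seed=seed),
            trajectories=AnalyteTrajectory.modality_split(
                run_effect_scale=run_effect_scale,
                rep_noise_scale=rep_noise_scale,
            ),
            modality_split=True,
        )


def generate_study(
    design: StudyDesign | None = None,
    trajectories: AnalyteTrajectory | None = None,
    sensors: SensorModel | None = None,
    spectra: SpectrumModel | None = None,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, list[ENoseRecording], list[Spectrum]]:
    """Generate a full labelled study: manifest, recordings and spectra.

    One recording and one spectrum per manifest row.  Deterministic for
    a fixed ``design.seed``: run effects are drawn once per run, and
    each sample's replicate/measurement noise comes from its own seed
    substream.

    Returns
    -------
    manifest : DataFrame with columns sample_id, run, day
    enose : list of ENoseRecording, manifest order
    nirs : list of Spectrum, manifest order
    """
    if config is not None:
        design = config.design
        trajectories = config.trajectories
        sensors = config.sensors
        spectra = config.spectra
    design = design or StudyDesign()
    trajectories = trajectories or AnalyteTrajectory()
    sensors = sensors or SensorModel.default(trajectories.n_analytes)
    spectra = spectra or SpectrumModel.default(trajectories.n_analytes)
    if sensors.n_analytes != trajectories.n_analytes or (
        spectra.n_analytes != trajectories.n_analytes
    ):
        raise ValueError("sensor and spectrum models must cover every analyte")

    effects = run_effects(trajectories, design.n_runs, design.seed)
    rows = []
    recordings: list[ENoseRecording] = []
    spectra_out: list[Spectrum] = []
    i = 0
    for run in range(1, design.n_runs + 1):
        for day in range(design.n_days):
            for rep in range(1, design.n_reps + 1):
                sid = f"R{run}D{day}S{rep}"
                rep_rng = np.random.default_rng(
                    np.random.SeedSequence([design.seed, _SUB_REP, i])
                )
                conc = analyte_concentrations(
                    trajectories, day, run, effects, rep_rng,
                    max_day=design.n_days - 1,
                )
                enose_rng = np.random.default_rng(
                    np.random.SeedSequence([design.seed, _SUB_ENOSE, i])
                )
                nir_rng = np.random.default_rng(
                    np.random.SeedSequence([design.seed, _SUB_NIR, i])
                )
                recordings.append(render_enose(conc, sensors, enose_rng, sample_id=sid))
                spectra_out.append(render_spectrum(conc, spectra, nir_rng, sample_id=sid))
                rows.append({"sample_id": sid, "run": run, "day": day})
                i += 1
    manifest = pd.DataFrame(rows, columns=["sample_id", "run", "day"])
    return manifest, recordings, spectra_out


# ---------------------------------------------------------------------------
# CSV / YAML I/O
# ---------------------------------------------------------------------------

def write_study(
    out_dir: str | Path,
    manifest: pd.DataFrame,
    recordings: list[ENoseRecording],
    spectra: list[Spectrum],
) -> None:
    """Write manifest, long-format e-nose and wide-format spectra CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)

    frames = []
    for rec in recordings:
        n_t = len(rec.time_s)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(rec.sample_id, N_SENSORS * n_t),
                    "sensor_id": np.repeat(np.arange(1, N_SENSORS + 1), n_t),
                    "time_s": np.tile(rec.time_s, N_SENSORS),
                    "response_ppm": rec.response.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "enose.csv", index=False)

    wide = pd.DataFrame(
        {s.sample_id: s.absorbance for s in spectra}
    ).T
    wide.columns = [f"{w:.3f}" for w in spectra[0].wavenumbers]
    wide.index.name = "sample_id"
    wide.to_csv(out / "nirs.csv")


def read_study(
    in_dir: str | Path,
) -> tuple[pd.DataFrame, list[ENoseRecording], list[Spectrum]]:
    """Read back the CSV dialects written by :func:`write_study`."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    long = pd.read_csv(src / "enose.csv")
    recordings = []
    for sid, block in long.groupby("sample_id", sort=False):
        piv = block.pivot(index="sensor_id", columns="time_s", values="response_ppm")
        piv = piv.sort_index()
        recordings.append(
            ENoseRecording(str(sid), piv.to_numpy(), piv.columns.to_numpy(dtype=float))
        )
    order = {sid: k for k, sid in enumerate(manifest["sample_id"])}
    recordings.sort(key=lambda r: order[r.sample_id])
    wide = pd.read_csv(src / "nirs.csv", index_col=0)
    wn = wide.columns.to_numpy(dtype=float)
    spectra = [
        Spectrum(str(sid), wide.loc[sid].to_numpy(dtype=float), wn)
        for sid in manifest["sample_id"]
    ]
    return manifest, recordings, spectra


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Write the generator configuration as YAML mirroring the model blocks."""
    def clean(d):
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()
        }

    payload = {
        "design": asdict(config.design),
        "trajectories": clean(asdict(config.trajectories)),
        "sensors": clean(asdict(config.sensors)),
        "spectra": clean(asdict(config.spectra)),
        "modality_split": config.modality_split,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> StudyConfig:
    payload = yaml.safe_load(Path(path).read_text())
    return StudyConfig(
        design=StudyDesign(**payload["design"]),
        trajectories=AnalyteTrajectory(**payload["trajectories"]),
        sensors=SensorModel(**payload["sensors"]) if "sensors" in payload else None,
        spectra=SpectrumModel(**payload["spectra"]) if "spectra" in payload else None,
        modality_split=payload.get("modality_split", False),
    )
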