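"""Forward model: a flowing scatter scene -> multi-channel PMT time-series.

For every sample time t and channel i the noiseless signal is

    P_i(t) = sum_c sum_j M_ij(dy_c) * exp(-2 dy_c^2 / w^2)
             * I_c * exp(-2 (x_c - x_n(t))^2 / w^2) * a(z_c, z_j)

where dy_c is the offset between scatterer c and the beam line along the flow
axis, x_n(t) is the sawtooth beam position, and the axial weight ``a`` assigns
the scatterer to its nearest focal plane (or spreads it with a Gaussian of
width ``axial_psf_sigma``).  The beam line advances through the object frame at
the flow speed; ``y_motion="exact"`` uses the instantaneous position at every
sample, ``y_motion="frozen"`` freezes it at the start of each scan, the
approximation the reconstruction inverts.

The module also materializes the model as an explicit dense matrix over a
voxel grid, the brute-force oracle used to verify the FFT reconstruction
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .errors import ResourceError, TransitError, ValidationError
from .instrument import (
    CrosstalkModel,
    InstrumentConfig,
    _parametric_matrix,
    crosstalk_profile,
)
from .phantoms import ScatterScene

__all__ = [
    "NoiseSpec",
    "PMTRecord",
    "VoxelGridSpec",
    "simulate",
    "build_dense_operator",
    "dense_reconstruct",
    "add_noise",
    "save_record",
    "load_record",
]

SCHEMA_VERSION = "1"

#: beam-envelope amplitudes below this are treated as zero
_ENVELOPE_FLOOR = 1e-15


@dataclass(frozen=True)
class NoiseSpec:
    """Detector-noise description: Poisson counting + additive Gaussian.

    ``poisson_scale`` is the expected photon count per signal unit (0 disables
    shot noise); ``gaussian_sigma`` is the additive read-noise RMS in signal
    units.
    """

    poisson_scale: float = 0.0
    gaussian_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sigma < 0:
            raise ValidationError("noise parameters must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "poisson_scale": self.poisson_scale,
            "gaussian_sigma": self.gaussian_sigma,
            "seed": self.seed,
        }


@dataclass
class PMTRecord:
    """Multi-channel PMT readout plus its timebase and configuration echo."""

    signals: np.ndarray
    sample_rate: float
    t0: float
    y_start: float
    config: InstrumentConfig
    crosstalk: CrosstalkModel
    noise_spec: dict | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValidationError("signals must be 2D (channels x samples)")
        if self.signals.shape[0] != self.config.n_channels:
            raise ValidationError("signal channel count disagrees with config")
        if not np.all(np.isfinite(self.signals)):
            raise ValidationError("signals must be finite")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def _axial_weights(z: float, config: InstrumentConfig) -> np.ndarray:
    """Channel weights for a scatterer at axial position z (um)."""
    z_planes = config.z_planes
    if config.axial_psf_sigma is None:
        w = np.zeros(config.n_channels)
        w[int(np.argmin(np.abs(z_planes - z)))] = 1.0
        return w
    return np.exp(-((z - z_planes) ** 2) / (2.0 * config.axial_psf_sigma**2))


def _sample_geometry(
    n_samples: int, config: InstrumentConfig, y_start: float, y_motion: str
) -> tuple[np.ndarray, np.ndarray]:
    """Beam (x, y) position at every sample, from integer sample indices.

    The scan index and in-scan phase are derived from ``sample // S`` and
    ``sample % S`` (the digitizer is synchronized to the sawtooth), avoiding
    floating-point scan-boundary jitter.
    """
    s = np.arange(n_samples)
    S = config.samples_per_scan
    n, k = s // S, s % S
    x_beam = -config.scan_range / 2.0 + k * config.pixel_size_x
    vy_um = config.flow_speed_vy * 1e6
    if y_motion == "exact":
        y_beam = y_start + vy_um * (s / config.sample_rate)
    elif y_motion == "frozen":
        y_beam = y_start + vy_um * n * config.scan_period
    else:
        raise ValidationError(f"unknown y_motion {y_motion!r}")
    return x_beam, y_beam


def _default_y_start(scene: ScatterScene, config: InstrumentConfig) -> float:
    dy = config.pixel_size_y
    lead = scene.extent[1, 0] - 4.0 * config.beam_waist_w
    return float(np.floor(lead / dy) * dy)


def _accumulate(
    signals: np.ndarray,
    positions: np.ndarray,
    intensities: np.ndarray,
    config: InstrumentConfig,
    crosstalk: CrosstalkModel,
    x_beam: np.ndarray,
    y_beam: np.ndarray,
) -> None:
    w = config.beam_waist_w
    parametric = crosstalk.mode in ("diagonal", "nearest_neighbor")
    m_param = _parametric_matrix(crosstalk, config.n_channels) if parametric else None
    for (xc, yc, zc), inten in zip(positions, intensities):
        if inten == 0.0:
            continue
        dy = yc - y_beam
        gy = np.exp(-2.0 * dy**2 / w**2)
        mask = gy > _ENVELOPE_FLOOR
        if not mask.any():
            continue
        gx = np.exp(-2.0 * (xc - x_beam[mask]) ** 2 / w**2)
        envelope = inten * gy[mask] * gx
        a = _axial_weights(zc, config)
        if parametric:
            signals[:, mask] += np.outer(m_param @ a, envelope)
        else:
            m = crosstalk_profile(crosstalk, dy[mask], config.n_channels)
            signals[:, mask] += (m @ a).T * envelope


def simulate(
    scene: ScatterScene,
    config: InstrumentConfig,
    crosstalk: CrosstalkModel | None = None,
    duration: float | None = None,
    noise: NoiseSpec | None = None,
    *,
    y_motion: str = "exact",
    y_start: float | None = None,
) -> PMTRecord:
    """Simulate the PMT array readout for a scene transiting the beam.

    Parameters
    ----------
    duration : float or None
        Acquisition length in seconds.  ``None`` auto-computes
        ``(y_span + 8 w) / vy`` so the whole scene plus beam tails transits;
        an explicit duration shorter than ``(y_span + 4 w) / vy`` raises
        :class:`~fsc3d.errors.TransitError`.
    y_start : float or None
        Beam-line position in the object frame at t = 0 (um), snapped to the
        inter-scan pitch by default so scene coordinates land on pixel rows.
    """
    if crosstalk is None:
        crosstalk = CrosstalkModel(mode="diagonal")
    if not np.all(np.isfinite(scene.positions)) or not np.all(np.isfinite(scene.intensities)):
        raise ValidationError("scene contains non-finite values")
    vy_um = config.flow_speed_vy * 1e6
    y_span = scene.y_span()
    min_duration = (y_span + 4.0 * config.beam_waist_w) / vy_um
    if duration is None:
        duration = (y_span + 8.0 * config.beam_waist_w) / vy_um
    elif duration < min_duration:
        raise TransitError(
            f"duration {duration:.3e} s < minimum transit {min_duration:.3e} s"
        )
    if y_start is None:
        y_start = _default_y_start(scene, config)

    n_samples = int(np.floor(duration * config.sample_rate))
    if n_samples < 1:
        raise TransitError("duration shorter than one sample")
    x_beam, y_beam = _sample_geometry(n_samples, config, y_start, y_motion)

    signals = np.zeros((config.n_channels, n_samples))
    _accumulate(signals, scene.positions, scene.intensities, config, crosstalk,
                x_beam, y_beam)

    if config.dead_time_fraction > 0.0:
        within = np.arange(n_samples) % config.samples_per_scan
        signals[:, within >= config.n_active_samples] = 0.0

    record = PMTRecord(
        signals=signals,
        sample_rate=config.sample_rate,
        t0=0.0,
        y_start=float(y_start),
        config=config,
        crosstalk=crosstalk,
        noise_spec=None,
    )
    if noise is not None:
        record = add_noise(record, noise.poisson_scale, noise.gaussian_sigma, noise.seed)
    return record


@dataclass(frozen=True)
class VoxelGridSpec:
    """Regular voxel grid: coordinate vectors (um) along x, y and z.

    Voxels are flattened in C order over (z, y, x), matching
    :class:`~fsc3d.reconstruct.Volume3D`.
    """

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xs", "ys", "zs"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.ndim != 1 or v.size == 0:
                raise ValidationError(f"{name} must be a nonempty 1D coordinate vector")
            object.__setattr__(self, name, v)

    @property
    def n_voxels(self) -> int:
        return self.xs.size * self.ys.size * self.zs.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.zs.size, self.ys.size, self.xs.size)

    def points(self) -> np.ndarray:
        """(n_voxels, 3) array of (x, y, z) positions in flattening order."""
        zz, yy, xx = np.meshgrid(self.zs, self.ys, self.xs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def scene(self, values: np.ndarray) -> ScatterScene:
        """A ScatterScene with one center per voxel carrying ``values``."""
        values = np.asarray(values, dtype=float).ravel()
        if values.size != self.n_voxels:
            raise ValidationError("values length must equal n_voxels")
        pts = self.points()
        extent = np.array(
            [
                [self.xs.min(), self.xs.max()],
                [self.ys.min(), self.ys.max()],
                [self.zs.min(), self.zs.max()],
            ]
        )
        return ScatterScene(pts, values, extent, {"generator": "voxel_grid"})


def build_dense_operator(
    scene_grid: VoxelGridSpec,
    config: InstrumentConfig,
    crosstalk: CrosstalkModel,
    duration: float,
    *,
    y_motion: str = "frozen",
    y_start: float | None = None,
    max_entries: float = 5e7,
) -> np.ndarray:
    """Materialize the forward model as a matrix of impulse responses.

    Column v holds the flattened (channels x samples) signal of a unit
    scatterer in voxel v, so ``operator @ values`` reproduces
    :func:`simulate` of the voxelized scene exactly (no noise).  Guarded
    against matrices above ``max_entries`` elements.  Defaults to the frozen-y
    motion model, the separable system the FFT pipeline inverts.
    """
    n_samples = int(np.floor(duration * config.sample_rate))
    entries = float(scene_grid.n_voxels) * config.n_channels * n_samples
    if entries > max_entries:
        raise ResourceError(
            f"dense operator would hold {entries:.3g} entries (> {max_entries:.3g})"
        )
    if y_start is None:
        y_start = _default_y_start(scene_grid.scene(np.ones(scene_grid.n_voxels)), config)
    x_beam, y_beam = _sample_geometry(n_samples, config, y_start, y_motion)
    pts = scene_grid.points()
    operator = np.zeros((config.n_channels * n_samples, scene_grid.n_voxels))
    col = np.zeros((config.n_channels, n_samples))
    for v in range(scene_grid.n_voxels):
        col[:] = 0.0
        _accumulate(col, pts[v : v + 1], np.ones(1), config, crosstalk, x_beam, y_beam)
        operator[:, v] = col.ravel()
    return operator


def dense_reconstruct(operator: np.ndarray, signals: np.ndarray, ridge: float) -> np.ndarray:
    """Tikhonov least squares against the dense operator (oracle route).

    Solves ``(A^T A + ridge * smax^2 I) f = A^T p`` where ``smax`` is the
    operator's largest singular value; returns the flattened voxel values.
    """
    p = np.asarray(signals, dtype=float).ravel()
    ata = operator.T @ operator
    smax2 = np.linalg.norm(operator, 2) ** 2
    rhs = operator.T @ p
    return np.linalg.solve(ata + ridge * smax2 * np.eye(ata.shape[0]), rhs)


def add_noise(
    record: PMTRecord, poisson_scale: float, gaussian_sigma: float, seed: int
) -> PMTRecord:
    """A noisy copy of ``record``; the original is left untouched.

    Shot noise first (``poisson(scale * signal) / scale``), then additive
    Gaussian read noise, both seeded.
    """
    if poisson_scale < 0 or gaussian_sigma < 0:
        raise ValidationError("noise parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    signals = record.signals.copy()
    if poisson_scale > 0:
        signals = rng.poisson(signals * poisson_scale).astype(float) / poisson_scale
    if gaussian_sigma > 0:
        signals = signals + rng.normal(0.0, gaussian_sigma, size=signals.shape)
    spec = NoiseSpec(poisson_scale, gaussian_sigma, seed).to_dict()
    return PMTRecord(
        signals=signals,
        sample_rate=record.sample_rate,
        t0=record.t0,
        y_start=record.y_start,
        config=record.config,
        crosstalk=record.crosstalk,
        noise_spec=spec,
    )


# ---- HDF5 container ----------------------------------------------------------


def save_record(record: PMTRecord, path) -> Path:
    """Write the record to HDF5: dataset ``signals`` plus metadata attributes."""
    path = Path(path)
    config_blob = {
        "instrument": record.config.to_dict(),
        "crosstalk": record.crosstalk.to_dict(),
        "y_start_um": record.y_start,
    }
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(
            "signals",
            data=np.ascontiguousarray(record.signals, dtype="<f8"),
            track_times=False,  # byte-identical re-runs
        )
        ds.attrs["units"] = "arbitrary"
        fh.attrs["sample_rate_hz"] = record.sample_rate
        fh.attrs["t0_s"] = record.t0
        fh.attrs["config_json"] = json.dumps(config_blob, sort_keys=True)
        fh.attrs["noise_json"] = json.dumps(record.noise_spec or {}, sort_keys=True)
        fh.attrs["schema_version"] = SCHEMA_VERSION
    return path


def load_record(path) -> PMTRecord:
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"record schema version {version!r} unsupported (expected {SCHEMA_VERSION!r})"
            )
        signals = fh["signals"][()]
        sample_rate = float(fh.attrs["sample_rate_hz"])
        t0 = float(fh.attrs["t0_s"])
        config_blob = json.loads(fh.attrs["config_json"])
        noise = json.loads(fh.attrs["noise_json"]) or None
    config = InstrumentConfig.from_dict(config_blob["instrument"])
    crosstalk = CrosstalkModel.from_dict(config_blob["crosstalk"])
    return PMTRecord(
        signals=signals,
        sample_rate=sample_rate,
        t0=t0,
        y_start=float(config_blob.get("y_start_um", 0.0)),
        config=config,
        crosstalk=crosstalk,
        noise_spec=noise,
    )
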