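"""Acquisition geometry, timing, scan law and the inter-plane crosstalk model.

The instrument scans a needle-shaped Gaussian beam (waist parameter ``w`` of
``exp(-2 r^2 / w^2)``) along x as an ideal sawtooth at ``scan_rate`` while the
sample flows along y at ``flow_speed_vy``.  Scattered light from each of
``n_channels`` axial focal planes ``z_j`` is redirected by a micro-mirror array
onto one PMT channel; imperfect redirection couples plane j into channel i with
a weight ``M_ij(y)``, the crosstalk matrix.  Both the forward simulator and the
reconstructor consume the objects defined here.

Units at the API boundary: lengths in micrometres, times in seconds, speeds in
metres per second.  Conversions are internal.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import RangeError, ValidationError

__all__ = [
    "InstrumentConfig",
    "CrosstalkModel",
    "beam_position",
    "scan_speed",
    "evaluate_crosstalk",
    "crosstalk_profile",
    "throughput",
    "energy_dose",
    "transit_time",
    "load_config",
]

#: metres per second corresponding to one micrometre per second
_UM_PER_M = 1e6


@dataclass(frozen=True)
class InstrumentConfig:
    """Static description of one acquisition configuration.

    Defaults reproduce the reference instrument: 200 kHz sawtooth scanning over
    40 um (scan speed 8 m/s, period 5 us), a ~3 um beam waist, 0.16 m/s flow,
    and an 8-channel PMT array with 2.5 um focal-plane spacing (20 um axial
    field of view).

    Parameters
    ----------
    scan_rate : float
        Sawtooth scan repetition rate in Hz.
    scan_range : float
        Peak-to-peak beam excursion along x, in um.
    beam_waist_w : float
        Gaussian beam parameter ``w`` of ``exp(-2 r^2 / w^2)``, in um.
    flow_speed_vy : float
        Sample flow speed along y in m/s.
    n_channels : int
        Number of PMT channels / focal planes.
    plane_spacing : float
        Axial separation between adjacent focal planes, in um.
    sample_rate : float or None
        Digitizer rate in samples/s.  ``None`` selects 64 samples per scan.
    axial_psf_sigma : float or None
        Optional Gaussian axial sensitivity width (um).  ``None`` assigns each
        scatterer to its nearest focal plane.
    dead_time_fraction : float
        Fraction of each scan blanked for flyback (0 = ideal sawtooth).
    magnification : float
        Detection-path magnification; metadata only.
    seed : int
        Default RNG seed recorded in outputs.
    """

    scan_rate: float = 200e3
    scan_range: float = 40.0
    beam_waist_w: float = 3.0
    flow_speed_vy: float = 0.16
    n_channels: int = 8
    plane_spacing: float = 2.5
    sample_rate: float | None = None
    axial_psf_sigma: float | None = None
    dead_time_fraction: float = 0.0
    magnification: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_rate <= 0:
            raise ValidationError("scan_rate must be positive")
        if self.scan_range < 0:
            raise ValidationError("scan_range must be nonnegative")
        if self.beam_waist_w <= 0:
            raise ValidationError("beam_waist_w must be positive")
        if self.flow_speed_vy <= 0:
            raise ValidationError("flow_speed_vy must be positive")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.plane_spacing <= 0:
            raise ValidationError("plane_spacing must be positive")
        if not 0.0 <= self.dead_time_fraction < 1.0:
            raise ValidationError("dead_time_fraction must be in [0, 1)")
        if self.sample_rate is None:
            object.__setattr__(self, "sample_rate", 64.0 * self.scan_rate)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.samples_per_scan < 8:
            raise ValidationError(
                f"sample_rate gives {self.samples_per_scan} samples per scan; >= 8 required"
            )
        # digitizer synchronized to the sawtooth: whole samples per scan
        if abs(self.sample_rate * self.scan_period - self.samples_per_scan) > 1e-6:
            raise ValidationError(
                "sample_rate must be an integer multiple of scan_rate "
                "(digitizer synchronized to the scan)"
            )
        if self.axial_psf_sigma is not None and self.axial_psf_sigma <= 0:
            raise ValidationError("axial_psf_sigma must be positive when set")
        ratio = self.scan_speed_vx / self.flow_speed_vy
        if ratio < 10.0:
            warnings.warn(
                f"vx/vy = {ratio:.2f} < 10: the frozen-y approximation used by the "
                "reconstruction is inaccurate at this flow speed",
                stacklevel=2,
            )

    # ---- derived quantities -------------------------------------------------

    @property
    def scan_period(self) -> float:
        """Scan period T in seconds (5 us at the default 200 kHz)."""
        return 1.0 / self.scan_rate

    @property
    def scan_speed_vx(self) -> float:
        """Beam scan speed vx = scan_range / T in m/s (8 m/s at defaults)."""
        return self.scan_range / _UM_PER_M * self.scan_rate

    @property
    def samples_per_scan(self) -> int:
        return int(round(self.sample_rate * self.scan_period))

    @property
    def n_active_samples(self) -> int:
        """Samples per scan after flyback blanking."""
        blanked = int(round(self.samples_per_scan * self.dead_time_fraction))
        return self.samples_per_scan - blanked

    @property
    def z_planes(self) -> np.ndarray:
        """Focal-plane positions z_j (um), centered symmetrically about 0."""
        j = np.arange(self.n_channels)
        return self.plane_spacing * (j - (self.n_channels - 1) / 2.0)

    @property
    def axial_fov(self) -> float:
        """Axial field of view n_channels * plane_spacing (um)."""
        return self.n_channels * self.plane_spacing

    @property
    def pixel_size_x(self) -> float:
        """x sampling pitch scan_range / samples_per_scan (um)."""
        return self.scan_range / self.samples_per_scan

    @property
    def pixel_size_y(self) -> float:
        """y pitch between scans, vy * T (um); 0.8 um at defaults."""
        return self.flow_speed_vy * _UM_PER_M * self.scan_period

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "InstrumentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> InstrumentConfig:
    """Read an :class:`InstrumentConfig` from flat key/value YAML text.

    Unknown keys raise :class:`~fsc3d.errors.ValidationError`; missing keys
    take the documented defaults.
    """
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a flat key/value mapping")
    return InstrumentConfig.from_dict(data)


def beam_position(t, config: InstrumentConfig):
    """Instantaneous beam x-position (um) under the ideal sawtooth scan law.

    ``x_n(t) = vx * (t - T/2 - nT)`` with ``n = floor(t / T)``: a linear ramp
    from -scan_range/2 to +scan_range/2 every period, with instantaneous
    flyback.  Accepts scalars or arrays; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("beam_position requires t >= 0")
    T = config.scan_period
    phase = np.mod(t, T)
    x = config.scan_speed_vx * _UM_PER_M * (phase - T / 2.0)
    return x if x.ndim else float(x)


def scan_speed(config: InstrumentConfig) -> float:
    """Beam scan speed vx = scan_range / T in m/s."""
    return config.scan_speed_vx


# ---- throughput / dose derivations ------------------------------------------


def throughput(volumetric_flow_ul_per_min: float, concentration_cells_per_ul: float) -> float:
    """Event rate in cells/s from sample flow and cell concentration.

    12 ul/min at 2000 cells/ul gives the instrument's nominal 400 cells/s.
    """
    if volumetric_flow_ul_per_min < 0 or concentration_cells_per_ul < 0:
        raise ValidationError("flow and concentration must be nonnegative")
    return volumetric_flow_ul_per_min * concentration_cells_per_ul / 60.0


def transit_time(length_um: float, speed_m_s: float) -> float:
    """Time (s) for a point moving at ``speed_m_s`` to cross ``length_um``."""
    if speed_m_s <= 0:
        raise ValidationError("speed must be positive")
    return length_um / _UM_PER_M / speed_m_s


def energy_dose(power_w: float, duration_s: float) -> float:
    """Optical energy delivered in microjoules: power x residence time.

    1.5 mW over 0.2 ms bounds the per-cell dose at 0.3 uJ.
    """
    if power_w < 0 or duration_s < 0:
        raise ValidationError("power and duration must be nonnegative")
    return power_w * duration_s * 1e6


# ---- crosstalk model ---------------------------------------------------------


@dataclass(frozen=True)
class CrosstalkModel:
    """Coupling M_ij(y) of object plane z_j into detector channel i.

    Modes
    -----
    ``diagonal``
        No crosstalk: M = identity at every y.
    ``nearest_neighbor``
        Unit diagonal with first off-diagonals equal to ``epsilon``
        (y-independent).
    ``tabulated``
        M sampled per (i, j) on a strictly increasing ``y_grid`` (um), e.g.
        from ray tracing or a measurement; evaluated by linear interpolation
        and only valid inside the grid.
    """

    mode: str = "diagonal"
    epsilon: float = 0.0
    table: np.ndarray | None = None
    y_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("diagonal", "nearest_neighbor", "tabulated"):
            raise ValidationError(f"unknown crosstalk mode {self.mode!r}")
        if self.mode == "nearest_neighbor":
            if not 0.0 <= self.epsilon < 1.0:
                raise ValidationError("epsilon must lie in [0, 1)")
        if self.mode == "tabulated":
            if self.table is None or self.y_grid is None:
                raise ValidationError("tabulated mode requires table and y_grid")
            table = np.asarray(self.table, dtype=float)
            y_grid = np.asarray(self.y_grid, dtype=float)
            if table.ndim != 3 or table.shape[0] != table.shape[1]:
                raise ValidationError("table must have shape (n, n, len(y_grid))")
            if y_grid.ndim != 1 or table.shape[2] != y_grid.size:
                raise ValidationError("y_grid length must match table's last axis")
            if y_grid.size < 2 or np.any(np.diff(y_grid) <= 0):
                raise ValidationError("y_grid must be strictly increasing with >= 2 samples")
            if np.any(table < 0):
                raise ValidationError("crosstalk couplings must be nonnegative")
            object.__setattr__(self, "table", table)
            object.__setattr__(self, "y_grid", y_grid)

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "epsilon": self.epsilon}
        if self.mode == "tabulated":
            d["table"] = np.asarray(self.table).tolist()
            d["y_grid"] = np.asarray(self.y_grid).tolist()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CrosstalkModel":
        kwargs = dict(data)
        if "table" in kwargs and kwargs["table"] is not None:
            kwargs["table"] = np.asarray(kwargs["table"], dtype=float)
        if "y_grid" in kwargs and kwargs["y_grid"] is not None:
            kwargs["y_grid"] = np.asarray(kwargs["y_grid"], dtype=float)
        return cls(**kwargs)


def _parametric_matrix(model: CrosstalkModel, n_channels: int) -> np.ndarray:
    if model.mode == "diagonal":
        return np.eye(n_channels)
    m = np.eye(n_channels)
    idx = np.arange(n_channels - 1)
    m[idx, idx + 1] = model.epsilon
    m[idx + 1, idx] = model.epsilon
    return m


def evaluate_crosstalk(model: CrosstalkModel, y: float, n_channels: int) -> np.ndarray:
    """The n x n matrix M(y) at lateral offset ``y`` (um).

    M never depends on x (the micro-mirrors span the full scan length).  In
    ``tabulated`` mode ``y`` must lie inside the table's y_grid.
    """
    return crosstalk_profile(model, np.asarray([y], dtype=float), n_channels)[0]


def crosstalk_profile(model: CrosstalkModel, y: np.ndarray, n_channels: int) -> np.ndarray:
    """Vectorized :func:`evaluate_crosstalk`: shape (len(y), n, n)."""
    y = np.asarray(y, dtype=float)
    if model.mode in ("diagonal", "nearest_neighbor"):
        m = _parametric_matrix(model, n_channels)
        return np.broadcast_to(m, (y.size, n_channels, n_channels)).copy()
    if model.table.shape[0] != n_channels:
        raise ValidationError(
            f"tabulated crosstalk is {model.table.shape[0]}-channel, config has {n_channels}"
        )
    lo, hi = model.y_grid[0], model.y_grid[-1]
    if np.any(y < lo) or np.any(y > hi):
        raise RangeError(f"y outside tabulated range [{lo}, {hi}] um")
    out = np.empty((y.size, n_channels, n_channels))
    for i in range(n_channels):
        for j in range(n_channels):
            out[:, i, j] = np.interp(y, model.y_grid, model.table[i, j])
    return out
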