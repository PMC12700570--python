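"""Spatiotemporal reconstruction: PMT time-series -> 3D scatter volume.

The pipeline inverts the separable frozen-y forward model in four stages:

1. **Demultiplex** — map sample k of scan n on channel i to pixel
   (row n, column k): x from the sawtooth beam position within the scan,
   y from the flow displacement vy*T between scans.
2. **Deconvolve x** — each image row is the object row convolved with the
   beam profile exp(-2 x^2 / w^2); undo it in the Fourier domain with a
   regularized inverse-Gaussian (Wiener) filter.
3. **Unmix planes per k_y** — along flow the channel images are the plane
   images convolved with kernels M_ij(y) exp(-2 y^2 / w^2); in the y-frequency
   domain this is, per k_y, an n_channels x n_channels linear system with
   matrix U_ij(k_y) = F_y{M_ij(y) exp(-2 y^2 / w^2)}, solved by
   Tikhonov-regularized least squares.
4. **Assemble** — inverse y-FFT and stack planes in ascending z_j.

Fourier convention: ordinary frequency (kernel e^{-2 pi i k x}), under which
the transform of exp(-2 x^2 / w^2) is w sqrt(pi/2) exp(-pi^2 w^2 k^2 / 2) and
the inverse filter of stage 2 is its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import (
    InstabilityError,
    InsufficientDataError,
    SingularityError,
    ValidationError,
)
from .forward_sim import PMTRecord
from .instrument import CrosstalkModel, InstrumentConfig, crosstalk_profile

__all__ = [
    "ChannelImageStack",
    "USpectrum",
    "Volume3D",
    "DeconvParams",
    "ReconParams",
    "demultiplex",
    "deconvolve_x",
    "build_U",
    "invert_axial",
    "reconstruct_volume",
    "resample_volume",
    "compensate_flow_speed",
    "threshold_volume",
    "save_volume",
    "load_volume",
]


@dataclass
class ChannelImageStack:
    """Per-channel 2D (y, x) images demultiplexed from the time series."""

    images: np.ndarray  # (n_channels, n_y, n_x)
    pixel_size_x: float
    pixel_size_y: float
    origin: tuple[float, float]  # (x, y) of pixel (0, 0) center, um

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValidationError("images must be 3D (channels, y, x)")
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise ValidationError("pixel sizes must be positive")

    @property
    def n_channels(self) -> int:
        return self.images.shape[0]

    @property
    def n_y(self) -> int:
        return self.images.shape[1]

    @property
    def n_x(self) -> int:
        return self.images.shape[2]


@dataclass(frozen=True)
class USpectrum:
    """Per-k_y crosstalk-times-beam coupling matrices U_ij(k_y)."""

    values: np.ndarray  # (n_y_freq, n_channels, n_channels), complex
    ky_grid: np.ndarray  # 1/um
    dy: float  # y sample spacing, um
    w: float  # beam waist parameter, um

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class Volume3D:
    """Reconstructed scatter intensity on a regular (z, y, x) grid."""

    intensities: np.ndarray  # (n_z, n_y, n_x)
    voxel_size: tuple[float, float, float]  # (dz, dy, dx), um
    origin: tuple[float, float, float]  # (z, y, x) of voxel (0,0,0) center, um
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("volume intensities must be finite")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_center(self, index: tuple[int, int, int]) -> np.ndarray:
        """Physical (z, y, x) position (um) of a voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.voxel_size)


@dataclass(frozen=True)
class DeconvParams:
    """Regularization of the inverse-Gaussian x filter.

    ``epsilon`` sets the Wiener floor (relative to the peak of |H|^2);
    ``epsilon <= 0`` requests the exact inverse, refused when any occupied
    frequency would be amplified beyond ``max_gain``.  ``filter_form``
    "discrete" uses the DFT of the sampled beam kernel (exact for the sampled
    model); "gaussian" uses the closed form exp(-pi^2 w^2 k^2 / 2).
    """

    epsilon: float = 1e-3
    max_gain: float = 1e3
    clip_negative: bool = False
    filter_form: str = "discrete"


@dataclass(frozen=True)
class ReconParams:
    """End-to-end reconstruction parameters."""

    deconv: DeconvParams = DeconvParams()
    ridge: float = 1e-6
    y_pad: str = "pow2"  # zero-pad rows to the next power of two


def _centered_offsets(n: int, step: float) -> np.ndarray:
    """Sample offsets in FFT layout: index 0 <-> offset 0, wrapping negatives."""
    k = np.arange(n)
    return ((k + n // 2) % n - n // 2) * step


def demultiplex(record: PMTRecord, config: InstrumentConfig) -> ChannelImageStack:
    """Fold the time series into per-channel (y, x) images.

    Sample k of scan n on channel i becomes pixel (row n, column k); rows are
    separated by the flow displacement vy*T, columns by scan_range /
    samples_per_scan.  A trailing partial scan is discarded; flyback-blanked
    columns are dropped.
    """
    if record.n_channels != config.n_channels:
        raise ValidationError("record channel count disagrees with config")
    if not np.isclose(record.sample_rate, config.sample_rate, rtol=1e-9):
        raise ValidationError("record sample rate disagrees with config")
    s = config.samples_per_scan
    n_rows = record.n_samples // s
    if n_rows < 2:
        raise InsufficientDataError(
            f"record holds {n_rows} complete scans; at least 2 required"
        )
    images = record.signals[:, : n_rows * s].reshape(record.n_channels, n_rows, s)
    images = images[:, :, : config.n_active_samples]
    return ChannelImageStack(
        images=images.copy(),
        pixel_size_x=config.pixel_size_x,
        pixel_size_y=config.pixel_size_y,
        origin=(-config.scan_range / 2.0, record.y_start),
    )


def _x_transfer(n_x: int, dx: float, w: float, form: str) -> np.ndarray:
    """|rfft|-layout transfer function of the beam profile along x."""
    if form == "discrete":
        kernel = np.exp(-2.0 * _centered_offsets(n_x, dx) ** 2 / w**2)
        return np.fft.rfft(kernel)
    if form == "gaussian":
        kernel_sum = np.exp(-2.0 * _centered_offsets(n_x, dx) ** 2 / w**2).sum()
        k = np.fft.rfftfreq(n_x, dx)
        return kernel_sum * np.exp(-0.5 * np.pi**2 * w**2 * k**2)
    raise ValidationError(f"unknown filter_form {form!r}")


def deconvolve_x(
    stack: ChannelImageStack, w: float, reg: DeconvParams = DeconvParams()
) -> ChannelImageStack:
    """Undo the beam blur along x on every image row.

    The row spectrum is multiplied by a regularized reciprocal of the beam
    transfer function H:  G = H* / (|H|^2 + eps (max|H|^2 - |H|^2)), which is
    exactly 1/H at the passband peak (so the w -> 0 limit is the identity) and
    rolls off the unstable high-frequency gain.  The output is the real part,
    optionally clipped at zero.
    """
    if w <= 0:
        raise ValidationError("w must be positive")
    n_x = stack.n_x
    h = _x_transfer(n_x, stack.pixel_size_x, w, reg.filter_form)
    habs2 = np.abs(h) ** 2
    hmax2 = habs2.max()
    hmax = np.sqrt(hmax2)
    spectra = np.fft.rfft(stack.images, axis=2)
    if reg.epsilon <= 0.0:
        gain = hmax / np.maximum(np.abs(h), np.finfo(float).tiny)
        content = np.abs(spectra).max(axis=(0, 1)) > 1e-12 * max(
            np.abs(spectra).max(), np.finfo(float).tiny
        )
        if np.any(content & (gain > reg.max_gain)):
            raise InstabilityError(
                "exact inverse refused: occupied frequencies exceed max_gain; "
                "set epsilon > 0"
            )
        g = 1.0 / h
    else:
        g = h.conj() / (habs2 + reg.epsilon * (hmax2 - habs2))
    cap = reg.max_gain / hmax
    gmag = np.abs(g)
    over = gmag > cap
    if np.any(over):
        scale = np.ones_like(gmag)
        scale[over] = cap / gmag[over]
        g = g * scale
    out = np.fft.irfft(spectra * g, n=n_x, axis=2)
    if reg.clip_negative:
        out = np.clip(out, 0.0, None)
    return replace(stack, images=out)


def build_U(
    crosstalk: CrosstalkModel,
    w: float,
    y_window: float,
    n_y: int,
    n_channels: int | None = None,
) -> USpectrum:
    """Discrete Fourier transform along y of M_ij(y) exp(-2 y^2 / w^2).

    Sampled on an ``n_y``-point grid of pitch ``y_window / n_y`` and scaled by
    the pitch so it approximates the continuous ordinary-frequency transform:
    for diagonal M, U_jj(k_y) ~= m_jj w sqrt(pi/2) exp(-pi^2 w^2 k_y^2 / 2).
    ``y_window`` must cover the Gaussian support (>= 6 w).
    """
    if w <= 0:
        raise ValidationError("w must be positive")
    if n_y < 2:
        raise ValidationError("n_y must be >= 2")
    if y_window < 6.0 * w:
        raise ValidationError("y_window must be >= 6 w to capture the beam envelope")
    if n_channels is None:
        if crosstalk.mode == "tabulated":
            n_channels = crosstalk.table.shape[0]
        else:
            raise ValidationError("n_channels is required for parametric crosstalk modes")
    dy = y_window / n_y
    y = _centered_offsets(n_y, dy)
    gauss = np.exp(-2.0 * y**2 / w**2)
    kernel = np.zeros((n_y, n_channels, n_channels))
    live = gauss > 1e-16
    if live.any():
        m = crosstalk_profile(crosstalk, y[live], n_channels)
        kernel[live] = m * gauss[live, None, None]
    values = dy * np.fft.fft(kernel, axis=0)
    return USpectrum(
        values=values, ky_grid=np.fft.fftfreq(n_y, dy), dy=dy, w=w
    )


def invert_axial(
    stack_deconvolved: ChannelImageStack,
    U: USpectrum,
    ridge: float = 1e-6,
    z_planes: np.ndarray | None = None,
) -> Volume3D:
    """Unmix the axial crosstalk per y-frequency and assemble the volume.

    For every (x, k_y) the n-channel system U f = V is solved by Tikhonov
    least squares ``(U^H U + ridge * smax^2 I) f = U^H V`` with ``smax`` the
    largest singular value of U over all k_y; ``ridge = 0`` uses the bare
    solve and raises :class:`~fsc3d.errors.SingularityError` if any U(k_y) is
    singular to machine precision.  Planes are ordered by ascending z_j.
    """
    if ridge < 0:
        raise ValidationError("ridge must be nonnegative")
    n_pad = U.values.shape[0]
    if n_pad < stack_deconvolved.n_y:
        raise ValidationError("U's k_y grid is shorter than the stack's y extent")
    if not np.isclose(U.dy, stack_deconvolved.pixel_size_y, rtol=1e-9):
        raise ValidationError("U's y pitch disagrees with the stack's pixel_size_y")
    if U.n_channels != stack_deconvolved.n_channels:
        raise ValidationError("U channel count disagrees with the stack")

    n_ch = U.n_channels
    vhat = np.fft.fft(stack_deconvolved.images, n=n_pad, axis=1)  # (ch, ky, x)
    vhat = np.moveaxis(vhat, 0, 1)  # (ky, ch, x)
    svals = np.linalg.svd(U.values, compute_uv=False)
    smax = svals.max()
    fhat = np.empty_like(vhat)
    eye = np.eye(n_ch)
    eps = np.finfo(float).eps
    for q in range(n_pad):
        u = U.values[q]
        if ridge == 0.0:
            if svals[q].min() <= eps * max(smax, eps) * n_ch:
                raise SingularityError(
                    f"U is singular at k_y = {U.ky_grid[q]:.6g} 1/um; use ridge > 0"
                )
            fhat[q] = np.linalg.solve(u, vhat[q])
        else:
            uh = u.conj().T
            fhat[q] = np.linalg.solve(uh @ u + ridge * smax**2 * eye, uh @ vhat[q])
    f = np.fft.ifft(fhat, axis=0)[: stack_deconvolved.n_y]  # (y, ch, x)
    f = np.moveaxis(f.real, 1, 0) * U.dy  # (ch=z, y, x); dy restores point units

    if z_planes is None:
        dz, z0 = 1.0, 0.0
    else:
        z_planes = np.asarray(z_planes, dtype=float)
        if z_planes.size != n_ch:
            raise ValidationError("z_planes length must equal n_channels")
        dz = float(z_planes[1] - z_planes[0]) if n_ch > 1 else 1.0
        z0 = float(z_planes[0])
    x0, y0 = stack_deconvolved.origin
    return Volume3D(
        intensities=f,
        voxel_size=(dz, stack_deconvolved.pixel_size_y, stack_deconvolved.pixel_size_x),
        origin=(z0, y0, x0),
        provenance={"ridge": ridge},
    )


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def reconstruct_volume(
    record: PMTRecord,
    config: InstrumentConfig | None = None,
    crosstalk: CrosstalkModel | None = None,
    params: ReconParams = ReconParams(),
) -> Volume3D:
    """Full pipeline: demultiplex -> deconvolve x -> per-k_y unmix -> volume.

    ``config`` and ``crosstalk`` default to the snapshots embedded in the
    record.  Deterministic given its inputs; parameters are echoed into the
    volume's provenance.
    """
    config = config or record.config
    crosstalk = crosstalk or record.crosstalk
    stack = demultiplex(record, config)
    w = config.beam_waist_w
    stack = deconvolve_x(stack, w, params.deconv)
    support = int(np.ceil(8.0 * w / stack.pixel_size_y)) + 1
    n_pad = _next_pow2(stack.n_y + support)
    u = build_U(
        crosstalk,
        w,
        y_window=n_pad * stack.pixel_size_y,
        n_y=n_pad,
        n_channels=config.n_channels,
    )
    vol = invert_axial(stack, u, params.ridge, z_planes=config.z_planes)
    vol.provenance = {
        "instrument": config.to_dict(),
        "crosstalk": crosstalk.to_dict(),
        "deconv": {
            "epsilon": params.deconv.epsilon,
            "max_gain": params.deconv.max_gain,
            "clip_negative": params.deconv.clip_negative,
            "filter_form": params.deconv.filter_form,
        },
        "ridge": params.ridge,
        "y_pad": n_pad,
        "y_start_um": record.y_start,
    }
    return vol


def resample_volume(vol: Volume3D, target_shape: tuple[int, int, int]) -> Volume3D:
    """Trilinear resampling onto ``target_shape`` (z, y, x) voxels.

    Voxel sizes are rescaled so the physical extent (voxel count times pitch)
    is preserved; constants and, for smooth volumes, the integrated intensity
    are preserved by the interpolation.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n < 2 for n in target_shape):
        raise ValidationError("target shape must be three dims, each >= 2")
    src = vol.intensities
    if target_shape == src.shape:
        return Volume3D(src.copy(), vol.voxel_size, vol.origin, dict(vol.provenance))
    factors = [t / s for t, s in zip(target_shape, src.shape)]
    out = ndimage.zoom(src, factors, order=1, mode="nearest", grid_mode=True)
    new_voxel = tuple(v * s / t for v, s, t in zip(vol.voxel_size, src.shape, target_shape))
    # grid_mode aligns cell edges: the box edge origin - voxel/2 is preserved
    new_origin = tuple(
        o - v / 2.0 + nv / 2.0 for o, v, nv in zip(vol.origin, vol.voxel_size, new_voxel)
    )
    return Volume3D(out, new_voxel, new_origin, dict(vol.provenance))


def compensate_flow_speed(
    stack: ChannelImageStack, vy_actual: float, vy_nominal: float
) -> ChannelImageStack:
    """Correct the y axis of a stack demultiplexed at the wrong flow speed.

    Rows were laid out assuming ``vy_nominal`` but the object actually moved at
    ``vy_actual`` per scan, so the true row pitch is off by vy_actual /
    vy_nominal.  The data are linearly resampled onto the nominal pitch,
    restoring the object's aspect ratio.  This is a plain y-rescaling, an
    approximation of a full flow-speed calibration.
    """
    if vy_actual <= 0 or vy_nominal <= 0:
        raise ValidationError("flow speeds must be positive")
    factor = vy_actual / vy_nominal
    if np.isclose(factor, 1.0, rtol=1e-12):
        return replace(stack, images=stack.images.copy())
    n_y = stack.n_y
    n_new = max(2, int(round(n_y * factor)))
    # target row m sits at old (fractional) row index m / factor
    idx = np.arange(n_new) / factor
    idx = np.clip(idx, 0, n_y - 1)
    i0 = np.floor(idx).astype(int)
    i1 = np.minimum(i0 + 1, n_y - 1)
    frac = (idx - i0)[None, :, None]
    out = stack.images[:, i0, :] * (1 - frac) + stack.images[:, i1, :] * frac
    return replace(stack, images=out)


def threshold_volume(vol: Volume3D, level: float) -> tuple[Volume3D, Volume3D]:
    """Binary mask at ``level`` x max plus the masked intensity copy.

    Negative reconstruction values are clipped to zero here (and only here),
    so rendering thresholds operate on nonnegative intensities.
    """
    if not 0.0 <= level <= 1.0:
        raise ValidationError("level must lie in [0, 1]")
    clipped = np.clip(vol.intensities, 0.0, None)
    maxv = clipped.max() if clipped.size else 0.0
    if maxv == 0.0:
        mask = np.ones_like(clipped, bool) if level == 0.0 else np.zeros_like(clipped, bool)
    else:
        mask = clipped >= level * maxv
    prov = dict(vol.provenance)
    prov["threshold_level"] = level
    mask_vol = Volume3D(mask.astype(np.uint8), vol.voxel_size, vol.origin, prov)
    masked = Volume3D(np.where(mask, clipped, 0.0), vol.voxel_size, vol.origin, prov)
    return mask_vol, masked


# ---- TIFF I/O ----------------------------------------------------------------


def save_volume(vol: Volume3D, path, dtype=np.float32) -> Path:
    """Write the volume as OME-TIFF (axes ZYX) with physical voxel sizes."""
    path = Path(path)
    dz, dy, dx = vol.voxel_size
    tifffile.imwrite(
        path,
        vol.intensities.astype(dtype),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


def load_volume(path) -> Volume3D:
    """Read a volume written by :func:`save_volume`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        voxel = (1.0, 1.0, 1.0)
        origin = (0.0, 0.0, 0.0)
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                voxel = (
                    float(px.get("PhysicalSizeZ", 1.0)),
                    float(px.get("PhysicalSizeY", 1.0)),
                    float(px.get("PhysicalSizeX", 1.0)),
                )
    if data.ndim == 2:
        data = data[None]
    return Volume3D(np.asarray(data, float), voxel, origin, {"source": str(path)})
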