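"""Reconstruction-fidelity metrics against known ground truth.

Peak detection with non-maximum suppression, greedy peak/truth matching,
bounding-box size estimation and before/after crosstalk ("ghost") ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EstimationError, ValidationError
from .phantoms import ScatterScene
from .reconstruct import ChannelImageStack, Volume3D

__all__ = [
    "PeakSet",
    "MatchReport",
    "detect_peaks",
    "match_peaks",
    "integrated_amplitude",
    "estimate_diameter",
    "crosstalk_suppression",
]


@dataclass
class PeakSet:
    """Detected local maxima in physical coordinates, brightest first."""

    peaks: pd.DataFrame  # columns: plane, x_um, y_um, z_um, amplitude
    threshold: float
    min_separation: float

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return self.peaks[["x_um", "y_um", "z_um"]].to_numpy()

    @property
    def amplitudes(self) -> np.ndarray:
        return self.peaks["amplitude"].to_numpy()

    def to_csv(self, path) -> None:
        self.peaks.to_csv(path, index=False, float_format="%.9g")


def _parabolic_refine(data: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, float]:
    """Sub-voxel peak position and amplitude by per-axis parabola fits.

    Voxel-max amplitudes of band-limited spots vary with the sub-voxel offset
    of the true maximum; the three-point parabola removes most of that bias.
    """
    pos = idx.astype(float)
    amp = float(data[tuple(idx)])
    for axis in (1, 2):  # y and x only: z planes are discrete detection planes
        i = idx[axis]
        if i == 0 or i == data.shape[axis] - 1:
            continue
        lo = tuple(idx + (np.arange(3) == axis) * -1)
        hi = tuple(idx + (np.arange(3) == axis))
        f_m, f_0, f_p = float(data[lo]), float(data[tuple(idx)]), float(data[hi])
        denom = f_m - 2.0 * f_0 + f_p
        if denom >= 0.0:
            continue  # not locally concave along this axis
        delta = 0.5 * (f_m - f_p) / denom
        pos[axis] = i + delta
        amp += -0.125 * (f_m - f_p) ** 2 / denom
    return pos, amp


def detect_peaks(vol: Volume3D, threshold: float = 0.5, min_separation: float = 1.5) -> PeakSet:
    """Local maxima above ``threshold`` x max with greedy suppression.

    Candidates are 26-connected local maxima of the nonnegative part of the
    volume; they are accepted in descending amplitude (ties broken by
    lexicographic (z, y, x) index) provided they lie at least
    ``min_separation`` um from every already-accepted peak.  Peak positions
    and amplitudes are refined to sub-voxel precision by per-axis parabolic
    interpolation.  An all-zero volume yields an empty set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    if min_separation < 0:
        raise ValidationError("min_separation must be nonnegative")
    data = np.clip(vol.intensities, 0.0, None)
    cols = ["plane", "x_um", "y_um", "z_um", "amplitude"]
    maxv = data.max() if data.size else 0.0
    if maxv <= 0.0:
        return PeakSet(pd.DataFrame(columns=cols), threshold, min_separation)
    footprint = np.ones((3,) * 3, bool)
    local_max = data == ndimage.maximum_filter(data, footprint=footprint, mode="constant")
    cand = np.argwhere(local_max & (data >= threshold * maxv))
    amps = data[tuple(cand.T)]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -amps))
    cand, amps = cand[order], amps[order]
    voxel = np.asarray(vol.voxel_size)
    origin = np.asarray(vol.origin)
    phys = origin + cand * voxel  # (n, 3) in (z, y, x)
    kept: list[int] = []
    for i in range(len(cand)):
        if all(np.linalg.norm(phys[i] - phys[j]) >= min_separation for j in kept):
            kept.append(i)
    refined_pos = np.empty((len(kept), 3))
    refined_amp = np.empty(len(kept))
    for out_i, i in enumerate(kept):
        sub, amp = _parabolic_refine(data, cand[i])
        refined_pos[out_i] = origin + sub * voxel
        refined_amp[out_i] = amp
    rows = pd.DataFrame(
        {
            "plane": cand[kept, 0],
            "x_um": refined_pos[:, 2],
            "y_um": refined_pos[:, 1],
            "z_um": refined_pos[:, 0],
            "amplitude": refined_amp,
        },
        columns=cols,
    )
    return PeakSet(rows, threshold, min_separation)


def integrated_amplitude(vol: Volume3D, position_um, radius_um: float = 2.5) -> float:
    """Source strength at a peak: in-plane window sum of the raw intensities.

    The reconstructed spot of a point source is band-limited, so its voxel
    maximum varies with the sub-voxel offset while its integral does not.
    Sums the *unclipped* volume (sidelobes are oscillatory and cancel) over
    voxels within ``radius_um`` of the position along x and y, on the plane
    nearest the position's z.
    """
    if radius_um <= 0:
        raise ValidationError("radius_um must be positive")
    x, y, z = np.asarray(position_um, dtype=float)
    oz, oy, ox = vol.origin
    dz, dy, dx = vol.voxel_size
    iz = int(np.clip(round((z - oz) / dz), 0, vol.shape[0] - 1))
    ry = int(np.ceil(radius_um / dy))
    rx = int(np.ceil(radius_um / dx))
    iy = int(round((y - oy) / dy))
    ix = int(round((x - ox) / dx))
    ys = slice(max(0, iy - ry), min(vol.shape[1], iy + ry + 1))
    xs = slice(max(0, ix - rx), min(vol.shape[2], ix + rx + 1))
    return float(vol.intensities[iz, ys, xs].sum())


@dataclass
class MatchReport:
    """Greedy peak-to-truth assignment summary."""

    recall: float
    precision: float
    n_truth: int
    n_found: int
    n_matched: int
    distances: np.ndarray  # per-match Euclidean distance, um
    matches: list[tuple[int, int]]  # (found index, truth index)

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "n_truth": self.n_truth,
            "n_found": self.n_found,
            "n_matched": self.n_matched,
            "max_distance_um": float(self.distances.max()) if len(self.distances) else None,
            "mean_distance_um": float(self.distances.mean()) if len(self.distances) else None,
        }


def match_peaks(found: PeakSet, truth: ScatterScene, max_dist: float) -> MatchReport:
    """Greedy nearest-neighbor matching without replacement.

    Found peaks are processed in descending amplitude; each claims its nearest
    unmatched ground-truth scatterer within ``max_dist`` um.  Recall is
    matched truth over total truth, precision matched found over total found.
    """
    if max_dist <= 0:
        raise ValidationError("max_dist must be positive")
    truth_pos = truth.positions
    found_pos = found.positions
    taken = np.zeros(len(truth_pos), bool)
    matches: list[tuple[int, int]] = []
    dists: list[float] = []
    for i in range(len(found_pos)):
        if not len(truth_pos) or taken.all():
            break
        d = np.linalg.norm(truth_pos - found_pos[i], axis=1)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            taken[j] = True
            matches.append((i, j))
            dists.append(float(d[j]))
    n_truth, n_found, n_matched = len(truth_pos), len(found_pos), len(matches)
    return MatchReport(
        recall=n_matched / n_truth if n_truth else 0.0,
        precision=n_matched / n_found if n_found else 0.0,
        n_truth=n_truth,
        n_found=n_found,
        n_matched=n_matched,
        distances=np.asarray(dists),
        matches=matches,
    )


def estimate_diameter(vol: Volume3D, threshold: float = 0.1) -> float:
    """Object diameter (um) from the suprathreshold bounding box.

    Mean of the three axis extents (voxel count times pitch) of the mask
    ``intensities >= threshold * max``.  Extent-based rather than
    volume-equivalent because shells reconstruct hollow.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    data = np.clip(vol.intensities, 0.0, None)
    maxv = data.max() if data.size else 0.0
    if maxv <= 0.0:
        raise EstimationError("volume has no suprathreshold voxels")
    level = threshold * maxv
    if not (data >= level).any():
        raise EstimationError("volume has no suprathreshold voxels")
    extents = []
    for axis, pitch in enumerate(vol.voxel_size):
        prof = data.max(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(prof >= level)
        i0, i1 = idx[0], idx[-1]
        # sub-voxel refinement: interpolate the crossing into the neighbors
        left = i0 - (
            (prof[i0] - level) / (prof[i0] - prof[i0 - 1])
            if i0 > 0 and prof[i0] > prof[i0 - 1] else 0.5
        )
        right = i1 + (
            (prof[i1] - level) / (prof[i1] - prof[i1 + 1])
            if i1 < len(prof) - 1 and prof[i1] > prof[i1 + 1] else 0.5
        )
        extents.append((right - left) * pitch)
    return float(np.mean(extents))


def crosstalk_suppression(
    vol_recon: Volume3D, stack_raw: ChannelImageStack, truth: ScatterScene
) -> dict:
    """Ghost-to-true response ratio before vs after reconstruction.

    ``before`` is the max response on channels whose focal plane holds no
    ground-truth scatterer divided by the max on-plane channel response in the
    raw demultiplexed stack; ``after`` is the same ratio measured across the
    reconstructed planes.  The suppression factor is before / after.  Requires
    a truth scene that leaves at least one plane empty.
    """
    n_planes = vol_recon.shape[0]
    if stack_raw.n_channels != n_planes:
        raise ValidationError("stack and volume disagree on plane count")
    z0, dz = vol_recon.origin[0], vol_recon.voxel_size[0]
    z_planes = z0 + dz * np.arange(n_planes)
    occupied = set(
        int(np.argmin(np.abs(z_planes - z))) for z in truth.positions[:, 2]
    ) if truth.n_centers else set()
    empty = [j for j in range(n_planes) if j not in occupied]
    if not occupied:
        raise ValidationError("truth scene holds no scatterers")
    if not empty:
        raise ValidationError("crosstalk ratio needs at least one empty plane")

    def ratio(per_plane_max: np.ndarray) -> float | None:
        on = max(per_plane_max[j] for j in occupied)
        if on <= 0:
            raise EstimationError("zero on-plane response; ratio undefined")
        off = max(per_plane_max[j] for j in empty)
        return max(off, 0.0) / on

    before = ratio(stack_raw.images.reshape(n_planes, -1).max(axis=1))
    after = ratio(np.clip(vol_recon.intensities, 0, None).reshape(n_planes, -1).max(axis=1))
    if before == 0.0:
        return {"before": 0.0, "after": after, "suppression_factor": None,
                "note": "no crosstalk present"}
    return {
        "before": before,
        "after": after,
        "suppression_factor": before / after if after > 0 else float("inf"),
    }
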