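"""Ground-truth scatter scenes mimicking the instrument's validation objects.

Every downstream stage (forward simulation, reconstruction, metrics) is tested
against scenes produced here: sparse point grids on the focal planes, a
terraced micro-structure with surface bumps, porous-bead simulants and
cell-with-surface-beads phantoms.  Scatterers are ideal points with additive,
incoherent intensities; continuous objects are represented by dense point
sampling.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import PackingError, ValidationError

__all__ = [
    "ScatterCenter",
    "ScatterScene",
    "grid_phantom",
    "terrace_phantom",
    "bead_shell_phantom",
    "cell_phantom",
    "save_scene",
    "load_scene",
]


class ScatterCenter(NamedTuple):
    """A single point scatterer: position (um, y along flow) and strength."""

    x: float
    y: float
    z: float
    intensity: float


@dataclass
class ScatterScene:
    """A 3D distribution of point scatterers with a bounding extent.

    Attributes
    ----------
    positions : (n, 3) array
        Scatterer coordinates (x, y, z) in um.
    intensities : (n,) array
        Nonnegative scatter strengths (arbitrary units).
    extent : (3, 2) array
        Bounding box [[xmin, xmax], [ymin, ymax], [zmin, zmax]] in um.
    metadata : dict
        Generator name, parameters, seed and any auxiliary ground truth
        (e.g. bead positions, terrace->z mapping).
    """

    positions: np.ndarray
    intensities: np.ndarray
    extent: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        self.extent = np.asarray(self.extent, dtype=float).reshape(3, 2)
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape[1] != 3:
            raise ValidationError("positions must have shape (n, 3)")
        if self.intensities.shape[0] != self.positions.shape[0]:
            raise ValidationError("positions and intensities disagree in length")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("scatterer positions must be finite")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValidationError("intensities must be finite and nonnegative")
        eps = 1e-9
        for axis in range(3):
            lo, hi = self.extent[axis]
            vals = self.positions[:, axis]
            if vals.size and (vals.min() < lo - eps or vals.max() > hi + eps):
                raise ValidationError(f"centers fall outside declared extent on axis {axis}")

    @property
    def n_centers(self) -> int:
        return self.positions.shape[0]

    @property
    def centers(self) -> list[ScatterCenter]:
        return [
            ScatterCenter(*pos, inten)
            for pos, inten in zip(self.positions, self.intensities)
        ]

    def y_span(self) -> float:
        return float(self.extent[1, 1] - self.extent[1, 0])

    @classmethod
    def from_centers(cls, centers: Sequence[ScatterCenter], metadata: dict | None = None,
                     extent: np.ndarray | None = None) -> "ScatterScene":
        pos = np.array([[c.x, c.y, c.z] for c in centers], dtype=float).reshape(-1, 3)
        inten = np.array([c.intensity for c in centers], dtype=float)
        if extent is None:
            extent = np.stack([pos.min(axis=0), pos.max(axis=0)], axis=1) if len(centers) \
                else np.zeros((3, 2))
        return cls(pos, inten, extent, metadata or {})

    def shifted(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "ScatterScene":
        """A copy translated by (dx, dy, dz) um."""
        shift = np.array([dx, dy, dz])
        return ScatterScene(
            self.positions + shift,
            self.intensities.copy(),
            self.extent + shift[:, None],
            dict(self.metadata),
        )


def _centered_planes(n_planes: int, plane_spacing: float) -> np.ndarray:
    j = np.arange(n_planes)
    return plane_spacing * (j - (n_planes - 1) / 2.0)


def grid_phantom(
    k_per_plane: int,
    n_planes: int = 8,
    plane_spacing: float = 2.5,
    xy_extent: float = 24.0,
    min_separation: float = 5.0,
    intensities="equal",
    seed: int = 0,
    cross_plane_separation: float | None = None,
) -> ScatterScene:
    """``k_per_plane`` scatterers on each of ``n_planes`` focal planes.

    Positions are drawn uniformly in a centered ``xy_extent`` x ``xy_extent``
    um box by seeded rejection sampling under an in-plane minimum pairwise
    separation.  Centers on *different* planes additionally keep a lateral
    distance of ``cross_plane_separation`` (default ``min_separation / 2``) so
    no scatterer hides directly above another, keeping the scene resolvable
    at the instrument's ~1.5 um lateral resolution.  ``intensities`` is
    ``"equal"`` (all 1) or a length ``k_per_plane`` sequence repeated on every
    plane — e.g. ``(1, 2, 3, 4, 5)`` for the five-intensity validation scene.
    """
    if k_per_plane < 1:
        raise ValidationError("k_per_plane must be >= 1")
    if n_planes < 1:
        raise ValidationError("n_planes must be >= 1")
    if xy_extent <= 0 or min_separation < 0:
        raise ValidationError("xy_extent must be positive and min_separation nonnegative")
    if isinstance(intensities, str):
        if intensities != "equal":
            raise ValidationError("intensities must be 'equal' or a sequence")
        levels = np.ones(k_per_plane)
    else:
        levels = np.asarray(intensities, dtype=float)
        if levels.shape != (k_per_plane,):
            raise ValidationError("intensities sequence must have length k_per_plane")
        if np.any(levels < 0):
            raise ValidationError("intensities must be nonnegative")

    if cross_plane_separation is None:
        cross_plane_separation = min_separation / 2.0

    rng = np.random.default_rng(seed)
    half = xy_extent / 2.0
    z_vals = _centered_planes(n_planes, plane_spacing)
    positions = []
    other_planes: list[np.ndarray] = []
    for z in z_vals:
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < k_per_plane:
            attempts += 1
            if attempts > 5000 * k_per_plane:
                raise PackingError(
                    f"could not place {k_per_plane} centers with separation "
                    f"{min_separation} um in a {xy_extent} um box"
                )
            cand = rng.uniform(-half, half, size=2)
            if any(np.hypot(*(cand - p)) < min_separation for p in placed):
                continue
            if any(np.hypot(*(cand - p)) < cross_plane_separation for p in other_planes):
                continue
            placed.append(cand)
        for p in placed:
            positions.append([p[0], p[1], z])
        other_planes.extend(placed)
    positions = np.asarray(positions)
    inten = np.tile(levels, n_planes)
    extent = np.array([[-half, half], [-half, half], [z_vals[0], z_vals[-1]]])
    meta = {
        "generator": "grid",
        "k_per_plane": k_per_plane,
        "n_planes": n_planes,
        "plane_spacing": plane_spacing,
        "xy_extent": xy_extent,
        "min_separation": min_separation,
        "intensities": levels.tolist(),
        "seed": seed,
    }
    return ScatterScene(positions, inten, extent, meta)


def terrace_phantom(
    terrace_area: tuple[float, float] = (35.0, 8.0),
    step_height: float = 2.5,
    n_terraces: int = 8,
    bump_size: tuple[float, float, float] = (1.5, 1.0, 1.0),
    bumps_per_terrace: int = 2,
    edge_point_spacing: float = 1.75,
    seed: int = 0,
) -> ScatterScene:
    """A staircase of terraces with discrete surface bumps.

    Each terrace is ``terrace_area[0] x terrace_area[1]`` um^2 (x by y) and is
    raised ``step_height`` um above its predecessor; every bump measures
    ``bump_size`` um^3 and scatters from its center.  Terrace step edges also
    scatter, represented by points spaced ``edge_point_spacing`` um along x.
    Terrace z values are offset so the staircase is centered on z = 0, making
    each terrace coincide with one focal plane when ``step_height`` equals the
    plane spacing.  The terrace index -> z map is returned in metadata.
    """
    ax, ay = terrace_area
    if ax <= 0 or ay <= 0 or step_height <= 0 or min(bump_size) <= 0:
        raise ValidationError("terrace dimensions, step height and bump size must be positive")
    if n_terraces < 1 or bumps_per_terrace < 0:
        raise ValidationError("n_terraces must be >= 1 and bumps_per_terrace >= 0")

    rng = np.random.default_rng(seed)
    z_vals = step_height * (np.arange(n_terraces) - (n_terraces - 1) / 2.0)
    n_edge = max(2, int(np.floor(ax / edge_point_spacing)) + 1)
    edge_x = np.linspace(-ax / 2, ax / 2, n_edge)
    centers: list[list[float]] = []
    inten: list[float] = []
    for m, z in enumerate(z_vals):
        y0 = m * ay
        # leading step edge of terrace m
        for x in edge_x:
            centers.append([x, y0, z])
            inten.append(0.5)
        for _ in range(bumps_per_terrace):
            bx = rng.uniform(-ax / 2 + bump_size[0], ax / 2 - bump_size[0])
            by = rng.uniform(y0 + bump_size[1], y0 + ay - bump_size[1])
            centers.append([bx, by, z])
            inten.append(1.0)
    positions = np.asarray(centers)
    extent = np.array(
        [[-ax / 2, ax / 2], [0.0, n_terraces * ay], [z_vals[0], z_vals[-1]]]
    )
    meta = {
        "generator": "terrace",
        "terrace_area": list(terrace_area),
        "step_height": step_height,
        "n_terraces": n_terraces,
        "bump_size": list(bump_size),
        "bumps_per_terrace": bumps_per_terrace,
        "terrace_z_um": {str(m): float(z) for m, z in enumerate(z_vals)},
        "seed": seed,
    }
    return ScatterScene(positions, np.asarray(inten), extent, meta)


def bead_shell_phantom(
    diameter: float = 25.0,
    n_surface_points: int = 400,
    interior_density: float = 0.0,
    interior_intensity: float = 0.5,
    seed: int = 0,
) -> ScatterScene:
    """A porous-bead simulant: a spherical shell plus interior pore scatterers.

    ``n_surface_points`` unit-intensity scatterers are distributed uniformly on
    a sphere of the given diameter (um); interior "pores" are Poisson-sampled
    at ``interior_density`` per um^3, uniform in the ball, with intensity
    ``interior_intensity``.
    """
    if diameter <= 0:
        raise ValidationError("diameter must be positive")
    if n_surface_points < 1:
        raise ValidationError("n_surface_points must be >= 1")
    if interior_density < 0:
        raise ValidationError("interior_density must be nonnegative")
    rng = np.random.default_rng(seed)
    r = diameter / 2.0
    surf = rng.normal(size=(n_surface_points, 3))
    surf /= np.linalg.norm(surf, axis=1, keepdims=True)
    surf *= r
    volume = 4.0 / 3.0 * np.pi * r**3
    n_interior = rng.poisson(interior_density * volume)
    interior = np.empty((0, 3))
    if n_interior:
        pts = rng.normal(size=(n_interior, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= r * rng.uniform(0, 1, size=(n_interior, 1)) ** (1.0 / 3.0)
        interior = pts
    positions = np.vstack([surf, interior])
    inten = np.concatenate([np.ones(n_surface_points),
                            np.full(len(interior), interior_intensity)])
    extent = np.array([[-r, r], [-r, r], [-r, r]])
    meta = {
        "generator": "bead_shell",
        "diameter": diameter,
        "n_surface_points": n_surface_points,
        "interior_density": interior_density,
        "n_interior": int(len(interior)),
        "seed": seed,
    }
    return ScatterScene(positions, inten, extent, meta)


def cell_phantom(
    cell_diameter: float = 15.0,
    n_internal: int = 150,
    n_beads: int = 4,
    bead_intensity_ratio: float = 5.0,
    min_bead_separation: float = 2.0,
    seed: int = 0,
) -> ScatterScene:
    """A cell with cytoplasmic scatterers and optional bright surface beads.

    ``n_internal`` weak scatterers (intensities uniform in [0.5, 1.5], mean 1)
    fill the cell sphere; ``n_beads`` surface beads scatter at
    ``bead_intensity_ratio`` times the internal mean, reflecting the higher
    refractive-index contrast of polystyrene beads against cytoplasm.  Bead
    positions are returned in ``metadata["bead_positions_um"]`` for recovery
    scoring.
    """
    if cell_diameter <= 0:
        raise ValidationError("cell_diameter must be positive")
    if n_internal < 0 or n_beads < 0:
        raise ValidationError("counts must be nonnegative")
    if bead_intensity_ratio < 1:
        raise ValidationError("bead_intensity_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    r = cell_diameter / 2.0

    internal = np.empty((0, 3))
    if n_internal:
        pts = rng.normal(size=(n_internal, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= r * rng.uniform(0, 1, size=(n_internal, 1)) ** (1.0 / 3.0)
        internal = pts
    internal_int = rng.uniform(0.5, 1.5, size=len(internal))
    mean_int = internal_int.mean() if len(internal) else 1.0

    beads: list[np.ndarray] = []
    attempts = 0
    while len(beads) < n_beads:
        attempts += 1
        if attempts > 5000 * max(1, n_beads):
            raise PackingError("could not place surface beads with requested separation")
        cand = rng.normal(size=3)
        cand = cand / np.linalg.norm(cand) * r
        if all(np.linalg.norm(cand - b) >= min_bead_separation for b in beads):
            beads.append(cand)
    bead_pos = np.asarray(beads).reshape(-1, 3)

    positions = np.vstack([internal, bead_pos])
    inten = np.concatenate(
        [internal_int, np.full(len(bead_pos), bead_intensity_ratio * mean_int)]
    )
    extent = np.array([[-r, r], [-r, r], [-r, r]])
    meta = {
        "generator": "cell",
        "cell_diameter": cell_diameter,
        "n_internal": n_internal,
        "n_beads": n_beads,
        "bead_intensity_ratio": bead_intensity_ratio,
        "internal_mean_intensity": float(mean_int),
        "bead_positions_um": bead_pos.tolist(),
        "seed": seed,
    }
    return ScatterScene(positions, inten, extent, meta)


# ---- serialization -----------------------------------------------------------


def save_scene(scene: ScatterScene, basepath) -> tuple[Path, Path]:
    """Write ``<base>.csv`` (x_um, y_um, z_um, intensity) + ``<base>.json``."""
    base = Path(basepath)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    df = pd.DataFrame(
        {
            "x_um": scene.positions[:, 0],
            "y_um": scene.positions[:, 1],
            "z_um": scene.positions[:, 2],
            "intensity": scene.intensities,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {"extent_um": scene.extent.tolist(), "metadata": scene.metadata}
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return csv_path, json_path


def load_scene(basepath) -> ScatterScene:
    """Inverse of :func:`save_scene`; accepts the base path or the CSV path."""
    base = Path(basepath)
    csv_path = base if base.suffix == ".csv" else base.with_suffix(".csv")
    json_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    meta: dict = {}
    extent = None
    if json_path.exists():
        sidecar = json.loads(json_path.read_text())
        meta = sidecar.get("metadata", {})
        extent = np.asarray(sidecar.get("extent_um"))
    positions = df[["x_um", "y_um", "z_um"]].to_numpy()
    intensities = df["intensity"].to_numpy()
    if extent is None:
        if len(positions):
            extent = np.stack([positions.min(axis=0), positions.max(axis=0)], axis=1)
        else:
            extent = np.zeros((3, 2))
    return ScatterScene(positions, intensities, extent, meta)
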