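"""Scan-line B-mode ultrasound simulation over surface heart models.

The simulation follows the classic surface-model pipeline: the posed
heart is transformed into image coordinates, virtual scan lines are laid
out from the transducer geometry, each line's crossings with the
structure meshes are found with a spatial index (contract: identical to
brute-force all-triangle intersection), the inter-crossing segments are
filled with per-material grey values, and the filled lines are
scan-converted into a Cartesian B-mode image.  A ground-truth LabelSlice
(structure id per pixel) is produced with the same sampling.

Image frame convention: the probe contact point is the top-centre of the
image, x is lateral (to the image right), y is depth (down), z is the
out-of-plane normal; scan lines live in the z = 0 plane.  Pixel (row,
col) has its centre at y = (row + 0.5) * pixel_spacing, x = (col + 0.5 -
width/2) * pixel_spacing.  All lengths in mm; intensities 0-255.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _ray
from .heart_model import HeartModel, Material, MaterialTable, Pose, apply_pose

__all__ = [
    "ProbeConfig",
    "ScanLine",
    "Crossing",
    "SpatialIndex",
    "BModeImage",
    "LabelSlice",
    "compute_scanlines",
    "build_index",
    "intersect",
    "fill_scanline",
    "scan_convert",
    "simulate",
    "add_speckle",
]


class SimulationError(RuntimeError):
    pass


#: asymmetric unit vector for point-in-mesh parity rays (avoids the
#: symmetry planes of regular tessellations)
_CONTAIN_DIR = np.array([0.8014421281, 0.3912297843, 0.4524353462])
_CONTAIN_DIR = _CONTAIN_DIR / np.linalg.norm(_CONTAIN_DIR)


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeConfig:
    """Transducer + output image geometry.

    ``kind`` is "linear" (parallel scan lines across ``footprint_mm``) or
    "curvilinear" (radial lines from an arc of ``transducer_radius_mm``
    spanning ``fov_deg``).  ``interpolation`` ("nearest" | "bilinear")
    controls grey-image scan conversion; label slices always use nearest.
    """

    kind: str = "curvilinear"
    n_scanlines: int = 160
    scanline_depth_mm: float = 55.0
    samples_per_line: int = 256
    image_width_px: int = 300
    image_height_px: int = 300
    pixel_spacing_mm: float = 0.2
    fov_deg: float | None = 60.0
    transducer_radius_mm: float | None = 28.0
    footprint_mm: float | None = None
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "curvilinear"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        if self.n_scanlines < 1 or self.samples_per_line < 1:
            raise ValueError("scan line and sample counts must be >= 1")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.scanline_depth_mm <= 0 or self.pixel_spacing_mm <= 0:
            raise ValueError("depth and pixel spacing must be > 0")
        if self.kind == "curvilinear":
            if self.fov_deg is None or not (0 < self.fov_deg < 180):
                raise ValueError("curvilinear probe needs 0 < fov_deg < 180")
            if self.transducer_radius_mm is None or self.transducer_radius_mm <= 0:
                raise ValueError("curvilinear probe needs transducer_radius_mm > 0")
        else:
            if self.footprint_mm is None or self.footprint_mm <= 0:
                raise ValueError("linear probe needs footprint_mm > 0")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be 'nearest' or 'bilinear'")

    @property
    def sample_spacing_mm(self) -> float:
        return self.scanline_depth_mm / self.samples_per_line


@dataclass(frozen=True)
class ScanLine:
    """One acoustic ray in image coordinates (z = 0 plane)."""

    origin: np.ndarray
    direction: np.ndarray
    length: float
    sample_spacing_mm: float

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("scan line direction must be unit length")
        if self.length <= 0:
            raise ValueError("scan line length must be > 0")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def sample_distances(self) -> np.ndarray:
        n = int(round(self.length / self.sample_spacing_mm))
        return (np.arange(n) + 0.5) * self.sample_spacing_mm


@dataclass(frozen=True)
class Crossing:
    """A scan-line/surface crossover."""

    distance_mm: float
    structure: str
    entering: bool


@dataclass
class BModeImage:
    pixels: np.ndarray          # (H, W) uint8
    pixel_spacing_mm: float
    pose: Pose
    probe: ProbeConfig


@dataclass
class LabelSlice:
    """Structure-id image aligned with a BModeImage (0 = background)."""

    pixels: np.ndarray          # (H, W) int16
    label_map: dict[int, str] = field(default_factory=dict)

    def count(self, name: str) -> int:
        ids = [l for l, n in self.label_map.items() if n == name]
        if not ids:
            return 0
        return int(np.isin(self.pixels, ids).sum())


# ---------------------------------------------------------------------------
# scan-line layout
# ---------------------------------------------------------------------------

def compute_scanlines(probe: ProbeConfig) -> list[ScanLine]:
    """Scan-line origins/directions in the image frame, left to right."""
    n = probe.n_scanlines
    ds = probe.sample_spacing_mm
    lines = []
    if probe.kind == "linear":
        f = probe.footprint_mm
        xs = np.zeros(1) if n == 1 else np.linspace(-f / 2.0, f / 2.0, n)
        for x in xs:
            lines.append(ScanLine(np.array([x, 0.0, 0.0]),
                                  np.array([0.0, 1.0, 0.0]),
                                  probe.scanline_depth_mm, ds))
    else:
        r = probe.transducer_radius_mm
        half = np.deg2rad(probe.fov_deg) / 2.0
        angles = np.zeros(1) if n == 1 else np.linspace(-half, half, n)
        for a in angles:
            d = np.array([np.sin(a), np.cos(a), 0.0])
            origin = np.array([r * np.sin(a), r * np.cos(a) - r, 0.0])
            lines.append(ScanLine(origin, d, probe.scanline_depth_mm, ds))
    return lines


# ---------------------------------------------------------------------------
# spatial index
# ---------------------------------------------------------------------------

class SpatialIndex:
    """Acceleration structure over all triangles of a posed model.

    Queries are contractually identical to brute force over every
    triangle (same epsilon rule); the BVH only prunes empty space.
    """

    def __init__(self, model: HeartModel, leaf_size: int = 32):
        if not model.structures:
            raise ValueError("cannot index an empty model")
        tris = []
        tags = []
        self.structure_names = [s.name for s in model.structures]
        self.priorities = {s.name: s.priority for s in model.structures}
        self.declaration_order = {s.name: i
                                  for i, s in enumerate(model.structures)}
        self.materials_by_structure = {
            s.name: s.material_id for s in model.structures}
        face_normals = []
        for i, s in enumerate(model.structures):
            tris.append(s.mesh.triangles)
            face_normals.append(s.mesh.face_normals)
            tags.append(np.full(len(s.mesh.faces), i, dtype=np.int32))
        self.triangles = np.concatenate(tris)
        self.face_normals = np.concatenate(face_normals)
        self.tri_structure = np.concatenate(tags)
        self._bvh = _ray.BVH(self.triangles, leaf_size=leaf_size)

    def _crossings_from_hits(self, t: np.ndarray, idx: np.ndarray,
                             direction: np.ndarray) -> list[Crossing]:
        out = []
        for ti, tri in zip(t, idx):
            s = self.structure_names[self.tri_structure[tri]]
            entering = bool(np.dot(direction, self.face_normals[tri]) < 0)
            out.append(Crossing(float(ti), s, entering))
        return out

    def query(self, origin, direction, t_min: float = 0.0,
              t_max: float = np.inf) -> list[Crossing]:
        t, idx = self._bvh.intersect(origin, direction, t_min, t_max)
        return self._crossings_from_hits(
            t, idx, np.asarray(direction, dtype=float))

    def query_brute(self, origin, direction, t_min: float = 0.0,
                    t_max: float = np.inf) -> list[Crossing]:
        """Reference path: identical result, no acceleration."""
        t, idx = _ray.intersect_brute(origin, direction, self.triangles,
                                      t_min, t_max)
        return self._crossings_from_hits(
            t, idx, np.asarray(direction, dtype=float))

    def structures_containing(self, point) -> set[str]:
        """Names of structures whose closed surface contains *point*.

        The test ray deliberately points in an asymmetric direction, and
        coincident edge/vertex hits are collapsed, so points on lattice- or
        symmetry-aligned positions classify correctly.
        """
        crossings = _dedupe_coincident(
            self.query(np.asarray(point, dtype=float), _CONTAIN_DIR,
                       t_min=_ray.EPS))
        counts: dict[str, int] = {}
        for c in crossings:
            counts[c.structure] = counts.get(c.structure, 0) + 1
        return {name for name, n in counts.items() if n % 2 == 1}


def build_index(model: HeartModel) -> SpatialIndex:
    return SpatialIndex(model)


def intersect(index: SpatialIndex, line: ScanLine) -> list[Crossing]:
    """Sorted crossings of one scan line (may be empty)."""
    return index.query(line.origin, line.direction, 0.0, line.length)


# ---------------------------------------------------------------------------
# grey-value filling
# ---------------------------------------------------------------------------

_COINCIDENT_TOL = 1e-9


def _dedupe_coincident(crossings: Sequence[Crossing]) -> list[Crossing]:
    """Collapse multiple hits at one geometric crossing.

    A ray passing exactly through a shared mesh edge or vertex reports one
    hit per adjacent triangle.  Hits of the same structure at the same
    distance collapse to one (a tangential graze with balanced enter/exit
    flags cancels entirely).
    """
    out: list[Crossing] = []
    by_key: list[Crossing] = []
    for c in sorted(crossings, key=lambda c: c.distance_mm):
        if by_key and (c.structure == by_key[0].structure
                       and c.distance_mm - by_key[0].distance_mm
                       <= _COINCIDENT_TOL):
            by_key.append(c)
            continue
        out.extend(_collapse(by_key))
        by_key = [c]
    out.extend(_collapse(by_key))
    return out


def _collapse(group: list[Crossing]) -> list[Crossing]:
    if len(group) <= 1:
        return group
    n_enter = sum(c.entering for c in group)
    n_exit = len(group) - n_enter
    if n_enter == n_exit:
        return []  # tangential graze: surface touched but not crossed
    return [group[0] if n_enter > n_exit else
            next(c for c in group if not c.entering)]

def fill_scanline(
    crossings: Sequence[Crossing],
    line: ScanLine,
    index: SpatialIndex,
    materials: MaterialTable,
    check_parity: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill the segments between crossings with material grey values.

    Returns (intensity, structure_id) arrays over the line's samples.
    The material at a sample is that of the highest-priority structure
    containing it (crossing parity per structure; the state at the line
    origin comes from a point-in-mesh test, so a probe placed inside a
    structure is legal).  With a nonzero attenuation coefficient the
    intensity decays as exp(-sum of attenuation * path) along the line.

    Raises SimulationError on inconsistent parity (a non-watertight or
    inverted mesh upstream).
    """
    dists = line.sample_distances()
    n = len(dists)
    intensity = np.empty(n, dtype=float)
    labels = np.zeros(n, dtype=np.int16)

    crossings = _dedupe_coincident(crossings)
    inside = index.structures_containing(line.origin)
    if check_parity:
        # each closed structure must alternate enter/exit along the ray
        state: dict[str, bool] = {}
        for c in sorted(crossings, key=lambda c: c.distance_mm):
            was_inside = state.get(c.structure, c.structure in inside)
            if c.entering == was_inside:
                raise SimulationError(
                    f"inconsistent crossing parity for structure "
                    f"{c.structure!r} at {c.distance_mm:.3f} mm")
            state[c.structure] = c.entering

    events = sorted(crossings, key=lambda c: c.distance_mm)
    edges = [0.0] + [c.distance_mm for c in events] + [line.length]
    sample_seg = np.searchsorted(
        [c.distance_mm for c in events], dists, side="right")

    # walk segments, maintaining the inside set
    seg_material: list[Material] = []
    seg_label: list[int] = []
    current = set(inside)
    for k in range(len(events) + 1):
        if current:
            top = min(
                current,
                key=lambda s: (-index.priorities[s],
                               index.declaration_order[s]))
            mat = materials.get(index.materials_by_structure[top])
            lab = index.declaration_order[top] + 1
        else:
            mat = materials.background
            lab = 0
        seg_material.append(mat)
        seg_label.append(lab)
        if k < len(events):
            c = events[k]
            if c.entering:
                current.add(c.structure)
            else:
                current.discard(c.structure)

    greys = np.array([m.grey_value for m in seg_material], dtype=float)
    attens = np.array([m.attenuation_per_mm for m in seg_material])
    labels[:] = np.array(seg_label, dtype=np.int16)[sample_seg]
    intensity[:] = greys[sample_seg]

    if np.any(attens > 0):
        # cumulative attenuation integral over the segment path
        seg_len = np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(attens * seg_len)])
        att_at = cum[sample_seg] + attens[sample_seg] * (
            dists - np.asarray(edges)[sample_seg])
        intensity *= np.exp(-att_at)
    return intensity, labels


# ---------------------------------------------------------------------------
# scan conversion
# ---------------------------------------------------------------------------

def _interp2(lines: np.ndarray, u: np.ndarray, v: np.ndarray,
             valid: np.ndarray, mode: str, fill: float) -> np.ndarray:
    """Sample the (n_lines, n_samples) grid at fractional (u=line, v=sample)."""
    n_l, n_s = lines.shape
    out = np.full(u.shape, fill, dtype=float)
    inside = valid & (u > -0.5) & (u < n_l - 0.5) & (v > -0.5) & (v < n_s - 0.5)
    if mode == "nearest":
        ui = np.clip(np.round(u[inside]).astype(int), 0, n_l - 1)
        vi = np.clip(np.round(v[inside]).astype(int), 0, n_s - 1)
        out[inside] = lines[ui, vi]
    else:
        uc = np.clip(u[inside], 0, n_l - 1)
        vc = np.clip(v[inside], 0, n_s - 1)
        u0 = np.floor(uc).astype(int)
        v0 = np.floor(vc).astype(int)
        u1 = np.minimum(u0 + 1, n_l - 1)
        v1 = np.minimum(v0 + 1, n_s - 1)
        fu = uc - u0
        fv = vc - v0
        out[inside] = (
            lines[u0, v0] * (1 - fu) * (1 - fv)
            + lines[u1, v0] * fu * (1 - fv)
            + lines[u0, v1] * (1 - fu) * fv
            + lines[u1, v1] * fu * fv)
    return out


def _pixel_grid(probe: ProbeConfig) -> tuple[np.ndarray, np.ndarray]:
    ps = probe.pixel_spacing_mm
    rows = (np.arange(probe.image_height_px) + 0.5) * ps
    cols = (np.arange(probe.image_width_px) + 0.5
            - probe.image_width_px / 2.0) * ps
    y, x = np.meshgrid(rows, cols, indexing="ij")
    return x, y


def scan_convert(line_data: np.ndarray, probe: ProbeConfig,
                 interpolation: str | None = None,
                 fill: float = 0.0) -> np.ndarray:
    """Resample per-line samples onto the Cartesian pixel grid.

    *line_data* is (n_scanlines, samples_per_line).  Linear probes map
    columns to lines directly; curvilinear probes map pixels to (angle,
    radius) about the transducer arc centre and pixels outside the fan
    get *fill*.  Interpolation defaults to the probe's setting.
    """
    line_data = np.asarray(line_data, dtype=float)
    if line_data.shape != (probe.n_scanlines, probe.samples_per_line):
        raise ValueError(
            f"expected line data shape {(probe.n_scanlines, probe.samples_per_line)}, "
            f"got {line_data.shape}")
    mode = interpolation or probe.interpolation
    x, y = _pixel_grid(probe)
    ds = probe.sample_spacing_mm
    if probe.kind == "linear":
        f = probe.footprint_mm
        n = probe.n_scanlines
        if n == 1:
            u = np.where(np.abs(x) <= f / 2.0, 0.0, -1.0)
        else:
            u = (x + f / 2.0) / (f / (n - 1))
        v = y / ds - 0.5
        valid = (x >= -f / 2.0 - 1e-9) & (x <= f / 2.0 + 1e-9)
        return _interp2(line_data, u, v, valid, mode, fill)
    r = probe.transducer_radius_mm
    half = np.deg2rad(probe.fov_deg) / 2.0
    cy = y + r  # arc centre at (0, -r)
    radius = np.hypot(x, cy)
    theta = np.arctan2(x, cy)
    n = probe.n_scanlines
    if n == 1:
        u = np.zeros_like(theta)
    else:
        u = (theta + half) / (2 * half / (n - 1))
    v = (radius - r) / ds - 0.5
    valid = ((np.abs(theta) <= half + 1e-12) & (radius >= r - 1e-9)
             & (radius <= r + probe.scanline_depth_mm + 1e-9))
    return _interp2(line_data, u, v, valid, mode, fill)


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------

def default_materials() -> MaterialTable:
    """Display materials for the cast models: the resin cast is echogenic
    (bright), surroundings anechoic (black)."""
    mats = {
        "blood_cast": Material("blood_cast", 200),
        "chamber": Material("chamber", 190),
        "artery": Material("artery", 215),
        "vein": Material("vein", 170),
        "airway": Material("airway", 70),
    }
    return MaterialTable(mats, background=Material("background", 0))


def simulate(model: HeartModel, pose: Pose, probe: ProbeConfig,
             materials: MaterialTable | None = None,
             speckle_sd: float = 0.0, seed: int = 0
             ) -> tuple[BModeImage, LabelSlice]:
    """Simulate one B-mode frame and its ground-truth label slice.

    *pose* maps image coordinates to heart coordinates, so the model is
    brought into the image frame with the inverse pose; the pipeline is
    scan-line layout -> spatial index -> crossover search -> grey-value
    fill -> scan conversion.  Deterministic unless ``speckle_sd > 0``
    (then deterministic per seed).
    """
    if materials is None:
        materials = default_materials()
    materials.check_model(model)
    pose.validate()
    model_img = apply_pose(model, pose.inverse())
    index = build_index(model_img)
    lines = compute_scanlines(probe)
    n_s = probe.samples_per_line
    intensities = np.zeros((len(lines), n_s))
    labels = np.zeros((len(lines), n_s), dtype=np.int16)
    for i, line in enumerate(lines):
        crossings = intersect(index, line)
        inten, lab = fill_scanline(crossings, line, index, materials)
        intensities[i, : len(inten)] = inten
        labels[i, : len(lab)] = lab

    img = scan_convert(intensities, probe)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    lab_img = scan_convert(labels.astype(float), probe,
                           interpolation="nearest").astype(np.int16)
    bmode = BModeImage(img, probe.pixel_spacing_mm, pose, probe)
    label_map = {i + 1: n for i, n in enumerate(index.structure_names)}
    slice_ = LabelSlice(lab_img, label_map)
    if speckle_sd > 0:
        bmode = add_speckle(bmode, seed=seed, sd=speckle_sd)
    return bmode, slice_


def add_speckle(image: BModeImage, seed: int = 0, sd: float = 0.1) -> BModeImage:
    """Multiplicative Gaussian speckle, clipped to [0, 255]; sd=0 is identity."""
    if sd < 0:
        raise ValueError("speckle sd must be >= 0")
    if sd == 0:
        return image
    rng = np.random.default_rng(seed)
    noisy = image.pixels.astype(float) * rng.normal(1.0, sd, image.pixels.shape)
    return BModeImage(np.clip(np.rint(noisy), 0, 255).astype(np.uint8),
                      image.pixel_spacing_mm, image.pose, image.probe)
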