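"""Procedural fetal heart models and a cast-CT rasteriser.

Generates blood-pool ("cast") geometry for three study cases at
mid-gestation scale (ventricular long axis ~15-18 mm, consistent with
25-26 week specimens):

* ``normal`` — all standard structures, single left-sided aortic arch,
  ductus arteriosus bridging the pulmonary trunk to the descending aorta,
  SVC and IVC entering the right atrium.
* ``double_aortic_arch`` — the ascending aorta splits into left and right
  arch branches that both rejoin the descending aorta, forming a closed
  vascular ring around a trachea placeholder.
* ``hrh_vsd_mga_pa`` — hypoplastic right ventricle (RV volume a set
  fraction of LV volume), a ventricular septal defect channel between the
  ventricular cavities, the aorta arising anteriorly from the RV
  (malposition of the great arteries), and an atretic pulmonary trunk
  whose initial segment is absent (fed only via the ductus).

Chambers are tapered ellipsoids; vessels are swept tubes along smooth
spline paths.  Every structure is a closed, outward-oriented triangle
mesh, so the whole model feeds the parity-based ultrasound simulator
directly.  Structures are allowed to interpenetrate slightly where they
join; overlap is resolved downstream by per-structure priority
(smaller structures carry higher priority so junction overlap is charged
to the larger partner).

The rasteriser emulates a CT scan of the physical cast: a label volume
whose voxel value identifies the structure containing the voxel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import trimesh
from scipy import interpolate

from . import _ray
from .heart_model import HeartModel, ModelError, Structure, scale_structure

__all__ = [
    "SyntheticHeartSpec",
    "LabelVolume",
    "generate_heart",
    "rasterize",
    "add_acquisition_noise",
    "vessel_graph",
]

CASE_KINDS = ("normal", "double_aortic_arch", "hrh_vsd_mga_pa", "custom")

#: overlap precedence: smaller structures win, so shared junction volume is
#: charged to the larger partner and per-structure volumes stay faithful.
_PRIORITY = {
    "LV": 10, "RV": 12, "RA": 13, "LA": 14, "Trachea": 16,
    "DAO": 20, "AO": 22, "PA": 24, "LAA": 28, "RAA": 28,
    "Arch": 30, "SVC": 32, "IVC": 32, "lArch": 33, "rArch": 33,
    "DA": 36, "lPA": 37, "rPA": 37, "AoBs": 40, "VSD": 50,
}

_MATERIAL = {
    "LA": "chamber", "RA": "chamber", "LV": "chamber", "RV": "chamber",
    "LAA": "chamber", "RAA": "chamber", "VSD": "chamber",
    "AO": "artery", "Arch": "artery", "DAO": "artery", "AoBs": "artery",
    "lArch": "artery", "rArch": "artery",
    "PA": "artery", "lPA": "artery", "rPA": "artery", "DA": "artery",
    "SVC": "vein", "IVC": "vein", "Trachea": "airway",
}

#: nominal chamber shapes: centre, semi-axes (mm), taper strength, taper axis
_CHAMBERS = {
    "LV": ((7.0, 4.0, -7.0), (5.0, 5.5, 9.0), 0.18, -1),
    "RV": ((-5.0, -2.0, -7.0), (5.5, 5.0, 8.0), 0.18, -1),
    "LA": ((6.0, 7.0, 2.5), (4.5, 4.0, 4.0), 0.10, +1),
    "RA": ((-6.0, 5.0, 2.5), (5.0, 4.5, 3.8), 0.10, +1),
    "LAA": ((11.0, 4.0, 4.0), (2.6, 2.1, 2.1), 0.0, +1),
    "RAA": ((-11.0, 1.5, 4.0), (2.6, 2.1, 2.1), 0.0, +1),
}

_DEFAULT_CHAMBER_RADII = {
    name: float(np.mean(sem)) for name, (_, sem, _, _) in _CHAMBERS.items()
}

_DEFAULT_VESSEL_RADII = {
    "AO": 2.2, "Arch": 2.0, "DAO": 2.2, "AoBs": 1.2,
    "PA": 2.4, "lPA": 1.7, "rPA": 1.7, "DA": 1.9,
    "SVC": 1.8, "IVC": 1.8, "lArch": 1.6, "rArch": 1.6,
    "Trachea": 1.0,
}

#: end-cap penetration (mm) used where a vessel must be truly joined to its
#: neighbour (drives the vessel adjacency graph); small enough that the
#: double-counted junction volume stays ~1-3% of either partner.
_JOIN = 0.45
#: stand-off (mm) for visually abutting but unconnected junctions.
_GAP = 0.05


@dataclass
class SyntheticHeartSpec:
    """Parameters of one procedural heart.

    ``chamber_radii`` are mean semi-axes in mm (anisotropy is fixed per
    chamber); ``vessel_radii`` are tube radii in mm.  ``rv_lv_ratio`` is the
    target RV/LV volume ratio for the hypoplastic case; ``vsd_radius`` the
    septal-channel radius (0 = intact septum).  ``scale_factors`` applies
    optional per-structure post-hoc scaling (perfusion-pressure
    calibration hook).  Generation is deterministic for a fixed seed.
    """

    case_kind: str = "normal"
    chamber_radii: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHAMBER_RADII))
    vessel_radii: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_VESSEL_RADII))
    rv_lv_ratio: float = 1.0
    vsd_radius: float = 0.0
    pa_atretic: bool = False
    aorta_from_rv: bool = False
    seed: int = 0
    subdivisions: int = 3
    tube_segments: int = 18
    ring_spacing_mm: float = 1.2
    scale_factors: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def preset(case_kind: str, seed: int = 0) -> "SyntheticHeartSpec":
        if case_kind == "normal":
            return SyntheticHeartSpec(case_kind="normal", seed=seed)
        if case_kind == "double_aortic_arch":
            return SyntheticHeartSpec(case_kind="double_aortic_arch", seed=seed)
        if case_kind == "hrh_vsd_mga_pa":
            return SyntheticHeartSpec(
                case_kind="hrh_vsd_mga_pa", rv_lv_ratio=0.4, vsd_radius=1.5,
                pa_atretic=True, aorta_from_rv=True, seed=seed)
        raise ValueError(f"unknown case preset {case_kind!r}")

    def validate(self) -> None:
        if self.case_kind not in CASE_KINDS:
            raise ValueError(f"unknown case_kind {self.case_kind!r}")
        for name, r in {**self.chamber_radii, **self.vessel_radii}.items():
            if r <= 0:
                raise ValueError(f"radius for {name!r} must be > 0, got {r}")
        if self.rv_lv_ratio <= 0:
            raise ValueError("rv_lv_ratio must be > 0")
        if self.vsd_radius < 0:
            raise ValueError("vsd_radius must be >= 0")
        rv = self.chamber_radii.get("RV", _DEFAULT_CHAMBER_RADII["RV"])
        if self.vsd_radius >= rv:
            raise ModelError(
                f"vsd_radius {self.vsd_radius} mm does not fit inside the "
                f"RV (mean radius {rv} mm)")


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _ellipsoid(center, semi_axes, taper: float, taper_axis: int,
               subdivisions: int) -> trimesh.Trimesh:
    """Tapered ellipsoid: transverse radius shrinks toward one pole."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions)
    v = m.vertices.copy()
    if taper:
        # u in [-1, 1] along z of the unit sphere; shrink x, y toward the
        # pole selected by taper_axis (-1 = apex at -z).
        u = v[:, 2] * taper_axis
        shrink = 1.0 - taper * (1.0 - u) / 2.0
        v[:, 0] *= shrink
        v[:, 1] *= shrink
    v = v * np.asarray(semi_axes, dtype=float) + np.asarray(center, dtype=float)
    return trimesh.Trimesh(vertices=v, faces=m.faces.copy(), process=False)


def _resample_path(points: np.ndarray, spacing: float) -> np.ndarray:
    """Smooth interpolating spline through the waypoints, sampled at
    roughly *spacing* mm of arc length.  Endpoints are hit exactly."""
    points = np.asarray(points, dtype=float)
    if len(points) == 2:
        n = max(int(np.ceil(np.linalg.norm(points[1] - points[0]) / spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        return points[0] + t[:, None] * (points[1] - points[0])
    k = min(3, len(points) - 1)
    tck, _ = interpolate.splprep(points.T, s=0.0, k=k)
    dense = np.column_stack(interpolate.splev(np.linspace(0, 1, 200), tck))
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    n = max(int(np.ceil(arc[-1] / spacing)), 2)
    u = np.interp(np.linspace(0, arc[-1], n + 1), arc, np.linspace(0, 1, 200))
    return np.column_stack(interpolate.splev(u, tck))


def _frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parallel-transport orthonormal frames along a polyline."""
    d = np.diff(points, axis=0)
    seg_t = d / np.linalg.norm(d, axis=1, keepdims=True)
    tangents = np.empty_like(points)
    tangents[0] = seg_t[0]
    tangents[-1] = seg_t[-1]
    if len(points) > 2:
        mid = seg_t[:-1] + seg_t[1:]
        tangents[1:-1] = mid / np.linalg.norm(mid, axis=1, keepdims=True)

    normals = np.empty_like(points)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = ref - np.dot(ref, tangents[0]) * tangents[0]
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(points)):
        n = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def _tube(path_points, radius, n_seg: int = 18,
          ring_spacing: float = 1.2) -> trimesh.Trimesh:
    """Closed swept tube with flat end caps along a smooth path."""
    pts = _resample_path(np.asarray(path_points, dtype=float), ring_spacing)
    _, normals, binormals = _frames(pts)
    theta = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    circ = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (s, 2)
    rings = (pts[:, None, :]
             + radius * (circ[None, :, 0:1] * normals[:, None, :]
                         + circ[None, :, 1:2] * binormals[:, None, :]))
    nr = len(pts)
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(nr - 1):
        a = i * n_seg
        b = (i + 1) * n_seg
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    # end caps: fan around the path endpoints
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, pts[0], pts[-1]])
    for j in range(n_seg):
        jn = (j + 1) % n_seg
        faces.append([c0, j, jn])                    # start cap
        last = (nr - 1) * n_seg
        faces.append([c1, last + jn, last + j])      # end cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# junction helpers
# ---------------------------------------------------------------------------

def _exit_point(mesh: trimesh.Trimesh, anchor, direction) -> np.ndarray:
    """First surface crossing of a ray cast from an interior anchor."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tris = mesh.triangles
    t, _ = _ray.intersect_brute(np.asarray(anchor, dtype=float), d, tris,
                                t_min=1e-6)
    if len(t) == 0:
        raise ModelError("junction anchor ray misses the target structure")
    return np.asarray(anchor, dtype=float) + t[0] * d


def _offset_along(p_from, p_toward, dist: float) -> np.ndarray:
    u = np.asarray(p_toward, dtype=float) - np.asarray(p_from, dtype=float)
    u = u / np.linalg.norm(u)
    return np.asarray(p_from, dtype=float) + dist * u


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _scaled_semi_axes(spec: SyntheticHeartSpec, name: str) -> np.ndarray:
    _, sem, _, _ = _CHAMBERS[name]
    sem = np.asarray(sem, dtype=float)
    want = spec.chamber_radii.get(name, _DEFAULT_CHAMBER_RADII[name])
    return sem * (want / np.mean(sem))


def _vr(spec: SyntheticHeartSpec, name: str) -> float:
    return float(spec.vessel_radii.get(name, _DEFAULT_VESSEL_RADII[name]))


def generate_heart(spec: SyntheticHeartSpec) -> HeartModel:
    """Build the procedural heart for *spec* (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    meshes: dict[str, trimesh.Trimesh] = {}

    def tube(name: str, path, radius=None) -> None:
        r = _vr(spec, name) if radius is None else radius
        meshes[name] = _tube(path, r, spec.tube_segments, spec.ring_spacing_mm)

    # ---- chambers ---------------------------------------------------------
    for name in ("LV", "RV", "LA", "RA", "LAA", "RAA"):
        center, _, taper, ax = _CHAMBERS[name]
        sub = spec.subdivisions if name not in ("LAA", "RAA") else max(
            spec.subdivisions - 1, 2)
        meshes[name] = _ellipsoid(center, _scaled_semi_axes(spec, name),
                                 taper, ax, sub)

    hrh = spec.case_kind == "hrh_vsd_mga_pa"
    if hrh:
        # shrink the RV about a basal fixed point so it still reaches the
        # four-chamber plane; exact target volume ratio from mesh volumes
        v_rv = meshes["RV"].volume
        v_lv = meshes["LV"].volume
        s = (spec.rv_lv_ratio * v_lv / v_rv) ** (1.0 / 3.0)
        base = np.array([-5.0, -2.0, 0.5])
        m = meshes["RV"]
        meshes["RV"] = trimesh.Trimesh(
            vertices=(m.vertices - base) * s + base,
            faces=m.faces.copy(), process=False)

    # ---- great arteries ---------------------------------------------------
    aorta_from_rv = spec.aorta_from_rv or hrh
    if aorta_from_rv:
        # malposition: aorta arises anteriorly from the right ventricle
        rv_c = meshes["RV"].center_mass
        ao_start = _offset_along(
            _exit_point(meshes["RV"], rv_c, np.array([-3, -5, 2]) - rv_c),
            np.array([-3.0, -5.0, 2.0]), _GAP)
        ao_path = [ao_start, (-3, -5, 2), (-2, -4.5, 7), (-1, -1, 11)]
    else:
        lv_anchor = np.array([7.0, 4.0, -4.0])
        ao_start = _offset_along(
            _exit_point(meshes["LV"], lv_anchor,
                        np.array([3, -0.5, 2]) - lv_anchor),
            np.array([3.0, -0.5, 2.0]), _GAP)
        ao_path = [ao_start, (3, -0.5, 2), (2.8, 0, 7), (2.5, 1.2, 11)]

    double_arch = spec.case_kind == "double_aortic_arch"
    if double_arch:
        ao_path = ao_path[:-1] + [(2.5, 1.2, 11), (2.2, 2.2, 12.5)]
    tube("AO", ao_path)

    dao_top = np.array([2.0, 11.0, 10.5])
    if double_arch:
        # left and right arch branches: up-and-over "staple" loops that
        # leave the ascending aorta laterally and rejoin the descending
        # aorta posteriorly, encircling the trachea placeholder.
        ao_end = np.asarray(ao_path[-1], dtype=float)
        r_ao = _vr(spec, "AO")
        l_start = ao_end + np.array([r_ao - 0.35, 0.0, 0.0])
        r_start = ao_end + np.array([-(r_ao - 0.35), 0.0, 0.0])
        r_dao = _vr(spec, "DAO")
        l_end = np.array([2.0 + (r_dao - 0.35), 11.3, 9.3])
        r_end = np.array([2.0 - (r_dao - 0.35), 11.3, 9.3])
        l_arch_path = [l_start, (5.0, 3.8, 12.6), (6.5, 6, 12.5),
                       (6.5, 9.5, 12.4), (4.5, 11.3, 9.6), l_end]
        tube("lArch", l_arch_path)
        tube("rArch", [r_start, (-2.4, 3.8, 12.6), (-4.5, 6, 12.5),
                       (-4.5, 9.5, 12.4), (-2.5, 11.3, 9.6), r_end])
        dao_path = [(2.0, 11.2, 9.8), (2, 11.5, 2), (2, 12, -14)]
    else:
        ao_end = np.asarray(ao_path[-1], dtype=float)
        ao_dir = ao_end - np.asarray(ao_path[-2], dtype=float)
        ao_dir = ao_dir / np.linalg.norm(ao_dir)
        arch_start = ao_end - _JOIN * ao_dir
        arch_path = [arch_start, (2, 5, 13), (2, 9, 12), tuple(dao_top)]
        if aorta_from_rv:
            arch_path[1] = (0, 4, 13)
        tube("Arch", arch_path)
        arch_dir = dao_top - np.asarray(arch_path[-2], dtype=float)
        arch_dir = arch_dir / np.linalg.norm(arch_dir)
        dao_start = dao_top - _JOIN * arch_dir
        dao_path = [dao_start, (2, 11.5, 2), (2, 12, -14)]
    tube("DAO", dao_path)

    # brachiocephalic branches off the (left) arch; in the double-arch case
    # they spring from the left arch branch.
    carrier_r = _vr(spec, "Arch" if not double_arch else "lArch")
    branch_meshes = []
    base_pts = np.asarray(
        l_arch_path if double_arch else arch_path, dtype=float)
    dense = _resample_path(base_pts, 0.5)
    r_b = _vr(spec, "AoBs")
    for frac in (0.30, 0.48, 0.66):
        i = int(frac * (len(dense) - 1))
        q = dense[i]
        t = dense[min(i + 1, len(dense) - 1)] - dense[max(i - 1, 0)]
        t = t / np.linalg.norm(t)
        up = np.array([0.0, 0.0, 1.0])
        up = up - np.dot(up, t) * t
        up = up / np.linalg.norm(up)
        start = q + (carrier_r + _GAP) * up
        end = start + 6.0 * (up + np.array([0.0, -0.05, 0.0]))
        branch_meshes.append(_tube([start, end], r_b,
                                   spec.tube_segments, spec.ring_spacing_mm))
    meshes["AoBs"] = trimesh.util.concatenate(branch_meshes)

    # ---- pulmonary side ---------------------------------------------------
    pa_junction = np.array([-1.5, 2.5, 7.8])
    if spec.pa_atretic or hrh:
        # atresia: the initial trunk segment is absent; the trunk begins
        # blind above the ventricle and is supplied only through the ductus
        pa_path = [(-2.2, 0.5, 6.0), tuple(pa_junction)]
    else:
        rv_anchor = np.array([-5.0, -2.0, -4.0])
        pa_start = _offset_along(
            _exit_point(meshes["RV"], rv_anchor,
                        np.array([-3, -1.5, 2]) - rv_anchor),
            np.array([-3.0, -1.5, 2.0]), _GAP)
        pa_path = [pa_start, (-3, -1.5, 2), (-2.2, 0.5, 6), tuple(pa_junction)]
    tube("PA", pa_path)
    trunk_t = pa_junction - np.asarray(pa_path[-2], dtype=float)
    trunk_t = trunk_t / np.linalg.norm(trunk_t)
    r_pa = _vr(spec, "PA")

    def branch_base(toward, clearance) -> np.ndarray:
        u = np.asarray(toward, dtype=float) - pa_junction
        u = u / np.linalg.norm(u)
        perp = u - np.dot(u, trunk_t) * trunk_t
        perp = perp / np.linalg.norm(perp)
        return pa_junction + clearance * perp

    # the lPA threads the corridor between the ascending aorta (anterior)
    # and the ductal arch (posterior), above the left atrial roof; its base
    # stands slightly off the trunk to keep clear of the ductus origin
    tube("lPA", [branch_base((3, 4.3, 7.3), r_pa + 0.9),
                 (3, 4.3, 7.3), (7, 5.3, 7.0)])
    tube("rPA", [branch_base((-5, 6.7, 8.6), r_pa + _GAP),
                 (-5, 6.7, 8.6), (-9, 7.7, 8.6)])

    # ductus arteriosus: continues the trunk, joins the descending aorta
    da_start = pa_junction - _JOIN * trunk_t
    dao_pts = _resample_path(np.asarray(dao_path, dtype=float), 0.5)
    i_join = int(np.argmin(np.abs(dao_pts[:, 2] - 8.2)))
    dao_axis_pt = dao_pts[i_join]
    r_dao = _vr(spec, "DAO")
    da_end = dao_axis_pt + np.array([0.0, -(r_dao - 0.35), 0.0])
    tube("DA", [da_start, (0.3, 6.0, 8.0), da_end])

    # ---- systemic veins and trachea --------------------------------------
    ra_c = meshes["RA"].center_mass
    svc_top = np.array([-7.0, 2.8, 16.0])
    svc_end = _offset_along(
        _exit_point(meshes["RA"], ra_c, np.array([-7, 2.8, 10]) - ra_c),
        svc_top, _GAP)
    tube("SVC", [svc_top, svc_end])
    ivc_end = _offset_along(
        _exit_point(meshes["RA"], ra_c, np.array([-6, 6, -10]) - ra_c),
        np.array([-6.0, 6.0, -14.0]), _GAP)
    tube("IVC", [(-6.0, 6.0, -14.0), ivc_end])
    tube("Trachea", [(-2.0, 8.5, 5.0), (-2.0, 8.5, 20.0)])

    # ---- ventricular septal defect ---------------------------------------
    if spec.vsd_radius > 0:
        lv_c = meshes["LV"].center_mass
        rv_c = meshes["RV"].center_mass
        lv_exit = _exit_point(meshes["LV"], lv_c, rv_c - lv_c)
        rv_exit = _exit_point(meshes["RV"], rv_c, lv_c - rv_c)
        p_lv = _offset_along(lv_exit, lv_c, 1.5)   # 1.5 mm inside the LV
        p_rv = _offset_along(rv_exit, rv_c, 1.5)   # 1.5 mm inside the RV
        tube("VSD", [p_lv, p_rv], radius=spec.vsd_radius)

    # ---- assemble ---------------------------------------------------------
    structures = []
    for name, mesh in meshes.items():
        # sub-micrometre seeded jitter: breaks exact lattice/pole
        # degeneracies in the parity tests without touching geometry
        v = mesh.vertices + rng.normal(0.0, 0.004, mesh.vertices.shape)
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(),
                               process=False)
        structures.append(Structure(
            name=name, mesh=mesh,
            material_id=_MATERIAL.get(name, "chamber"),
            priority=_PRIORITY.get(name, 25)))
    model = HeartModel(structures)
    for name, f in spec.scale_factors.items():
        model = scale_structure(model, name, f)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Integer label grid emulating the segmented cast-CT scan.

    ``array`` is indexed (x, y, z); ``origin`` is the world position of the
    centre of voxel (0, 0, 0); 0 = background.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        present = set(np.unique(self.array)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels missing from label_map: {sorted(missing)}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_per_label(self) -> dict[str, float]:
        """Voxel-count volume (mm^3) per named label."""
        labels, counts = np.unique(self.array, return_counts=True)
        return {
            self.label_map[int(l)]: float(c) * self.voxel_volume
            for l, c in zip(labels, counts) if l != 0
        }

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.array.shape[i])
            for i in range(3)
        )  # type: ignore[return-value]


def rasterize(model: HeartModel, spacing: Sequence[float] = (0.4, 0.4, 0.6),
              margin: float = 2.0) -> LabelVolume:
    """Voxelise a heart model into a label volume (emulated cast CT).

    Each voxel is labelled by the structure containing its centre; where
    structures overlap the higher-priority structure wins (ties by
    declaration order).  The grid covers the model bounds plus *margin* mm.
    The default spacing mirrors a clinical cast protocol (0.4 mm in-plane
    pitch, 0.6 mm slice thickness).
    """
    if not model.structures:
        raise ModelError("cannot rasterize an empty model")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    lo, hi = model.bounds()
    # offset the grid by an irrational voxel fraction so lattice-aligned
    # geometry (e.g. analytic spheres) is sampled without systematic bias
    lo = lo - margin - 0.381966 * np.asarray(spacing)
    hi = hi + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) + 1
                  for i in range(3))
    coords = [lo[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    labels = np.zeros(shape, dtype=np.int16)
    name_to_label = {s.name: i + 1 for i, s in enumerate(model.structures)}
    # paint in ascending priority so the highest priority wins
    for s in model.render_order():
        blo, bhi = s.mesh.bounds
        sl = []
        axcoords = []
        for ax in range(3):
            i0 = int(np.searchsorted(coords[ax], blo[ax] - spacing[ax]))
            i1 = int(np.searchsorted(coords[ax], bhi[ax] + spacing[ax]))
            sl.append(slice(i0, i1))
            axcoords.append(coords[ax][i0:i1])
        if any(len(c) == 0 for c in axcoords):
            continue
        occ = _ray.mesh_occupancy(s.mesh.triangles, *axcoords)
        sub = labels[tuple(sl)]
        sub[occ] = name_to_label[s.name]
    return LabelVolume(
        array=labels, spacing=spacing, origin=tuple(lo),
        label_map={v: k for k, v in name_to_label.items()})


def add_acquisition_noise(
    vol: LabelVolume,
    intensity_map: Mapping[str | int, float] | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
    air_intensity: float = 40.0,
    cast_intensity: float = 200.0,
) -> np.ndarray:
    """Turn a label volume into a grey-valued pseudo-CT with Gaussian noise.

    *intensity_map* may key either structure names or label integers;
    unmapped labels default to *cast_intensity* and the background (label
    0) to *air_intensity*.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    name_to_label = {v: k for k, v in vol.label_map.items()}
    lut = np.full(int(vol.array.max()) + 1, cast_intensity, dtype=np.float64)
    lut[0] = air_intensity
    if intensity_map:
        for key, val in intensity_map.items():
            label = name_to_label[key] if isinstance(key, str) else int(key)
            lut[label] = float(val)
    grey = lut[vol.array]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grey = grey + rng.normal(0.0, noise_sd, grey.shape)
    return grey.astype(np.float32)


# ---------------------------------------------------------------------------
# vessel adjacency
# ---------------------------------------------------------------------------

VESSEL_NAMES = ("AO", "Arch", "DAO", "AoBs", "lArch", "rArch",
                "PA", "lPA", "rPA", "DA", "SVC", "IVC")


def vessel_graph(model: HeartModel,
                 names: Sequence[str] | None = None) -> nx.Graph:
    """Adjacency graph of the vessels: an edge joins two vessels whose
    meshes interpenetrate (any vertex of one strictly inside the other).

    For the double-aortic-arch case the graph contains two distinct
    AO->DAO paths (left and right arch branches): a vascular-ring cycle.
    """
    if names is None:
        names = [n for n in VESSEL_NAMES if n in model.names]
    g = nx.Graph()
    g.add_nodes_from(names)
    structs = {n: model.get(n) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ma, mb = structs[a].mesh, structs[b].mesh
            if np.any(ma.bounds[1] < mb.bounds[0]) or \
               np.any(mb.bounds[1] < ma.bounds[0]):
                continue
            if np.any(_ray.points_in_mesh(ma.vertices, mb.triangles)) or \
               np.any(_ray.points_in_mesh(mb.vertices, ma.triangles)):
                g.add_edge(a, b)
    return g
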