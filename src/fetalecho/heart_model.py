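"""Domain types for multi-structure digital heart models.

A digital heart is a collection of named, closed (watertight) triangle
surfaces — one per cardiovascular structure — expressed in a shared
anatomical frame, each tagged with a display material and an overlap
priority.  Probe poses are rigid 4x4 homogeneous transforms mapping
probe/image coordinates into heart coordinates.

Conventions
-----------
* All lengths are millimetres.
* Canonical anatomical frame: x = fetal left, y = fetal posterior,
  z = fetal cephalad; origin at the centre of the four-chamber crux.
* Meshes are outward-oriented (signed volume > 0).
* Where structures overlap, the higher ``priority`` wins; ties are
  broken by declaration order within the model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh
import yaml

__all__ = [
    "Material",
    "MaterialTable",
    "Structure",
    "HeartModel",
    "Pose",
    "compose",
    "apply_pose",
    "scale_structure",
    "load_model",
    "pose_from_plane",
]

#: Anatomical vocabulary of the cast-segmentation workflow. User-defined
#: names are also allowed; this set is informational.
STANDARD_STRUCTURES = frozenset(
    {
        "LA", "LAA", "RA", "RAA", "LV", "RV",
        "AO", "Arch", "DAO", "AoBs",
        "PA", "lPA", "rPA", "DA",
        "SVC", "IVC",
    }
)


class ModelError(ValueError):
    """Raised when a mesh or model violates a structural invariant."""


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Display/acoustic parameters of one material.

    grey_value is the flat B-mode fill intensity (0-255); an optional
    exponential depth attenuation coefficient (per mm of in-material
    path) darkens deep samples.
    """

    material_id: str
    grey_value: int
    attenuation_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= int(self.grey_value) <= 255):
            raise ValueError(f"grey_value must be in [0, 255], got {self.grey_value}")
        if self.attenuation_per_mm < 0:
            raise ValueError("attenuation_per_mm must be >= 0")


@dataclass
class MaterialTable:
    """Mapping material_id -> Material, plus the background material."""

    materials: dict[str, Material]
    background: Material = field(
        default_factory=lambda: Material("background", 0)
    )

    def get(self, material_id: str) -> Material:
        try:
            return self.materials[material_id]
        except KeyError:
            raise KeyError(f"unknown material_id {material_id!r}") from None

    def check_model(self, model: "HeartModel") -> None:
        """Verify that every material referenced by *model* resolves."""
        for s in model.structures:
            self.get(s.material_id)


# ---------------------------------------------------------------------------
# Structures and models
# ---------------------------------------------------------------------------

def _check_mesh(mesh: trimesh.Trimesh, name: str) -> None:
    if not mesh.is_watertight:
        raise ModelError(f"structure {name!r}: mesh is not watertight")
    if not mesh.is_winding_consistent:
        raise ModelError(f"structure {name!r}: inconsistent triangle winding")
    if mesh.volume <= 0:
        raise ModelError(
            f"structure {name!r}: signed volume {mesh.volume:.3g} <= 0 "
            "(mesh not outward-oriented)"
        )


@dataclass
class Structure:
    """One named cardiovascular structure: a closed triangle surface."""

    name: str
    mesh: trimesh.Trimesh
    material_id: str = "blood_cast"
    priority: int = 0

    def validate(self) -> None:
        _check_mesh(self.mesh, self.name)

    @property
    def volume(self) -> float:
        """Enclosed volume in mm^3."""
        return float(self.mesh.volume)

    def copy(self) -> "Structure":
        return Structure(self.name, self.mesh.copy(), self.material_id, self.priority)


@dataclass
class HeartModel:
    """Ordered collection of structures sharing one anatomical frame."""

    structures: list[Structure]
    frame_note: str = (
        "x = fetal left, y = fetal posterior, z = fetal cephalad; "
        "origin at the four-chamber crux; units mm"
    )

    def __post_init__(self) -> None:
        if not self.structures:
            raise ModelError("HeartModel needs at least one structure")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ModelError(f"duplicate structure names: {sorted(dupes)}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def get(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}")

    def validate(self) -> None:
        for s in self.structures:
            s.validate()

    def copy(self) -> "HeartModel":
        return HeartModel([s.copy() for s in self.structures], self.frame_note)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of min/max corners over all structures."""
        lo = np.min([s.mesh.bounds[0] for s in self.structures], axis=0)
        hi = np.max([s.mesh.bounds[1] for s in self.structures], axis=0)
        return np.array([lo, hi])

    def render_order(self) -> list[Structure]:
        """Structures sorted so that higher priority comes last (painter's
        order for overlap resolution); ties keep declaration order."""
        return sorted(self.structures, key=lambda s: s.priority)


# ---------------------------------------------------------------------------
# Poses
# ---------------------------------------------------------------------------

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class Pose:
    """Rigid 4x4 homogeneous transform (probe/image -> heart coordinates)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"pose matrix must be 4x4, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(4))

    @staticmethod
    def from_rt(rotation: np.ndarray, translation: Sequence[float]) -> "Pose":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return Pose(m)

    @staticmethod
    def translation(offset: Sequence[float]) -> "Pose":
        return Pose.from_rt(np.eye(3), offset)

    @staticmethod
    def rotation(axis: Sequence[float], angle_deg: float,
                 center: Sequence[float] = (0.0, 0.0, 0.0)) -> "Pose":
        """Rotation by angle_deg about *axis* through *center*."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        th = np.deg2rad(angle_deg)
        k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        r = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        c = np.asarray(center, dtype=float)
        return Pose.from_rt(r, c - r @ c)

    def validate(self, tol: float = _ORTHO_TOL) -> None:
        m = self.matrix
        if not np.allclose(m[3], [0, 0, 0, 1], atol=tol):
            raise ValueError("pose bottom row must be (0, 0, 0, 1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=tol):
            raise ValueError("pose rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("pose rotation block has determinant -1 (reflection)")

    @property
    def rotation_block(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation_vec(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "Pose":
        """Analytic rigid inverse (R^T, -R^T t)."""
        r = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        return Pose.from_rt(r.T, -r.T @ t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def compose(a: Pose, b: Pose) -> Pose:
    """Pose composition a∘b (apply b first, then a)."""
    a.validate()
    b.validate()
    return Pose(a.matrix @ b.matrix)


def pose_from_plane(target: Sequence[float], depth_dir: Sequence[float],
                    plane_normal: Sequence[float], standoff: float) -> Pose:
    """Build a probe pose whose image plane contains *target*.

    The image plane is spanned by the lateral axis (image x) and the depth
    axis (image y = *depth_dir*), with image z along *plane_normal*.  The
    probe contact point is placed *standoff* mm before the target along the
    depth direction, so the target sits at depth ``standoff`` in the image.
    """
    d = np.asarray(depth_dir, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = d - np.dot(d, n) * n  # force depth axis into the plane
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("depth_dir is parallel to plane_normal")
    d = d / nd
    lateral = np.cross(d, n)  # unit; (l, d, n) right-handed
    m = np.eye(4)
    m[:3, 0] = lateral
    m[:3, 1] = d
    m[:3, 2] = n
    m[:3, 3] = np.asarray(target, dtype=float) - standoff * d
    return Pose(m)


# ---------------------------------------------------------------------------
# Model-level operations
# ---------------------------------------------------------------------------

def apply_pose(model: HeartModel, pose: Pose) -> HeartModel:
    """Rigidly transform every structure by *pose* (topology unchanged)."""
    pose.validate()
    out = []
    for s in model.structures:
        mesh = trimesh.Trimesh(
            vertices=pose.apply(s.mesh.vertices),
            faces=s.mesh.faces.copy(),
            process=False,
        )
        out.append(Structure(s.name, mesh, s.material_id, s.priority))
    return HeartModel(out, model.frame_note)


def scale_structure(model: HeartModel, name: str, factor: float,
                    center: Sequence[float] | None = None) -> HeartModel:
    """Scale one named structure about *center* (default: its centroid).

    Used to calibrate per-structure proportions, e.g. to undo the casting
    distortion where chambers near the perfusion inlet are over-inflated.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    target = model.get(name)  # raises KeyError for unknown names
    if center is None:
        center = target.mesh.center_mass
    c = np.asarray(center, dtype=float)
    out = []
    for s in model.structures:
        if s.name == name:
            mesh = trimesh.Trimesh(
                vertices=(s.mesh.vertices - c) * factor + c,
                faces=s.mesh.faces.copy(),
                process=False,
            )
            out.append(Structure(s.name, mesh, s.material_id, s.priority))
        else:
            out.append(s.copy())
    return HeartModel(out, model.frame_note)


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

_MESH_SUFFIXES = {".stl", ".ply", ".obj"}


def _load_mesh_file(path: Path) -> trimesh.Trimesh:
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ModelError(f"unsupported mesh format: {path.name}")
    mesh = trimesh.load_mesh(str(path))
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        mesh = trimesh.util.concatenate(geoms) if len(geoms) > 1 else geoms[0]
    return mesh


def load_model(
    paths: Iterable[str | Path] | None,
    manifest: str | Path | Mapping[str, Mapping],
    repair: bool = False,
    max_repair_boundary_edges: int = 100,
) -> HeartModel:
    """Load a multi-structure model from mesh files plus a manifest.

    Parameters
    ----------
    paths
        Mesh files (STL/PLY/OBJ).  May be ``None`` if every manifest entry
        carries an absolute/relative ``file`` path of its own.
    manifest
        Mapping ``structure name -> {file, material_id, priority}`` or a
        path to a YAML file containing it.  ``file`` entries are matched
        against *paths* by file name.
    repair
        If True, attempt hole filling on non-watertight meshes with at most
        *max_repair_boundary_edges* boundary edges; otherwise such meshes
        are rejected.
    """
    base_dir = Path(".")
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        base_dir = manifest_path.parent
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, Mapping) or not manifest:
        raise ModelError("manifest must be a non-empty mapping")

    by_name: dict[str, Path] = {}
    for p in paths or []:
        p = Path(p)
        by_name[p.name] = p

    structures = []
    for name, entry in manifest.items():
        entry = dict(entry or {})
        fname = entry.get("file", f"{name}.stl")
        path = by_name.get(Path(fname).name)
        if path is None:
            path = Path(fname)
            if not path.is_absolute():
                path = base_dir / path
        if not path.exists():
            raise ModelError(f"mesh file not found for structure {name!r}: {fname}")
        mesh = _load_mesh_file(path)
        if not mesh.is_watertight:
            n_boundary = len(
                trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
            )
            if repair and n_boundary <= max_repair_boundary_edges:
                trimesh.repair.fill_holes(mesh)
            if not mesh.is_watertight:
                raise ModelError(
                    f"structure {name!r}: mesh has {n_boundary} boundary edges "
                    "and is not watertight"
                )
        if mesh.volume < 0:
            mesh.invert()
        structures.append(
            Structure(
                name=name,
                mesh=mesh,
                material_id=entry.get("material_id", "blood_cast"),
                priority=int(entry.get("priority", 0)),
            )
        )
    model = HeartModel(structures)
    model.validate()
    return model


def save_model(model: HeartModel, out_dir: str | Path,
               fmt: str = "stl") -> Path:
    """Write one mesh file per structure plus ``manifest.yaml``.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for s in model.structures:
        fname = f"{s.name}.{fmt}"
        s.mesh.export(out / fname)
        manifest[s.name] = {
            "file": fname,
            "material_id": s.material_id,
            "priority": s.priority,
        }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
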