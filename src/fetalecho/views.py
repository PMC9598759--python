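"""Standard fetal echocardiography view presets and verification.

The eight standard views (four-chamber, LV outflow tract, RV outflow
tract, three-vessel, three vessels and trachea, aortic arch, ductal,
bicaval) are shipped as probe poses in the canonical heart frame, each
with the set of structures the view must display.  Verification runs on
the ground-truth LabelSlice (never the grey image): a view passes when
every required structure covers at least ``min_pixels`` pixels and every
forbidden one stays below.

Lesion-sensitive presets for the two pathology cases check the imaging
signatures of the malformations: two separate arch cross-sections and
the arches rejoining the descending aorta (double aortic arch); RV
smaller than LV in the four-chamber plane, a ventricular septal channel
bridging the ventricles, and a pulmonary trunk with no connection to the
ventricle (hypoplastic right heart complex).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .heart_model import HeartModel, MaterialTable, Pose
from .ultrasound_sim import LabelSlice, ProbeConfig, simulate

__all__ = [
    "ViewSpec",
    "standard_views",
    "lesion_views",
    "verify_view",
    "find_view",
    "count_structure_regions",
    "structures_connected",
    "structures_adjacent",
]

STANDARD_VIEW_NAMES = (
    "four_chamber", "lvot", "rvot", "three_vessel", "three_vessel_trachea",
    "aortic_arch", "ductal", "bicaval",
)

#: default area threshold (pixels) at the default 0.2 mm pixel spacing
DEFAULT_MIN_PIXELS = 30
#: pixel spacing (mm) at which DEFAULT_MIN_PIXELS is defined
REFERENCE_PIXEL_SPACING_MM = 0.2


def scaled_min_pixels(pixel_spacing_mm: float,
                      min_pixels: int = DEFAULT_MIN_PIXELS) -> int:
    """The area threshold expressed in pixels of another spacing (the
    criterion is an area in mm^2, so the pixel count scales inversely with
    the squared spacing)."""
    scale = (REFERENCE_PIXEL_SPACING_MM / pixel_spacing_mm) ** 2
    return max(1, int(round(min_pixels * scale)))


@dataclass(frozen=True)
class ViewSpec:
    """A named probe pose plus the structures it must (not) display."""

    name: str
    pose: Pose
    required_structures: frozenset[str]
    forbidden_structures: frozenset[str] = frozenset()
    check: str | None = None  # extra lesion-specific check identifier

    def __post_init__(self) -> None:
        if not self.required_structures:
            raise ValueError(f"view {self.name!r} requires at least one structure")


def _load_library() -> dict:
    ref = importlib.resources.files("fetalecho") / "data" / "standard_views.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def _spec_from_entry(name: str, entry: dict) -> ViewSpec:
    pose = Pose(np.asarray(entry["pose"], dtype=float).reshape(4, 4))
    return ViewSpec(
        name=name,
        pose=pose,
        required_structures=frozenset(entry["required"]),
        forbidden_structures=frozenset(entry.get("forbidden", [])),
        check=entry.get("check"),
    )


def standard_views() -> dict[str, ViewSpec]:
    """The eight standard view presets, keyed by name."""
    lib = _load_library()
    views = {name: _spec_from_entry(name, entry)
             for name, entry in lib["views"].items()}
    assert tuple(views) == STANDARD_VIEW_NAMES
    return views


def lesion_views(case_kind: str) -> list[ViewSpec]:
    """Lesion-sensitive presets for a pathology case (empty for normal)."""
    lib = _load_library()
    if case_kind == "normal":
        return []
    entries = lib["lesion_views"].get(case_kind)
    if entries is None:
        raise KeyError(f"no lesion views for case {case_kind!r}")
    return [_spec_from_entry(name, entry) for name, entry in entries.items()]


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def verify_view(slice_: LabelSlice, spec: ViewSpec,
                min_pixels: int = DEFAULT_MIN_PIXELS) -> dict:
    """Check a label slice against a view spec.

    Returns ``{"view", "pass", "counts", "missing", "forbidden_present"}``
    where counts covers every structure present in the slice plus the
    required set.
    """
    present = {spec_name: slice_.count(spec_name)
               for spec_name in slice_.label_map.values()}
    counts = {name: present.get(name, 0)
              for name in set(present) | set(spec.required_structures)}
    known = set(slice_.label_map.values())
    unknown = (spec.required_structures | spec.forbidden_structures) - known
    missing = sorted(n for n in spec.required_structures
                     if counts.get(n, 0) < min_pixels)
    forbidden = sorted(n for n in spec.forbidden_structures
                       if counts.get(n, 0) >= min_pixels)
    return {
        "view": spec.name,
        "pass": not missing and not forbidden and not
                (spec.required_structures & unknown),
        "counts": counts,
        "missing": missing,
        "forbidden_present": forbidden,
        "unknown_structures": sorted(unknown),
    }


def _mask_for(slice_: LabelSlice, names) -> np.ndarray:
    ids = [l for l, n in slice_.label_map.items() if n in set(names)]
    return np.isin(slice_.pixels, ids)


def count_structure_regions(slice_: LabelSlice, names) -> int:
    """Number of 4-connected pixel regions carrying any of *names*."""
    mask = _mask_for(slice_, names)
    _, n = ndimage.label(mask)
    return int(n)


def structures_connected(slice_: LabelSlice, a: str, b: str,
                         via=()) -> bool:
    """True if pixels of *a* and *b* fall in one 4-connected region of the
    union mask a|b|via (e.g. ventricles bridged by a septal channel)."""
    union = _mask_for(slice_, {a, b, *via})
    lab, _ = ndimage.label(union)
    la = set(np.unique(lab[_mask_for(slice_, {a})])) - {0}
    lb = set(np.unique(lab[_mask_for(slice_, {b})])) - {0}
    return bool(la & lb)


def structures_adjacent(slice_: LabelSlice, a: str, b: str) -> bool:
    """True if any pixel of *a* touches a pixel of *b* (8-neighbourhood)."""
    ma = _mask_for(slice_, {a})
    mb = _mask_for(slice_, {b})
    if not ma.any() or not mb.any():
        return False
    grown = ndimage.binary_dilation(ma, structure=np.ones((3, 3), dtype=bool))
    return bool((grown & mb).any())


# ---------------------------------------------------------------------------
# automated view search
# ---------------------------------------------------------------------------

def _score(slice_: LabelSlice, spec: ViewSpec, min_pixels: int) -> tuple:
    rep = verify_view(slice_, spec, min_pixels)
    n_ok = len(spec.required_structures) - len(rep["missing"])
    n_bad = len(rep["forbidden_present"])
    worst = min((rep["counts"].get(n, 0)
                 for n in spec.required_structures), default=0)
    return (n_ok - n_bad, worst)


def find_view(model: HeartModel, spec: ViewSpec,
              probe: ProbeConfig | None = None,
              materials: MaterialTable | None = None,
              search_budget: int = 50, seed: int = 0,
              min_pixels: int = DEFAULT_MIN_PIXELS,
              translation_sd_mm: float = 1.0,
              rotation_sd_deg: float = 2.0) -> tuple[Pose, dict]:
    """Local stochastic search for a passing probe pose.

    Starting from ``spec.pose``, seeded random rigid perturbations are
    accepted when they improve the verification score; the search stops
    early once the view passes.  Returns (best pose, its report);
    deterministic for a fixed seed, and may return a non-passing best if
    the budget runs out.
    """
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    if probe is None:
        probe = ProbeConfig()
    rng = np.random.default_rng(seed)
    best_pose = spec.pose
    _, slice_ = simulate(model, best_pose, probe, materials)
    best_report = verify_view(slice_, spec, min_pixels)
    best_score = _score(slice_, spec, min_pixels)
    for _ in range(search_budget - 1):
        if best_report["pass"]:
            break
        axis = rng.normal(size=3)
        angle = rng.normal(0.0, rotation_sd_deg)
        shift = rng.normal(0.0, translation_sd_mm, size=3)
        center = best_pose.apply(np.array(
            [[0.0, probe.scanline_depth_mm / 2.0, 0.0]]))[0]
        cand = Pose(
            Pose.rotation(axis, angle, center).matrix
            @ Pose.translation(shift).matrix
            @ best_pose.matrix)
        _, slice_ = simulate(model, cand, probe, materials)
        s = _score(slice_, spec, min_pixels)
        if s > best_score:
            best_score = s
            best_pose = cand
            best_report = verify_view(slice_, spec, min_pixels)
    return best_pose, best_report
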