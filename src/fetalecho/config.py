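"""Simulation configuration files (XML or YAML) and pose files.

The XML layout mirrors the classic ultrasound-simulator convention of a
single configuration file declaring the probe, output image and material
parameters::

    <SimulationConfig>
      <Probe kind="curvilinear" n_scanlines="160" depth_mm="55"
             samples_per_line="256" fov_deg="60" transducer_radius_mm="28"/>
      <Image width_px="300" height_px="300" pixel_spacing_mm="0.2"
             interpolation="bilinear"/>
      <Materials background_grey="0">
        <Material id="chamber" grey="190" attenuation_per_mm="0"/>
        ...
      </Materials>
    </SimulationConfig>

The YAML equivalent nests the same fields under ``probe``, ``image`` and
``materials`` keys.  Pose files are 4x4 row-major matrices, either JSON
(``{"matrix": [[...], ...]}``) or whitespace-separated plain text.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import yaml

from .heart_model import Material, MaterialTable, Pose
from .ultrasound_sim import ProbeConfig, default_materials

__all__ = [
    "load_config",
    "save_config_yaml",
    "load_pose",
    "save_pose",
    "default_materials",
]


def _probe_from_fields(probe: dict, image: dict) -> ProbeConfig:
    kind = str(probe.get("kind", "curvilinear"))
    kwargs = dict(
        kind=kind,
        n_scanlines=int(probe.get("n_scanlines", 160)),
        scanline_depth_mm=float(probe.get("depth_mm", 55.0)),
        samples_per_line=int(probe.get("samples_per_line", 256)),
        image_width_px=int(image.get("width_px", 300)),
        image_height_px=int(image.get("height_px", 300)),
        pixel_spacing_mm=float(image.get("pixel_spacing_mm", 0.2)),
        interpolation=str(image.get("interpolation", "bilinear")),
    )
    if kind == "curvilinear":
        kwargs["fov_deg"] = float(probe.get("fov_deg", 60.0))
        kwargs["transducer_radius_mm"] = float(
            probe.get("transducer_radius_mm", 28.0))
        kwargs["footprint_mm"] = None
    else:
        kwargs["fov_deg"] = None
        kwargs["transducer_radius_mm"] = None
        kwargs["footprint_mm"] = float(probe.get("footprint_mm", 40.0))
    return ProbeConfig(**kwargs)


def _materials_from_entries(entries, background_grey: int) -> MaterialTable:
    mats = {}
    for e in entries:
        mid = str(e["id"])
        mats[mid] = Material(
            mid, int(e.get("grey", 128)),
            float(e.get("attenuation_per_mm", 0.0)))
    table = default_materials()
    if mats:
        table = MaterialTable(
            mats, background=Material("background", int(background_grey)))
    return table


def load_config(path: str | Path) -> tuple[ProbeConfig, MaterialTable]:
    """Load probe + material configuration from .xml or .yaml/.yml."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    if path.suffix.lower() == ".xml":
        root = ET.parse(path).getroot()
        probe_el = root.find("Probe")
        image_el = root.find("Image")
        probe = dict(probe_el.attrib) if probe_el is not None else {}
        image = dict(image_el.attrib) if image_el is not None else {}
        mats_el = root.find("Materials")
        entries = []
        background = 0
        if mats_el is not None:
            background = int(mats_el.get("background_grey", 0))
            for m in mats_el.findall("Material"):
                entries.append(dict(m.attrib))
        return (_probe_from_fields(probe, image),
                _materials_from_entries(entries, background))
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    probe = data.get("probe", {}) or {}
    image = data.get("image", {}) or {}
    mats = data.get("materials", {}) or {}
    entries = mats.get("table", [])
    background = int(mats.get("background_grey", 0))
    return (_probe_from_fields(probe, image),
            _materials_from_entries(entries, background))


def save_config_yaml(probe: ProbeConfig, materials: MaterialTable,
                     path: str | Path) -> None:
    probe_d = {
        "kind": probe.kind,
        "n_scanlines": probe.n_scanlines,
        "depth_mm": probe.scanline_depth_mm,
        "samples_per_line": probe.samples_per_line,
    }
    if probe.kind == "curvilinear":
        probe_d["fov_deg"] = probe.fov_deg
        probe_d["transducer_radius_mm"] = probe.transducer_radius_mm
    else:
        probe_d["footprint_mm"] = probe.footprint_mm
    data = {
        "probe": probe_d,
        "image": {
            "width_px": probe.image_width_px,
            "height_px": probe.image_height_px,
            "pixel_spacing_mm": probe.pixel_spacing_mm,
            "interpolation": probe.interpolation,
        },
        "materials": {
            "background_grey": materials.background.grey_value,
            "table": [
                {"id": m.material_id, "grey": m.grey_value,
                 "attenuation_per_mm": m.attenuation_per_mm}
                for m in materials.materials.values()
            ],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_pose(path: str | Path) -> Pose:
    """Read a pose from JSON ({"matrix": ...}) or plain-text 16 numbers."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
        m = np.asarray(data["matrix"] if isinstance(data, dict) else data,
                       dtype=float)
    else:
        m = np.array(text.replace(",", " ").split(), dtype=float)
    pose = Pose(m.reshape(4, 4))
    pose.validate()
    return pose


def save_pose(pose: Pose, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": pose.matrix.tolist()}, fh, indent=1)
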