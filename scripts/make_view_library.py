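"""Regenerate the packaged view library (data/standard_views.yaml).

The preset poses are *designed* against the default procedural hearts:
plane anchors come from structure centroids and the canonical anatomy,
the probe stands off so the target sits mid-field.  Run after any change
to the generator anatomy:

    python scripts/make_view_library.py
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from fetalecho.heart_model import pose_from_plane
from fetalecho.synthetic_heart import SyntheticHeartSpec, generate_heart

STANDOFF = 28.0  # mm: target sits mid-field of the 55 mm default depth


def plane_normal(p1, p2, p3):
    n = np.cross(np.asarray(p2, float) - p1, np.asarray(p3, float) - p1)
    return n / np.linalg.norm(n)


def entry(target, d, n, required, forbidden=(), check=None, standoff=STANDOFF):
    pose = pose_from_plane(target, d, n, standoff)
    e = {
        "pose": [float(v) for v in pose.matrix.ravel()],
        "required": sorted(required),
    }
    if forbidden:
        e["forbidden"] = sorted(forbidden)
    if check:
        e["check"] = check
    return e


def main() -> None:
    normal = generate_heart(SyntheticHeartSpec.preset("normal"))
    hrh = generate_heart(SyntheticHeartSpec.preset("hrh_vsd_mga_pa"))
    c = {s.name: s.mesh.center_mass for s in normal.structures}
    ch = {s.name: s.mesh.center_mass for s in hrh.structures}

    views = {}

    # four-chamber: best-fit plane through the four chamber centroids,
    # probe from the fetal anterior chest wall
    pts = np.array([c["LV"], c["RV"], c["LA"], c["RA"]])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    n4 = vt[2]
    views["four_chamber"] = entry(centroid, (0, 1, 0), n4,
                                  ["LA", "RA", "LV", "RV"])

    # LV outflow tract: plane spanned by the LV long axis and the
    # proximal ascending aorta
    apex_dir = np.array([0.0, 0.0, -8.0])
    n = plane_normal(c["LV"], c["LV"] + apex_dir, c["AO"])
    d = c["AO"] - (c["LV"] + apex_dir)
    views["lvot"] = entry((c["LV"] + c["AO"]) / 2, d, n, ["LV", "AO"])

    # RV outflow tract: RV long axis and pulmonary trunk
    n = plane_normal(c["RV"], c["RV"] + apex_dir, c["PA"])
    d = c["PA"] - (c["RV"] + apex_dir)
    views["rvot"] = entry((c["RV"] + c["PA"]) / 2, d, n, ["RV", "PA"])

    # three-vessel view: transverse plane through the upper mediastinum
    views["three_vessel"] = entry((0, 2, 6.5), (0, 1, 0), (0, 0, 1),
                                  ["PA", "AO", "SVC"])

    # three vessels and trachea: slightly more cephalad transverse plane
    views["three_vessel_trachea"] = entry(
        (0, 4, 8.7), (0, 1, 0), (0, 0, 1),
        ["PA", "DA", "AO", "SVC", "Trachea"])

    # aortic arch ("candy cane"): plane through ascending aorta, arch
    # and descending aorta
    n = plane_normal(c["AO"], c["Arch"], c["DAO"])
    d = c["DAO"] - c["AO"]
    views["aortic_arch"] = entry(c["Arch"], d, n, ["AO", "Arch", "DAO"])

    # ductal arch: plane through pulmonary trunk, ductus and DAO
    n = plane_normal(c["PA"], c["DA"], c["DAO"])
    d = c["DAO"] - c["PA"]
    views["ductal"] = entry(c["DA"], d, n, ["PA", "DA", "DAO"])

    # bicaval: plane through both venae cavae and the right atrium
    n = plane_normal(c["SVC"], c["IVC"], c["RA"])
    d = c["IVC"] - c["SVC"]
    views["bicaval"] = entry(c["RA"], d, n, ["SVC", "IVC", "RA"])

    # ---- lesion-sensitive views ------------------------------------------
    lesion = {"double_aortic_arch": {}, "hrh_vsd_mga_pa": {}}

    # transverse plane cephalad of the 3VT: both arch limbs in cross
    # section on either side of the trachea
    lesion["double_aortic_arch"]["ring_transverse"] = entry(
        (0.5, 7.5, 10.3), (0, 1, 0), (0, 0, 1),
        ["lArch", "rArch", "Trachea"], check="two_arch_regions")
    # coronal plane through the posterior junctions: both limbs rejoining
    # the descending aorta
    lesion["double_aortic_arch"]["ring_coronal"] = entry(
        (1.0, 11.3, 2.0), (0, 0, -1), (0, 1, 0),
        ["lArch", "rArch", "DAO"], check="arches_join_dao")

    # HRH four-chamber: same plane as the standard preset, but the RV
    # area must be smaller than the LV area
    lesion["hrh_vsd_mga_pa"]["four_chamber_rv_small"] = dict(
        views["four_chamber"], check="rv_smaller_than_lv")

    # VSD plane: contains the LV-RV axis (and so the septal channel)
    axis = ch["RV"] - ch["LV"]
    n = np.cross(axis, [0.0, 1.0, 0.0])
    n = n / np.linalg.norm(n)
    lesion["hrh_vsd_mga_pa"]["vsd_channel"] = entry(
        (ch["LV"] + ch["RV"]) / 2, (0, 1, 0), n,
        ["LV", "RV", "VSD"], check="lv_rv_channel")

    # pulmonary atresia: plane through the blind trunk and the ventricle
    n = plane_normal(ch["PA"], ch["RV"], ch["DA"])
    d = ch["PA"] - ch["RV"]
    lesion["hrh_vsd_mga_pa"]["pa_origin"] = entry(
        (ch["PA"] + ch["RV"]) / 2, d, n,
        ["PA", "RV"], check="no_pa_rv_contact")

    out = Path(__file__).resolve().parents[1] / "src" / "fetalecho" / \
        "data" / "standard_views.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write("# Preset probe poses (image->heart, 4x4 row-major) for the\n"
                 "# standard fetal echocardiography views and the lesion-\n"
                 "# sensitive views of the two pathology cases, designed on\n"
                 "# the default procedural hearts.  Regenerate with\n"
                 "# scripts/make_view_library.py.\n")
        yaml.safe_dump({"views": views, "lesion_views": lesion}, fh,
                       sort_keys=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
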