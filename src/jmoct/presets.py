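"""Packaged zebrafish phantom presets.

A preset couples a cartoon geometry (labelled regions: water, skin, muscles,
spine, gills, a flow vessel and a pigmented depolarizing patch) with per-organ
optical properties for a requested age group.  The geometry is deterministic;
two seeds differ only in the speckle/noise realization of the simulated
volume, never in the property tables.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml
from scipy.ndimage import binary_erosion

from .phantom import LayerProperty, PhantomSpec
from .system import SystemProfile
from .volumes import ROIMask

__all__ = ["available_presets", "age_groups", "make_zebrafish_phantom",
           "organ_masks", "LABELS"]

#: integer label per region
LABELS = {"water": 0, "skin": 1, "muscles": 2, "spine": 3, "gills": 4,
          "vessel": 5, "pigment": 6}

_AGE_ALIASES = {"1m": "1-month", "1-month": "1-month",
                "2m": "2-month", "2-month": "2-month"}


def _load_preset_file() -> dict:
    text = resources.files("jmoct").joinpath("presets/zebrafish.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(k for k in _load_preset_file() if k != "optics")


def age_groups() -> list[str]:
    return sorted(_load_preset_file()["optics"]["by_age"])


def make_zebrafish_phantom(preset: str, age_group: str, seed: int = 0) -> PhantomSpec:
    """Build a PhantomSpec for a packaged layout and age group.

    The per-organ attenuation and birefringence equal the bundled reference
    means for the requested age; the geometry is the preset's layered cartoon.
    """
    cfg = _load_preset_file()
    if preset not in cfg or preset == "optics":
        raise ValueError(
            f"unknown preset {preset!r}; available: {available_presets()}")
    age = _AGE_ALIASES.get(age_group)
    if age is None or age not in cfg["optics"]["by_age"]:
        raise ValueError(
            f"unknown age group {age_group!r}; available: {age_groups()} "
            f"(aliases: 1m, 2m)")

    layout = cfg[preset]
    optics = cfg["optics"]
    labels = _build_labels(layout)
    system = SystemProfile(**layout["system"])

    albedo = float(optics["albedo_scale"])
    props: dict[int, LayerProperty] = {}
    for name, st in optics["static"].items():
        props[LABELS[name]] = LayerProperty(
            label=name, mu_atten=st["mu"], birefringence=st["birefringence"],
            optic_axis=st.get("axis", 0.0), reflectivity=albedo * st["mu"],
            depol_fraction=st.get("depol_fraction", 0.0),
            flow=bool(st.get("flow", False)))
    for organ, vals in optics["by_age"][age].items():
        props[LABELS[organ]] = LayerProperty(
            label=organ, mu_atten=vals["mu"],
            birefringence=vals["birefringence"],
            optic_axis=optics["axes"][organ],
            reflectivity=albedo * vals["mu"])

    return PhantomSpec(label_volume=labels, properties=props, system=system,
                       seed=seed, name=f"{preset}/{age}",
                       meta={"preset": preset, "age_group": age})


def _build_labels(layout: dict) -> np.ndarray:
    nz, nx, ny = layout["shape"]
    g = layout["geometry"]
    lab = np.full((nz, nx, ny), LABELS["water"], dtype=np.int16)

    top = g["water_top"]
    skin_bottom = top + g["skin_thickness"]
    lab[top:skin_bottom] = LABELS["skin"]
    lab[skin_bottom:] = LABELS["muscles"]

    gl = g["gills"]
    lab[skin_bottom:gl["z_max"], : gl["x_max"], :] = LABELS["gills"]

    sp = g["spine"]
    z = np.arange(nz)[:, None]
    x = np.arange(nx)[None, :]
    ell = ((z - sp["z_center"]) / sp["rz"]) ** 2 + \
          ((x - sp["x_center"]) / sp["rx"]) ** 2 <= 1.0
    lab[np.broadcast_to(ell[:, :, None], lab.shape)] = LABELS["spine"]

    vs = g["vessel"]
    circ = (z - vs["z_center"]) ** 2 + (x - vs["x_center"]) ** 2 <= vs["radius"] ** 2
    circ &= z >= skin_bottom
    lab[np.broadcast_to(circ[:, :, None], lab.shape)] = LABELS["vessel"]

    pg = g["pigment"]
    lab[pg["z_min"]:pg["z_max"], pg["x_min"]:, :] = LABELS["pigment"]
    return lab


def organ_masks(spec: PhantomSpec,
                organs: tuple[str, ...] = ("spine", "muscles", "gills", "skin"),
                erode: tuple[int, int] = (2, 1)) -> dict[str, ROIMask]:
    """Ground-truth ROI masks from the phantom labels.

    Masks are eroded by ``erode`` pixels in (z, x) so that quantification
    avoids boundary voxels, where kernel-based estimators mix neighbouring
    regions (the counterpart of conservative manual segmentation).
    """
    ez, ex = erode
    struct = np.ones((2 * ez + 1, 2 * ex + 1, 1), dtype=bool)
    out = {}
    for organ in organs:
        m = spec.label_volume == LABELS[organ]
        if ez or ex:
            m = binary_erosion(m, structure=struct)
        out[organ] = ROIMask(mask=m, organ_label=organ,
                             source=f"phantom labels ({spec.name})")
    return out
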