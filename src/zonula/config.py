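"""YAML study-configuration loading.

A config file has optional blocks ``lenses`` (per-lens geometry overrides),
``zonule`` / ``combinations``, ``materials``, ``resolution`` and top-level
``stretch``, ``output_dir``, ``seed``.  Missing keys fall back to the study
defaults (the two reference lenses with combinations A/B and C/D).

Example::

    stretch: 0.5
    resolution: {n_meridional: 40, n_radial: 16, n_azimuthal: 16}
    lenses:
      asymmetric: {r_anterior: 10.96, r_posterior: 6.94}
    combinations:
      asymmetric: [A, B]
      symmetric: [C, D]
    zonule: {count: 17, length_mm: 1.5, radius_mm: 0.025, angle_deg: 15}
    materials:
      nucleus_E_kpa: 0.6
      step_kpa: 0.5
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import geometry
from .experiments import StudyConfig
from .materials import MaterialTable, layer_moduli
from .mesh import Resolution
from .optics import OpticalConstants

__all__ = ["load_config", "default_config"]

_LENS_FACTORIES = {
    "asymmetric": geometry.asymmetric_lens_spec,
    "symmetric": geometry.symmetric_lens_spec,
}


def default_config() -> StudyConfig:
    return StudyConfig()


def load_config(path: str | Path) -> StudyConfig:
    """Parse a YAML study configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}

    lenses = {}
    for label, overrides in (raw.get("lenses") or {}).items():
        factory = _LENS_FACTORIES.get(label)
        if factory is None:
            lenses[label] = geometry.LensGeometrySpec(name=label, **(overrides or {}))
        else:
            lenses[label] = factory(**(overrides or {}))
    if lenses:
        for label, factory in _LENS_FACTORIES.items():
            lenses.setdefault(label, factory())
        kwargs["lenses"] = lenses

    if "combinations" in raw:
        kwargs["combinations"] = {
            lens: tuple(combos) for lens, combos in raw["combinations"].items()
        }
    if "resolution" in raw:
        kwargs["resolution"] = Resolution(**raw["resolution"])
    if "stretch" in raw:
        kwargs["stretch"] = float(raw["stretch"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])

    mat = raw.get("materials") or {}
    if mat:
        layer_E = mat.get("layer_E_kpa")
        if layer_E is None:
            layer_E = layer_moduli(
                n_layers=int(mat.get("n_layers", 13)),
                nucleus_E=float(mat.get("nucleus_E_kpa", 0.6)),
                step=float(mat.get("step_kpa", 0.5)),
            )
        kwargs["materials"] = MaterialTable(
            layer_E=np.asarray(layer_E, dtype=float),
            nu_lens=float(mat.get("nu_lens", 0.49)),
            E_capsule=float(mat.get("E_capsule_mpa", 1.5)),
            nu_capsule=float(mat.get("nu_capsule", 0.47)),
            E_zonule=float(mat.get("E_zonule_mpa", 0.35)),
            nu_zonule=float(mat.get("nu_zonule", 0.47)),
            capsule_thickness=float(mat.get("capsule_thickness_mm", 0.006)),
            zonule_area=float(mat.get("zonule_area_mm2", np.pi * 0.025**2)),
        )

    zon = raw.get("zonule") or {}
    if zon:
        overrides = {}
        if "count" in zon:
            overrides["fibres_per_section"] = int(zon["count"])
        if "length_mm" in zon:
            overrides["fibre_length"] = float(zon["length_mm"])
        if "radius_mm" in zon:
            overrides["fibre_radius"] = float(zon["radius_mm"])
        if "angle_deg" in zon:
            a = float(zon["angle_deg"])
            overrides["section_angles"] = (a, 0.0, -a)
        kwargs["zonule_overrides"] = overrides

    opt = raw.get("optics") or {}
    if opt:
        kwargs["constants"] = OpticalConstants(
            n_lens=float(opt.get("n_lens", 1.42)),
            n_aqueous=float(opt.get("n_aqueous", 1.336)),
            paraxial_halfwidth=float(opt.get("paraxial_halfwidth_mm", 1.5)),
            central_zone_diameter=float(opt.get("central_zone_diameter_mm", 6.0)),
        )
    return StudyConfig(**kwargs)
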