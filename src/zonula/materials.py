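"""Layered elastic properties of the lens, capsule and zonule.

The lens interior carries a stiffness gradient: the nucleus is softest and
each of the 12 cortical shells is stiffer than the one inside it, in equal
arithmetic steps (0.6 kPa nucleus, +0.5 kPa per layer, 6.6 kPa outermost
cortex, cortical average 3.85 kPa).  The capsule is a 6 micron membrane at
1.5 MPa; zonular fibres are 0.35 MPa.  Poisson's ratio is 0.49 for the whole
lens (nearly incompressible) and 0.47 for capsule and zonule.

Assembly works in a consistent (mm, N, MPa) unit system; lens-layer moduli
are stored in kPa, as tabulated, and converted to MPa exactly once via
:meth:`MaterialTable.layer_E_mpa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaterialTable", "layer_moduli", "cortex_average"]


def layer_moduli(n_layers: int = 13, nucleus_E: float = 0.6, step: float = 0.5) -> np.ndarray:
    """Arithmetic stiffness ladder from nucleus to outer cortex, kPa.

    ``layer_moduli()[0]`` is the nucleus (0.6 kPa); each subsequent cortical
    layer adds ``step`` (0.5 kPa), ending at 6.6 kPa for the defaults.
    """
    if n_layers < 2:
        raise ValueError("need at least nucleus + one cortical layer")
    if nucleus_E <= 0 or step < 0:
        raise ValueError("nucleus modulus must be positive and step non-negative")
    return nucleus_E + step * np.arange(n_layers, dtype=float)


@dataclass(frozen=True)
class MaterialTable:
    """Elastic constants of every structural component.

    ``layer_E`` is indexed 0 (nucleus) .. n-1 (outermost cortex), kPa; all
    other moduli are MPa.
    """

    layer_E: np.ndarray = field(default_factory=layer_moduli)
    nu_lens: float = 0.49
    E_capsule: float = 1.5
    nu_capsule: float = 0.47
    E_zonule: float = 0.35
    nu_zonule: float = 0.47
    capsule_thickness: float = 0.006
    zonule_area: float = float(np.pi * 0.025**2)

    def __post_init__(self) -> None:
        E = np.asarray(self.layer_E, dtype=float)
        object.__setattr__(self, "layer_E", E)
        if np.any(E <= 0):
            raise ValueError("layer moduli must be positive")
        if np.any(np.diff(E) < 0):
            raise ValueError("layer moduli must be non-decreasing from nucleus outward")
        for nu in (self.nu_lens, self.nu_capsule, self.nu_zonule):
            if not 0.0 < nu < 0.5:
                raise ValueError("Poisson ratios must lie in (0, 0.5)")
        if self.E_capsule <= 0 or self.E_zonule <= 0:
            raise ValueError("capsule and zonule moduli must be positive")
        if self.capsule_thickness <= 0:
            raise ValueError("capsule thickness must be positive")
        if self.zonule_area <= 0:
            raise ValueError("zonule cross-section must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.layer_E)

    def layer_E_mpa(self) -> np.ndarray:
        """Lens layer moduli converted kPa -> MPa (the assembly unit)."""
        return self.layer_E * 1e-3


def cortex_average(table: MaterialTable) -> float:
    """Arithmetic mean of the cortical layer moduli (all layers but the
    nucleus), kPa; 3.85 kPa for the default ladder."""
    if table.n_layers < 2:
        raise ValueError("table has no cortical layers")
    return float(np.mean(table.layer_E[1:]))
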