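"""Thermal-energy scales and product-release energetics.

Free energies of the translocase cycle are expressed in units of the thermal
energy k_B·T. Two quantities recur throughout the analysis of a DNA motor:

* the free energy released when the enzyme lets go of a hydrolysis product
  (phosphate or ADP), estimated from the ratio of release and binding rates or
  equivalently from the dissociation constant and the ambient concentration,
  ``ΔG = k_B·T · ln(K_d / [ligand])``;
* the mechanical work performed per power stroke, ``W = F · d``, compared
  against the ~110 pN·nm available from one ATP turnover.

Sign convention: release free energies are returned as the *magnitude* of
free energy released — positive means release is favorable at the given
ligand concentration. A negative return value signals that release is
thermodynamically uphill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BOLTZMANN_PN_NM",
    "BP_RISE_NM",
    "ATP_HYDROLYSIS_PN_NM",
    "ThermalScale",
    "ReleaseEquilibrium",
    "thermal_energy",
    "release_free_energy",
    "power_stroke_work",
    "step_to_nm",
]

#: Boltzmann constant in pN·nm/K.
BOLTZMANN_PN_NM = 0.0138065

#: Helical rise of B-form DNA, nm per base pair.
BP_RISE_NM = 0.34

#: Free energy available from hydrolysing one ATP under the assay's buffer
#: conditions, pN·nm. Exposed as a configurable budget, not computed from
#: standard free energies.
ATP_HYDROLYSIS_PN_NM = 110.0


def thermal_energy(temperature: float) -> float:
    """Return k_B·T in pN·nm for a temperature in kelvin.

    >>> round(thermal_energy(298.0), 3)
    4.114
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature} K")
    return BOLTZMANN_PN_NM * temperature


@dataclass(frozen=True)
class ThermalScale:
    """Temperature and the derived thermal energy k_B·T (pN·nm)."""

    temperature: float = 298.0
    kBT: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kBT", thermal_energy(self.temperature))

    @classmethod
    def from_kBT(cls, kBT: float) -> "ThermalScale":
        """Build a scale from a thermal energy in pN·nm."""
        if kBT <= 0:
            raise ValueError(f"kBT must be positive, got {kBT}")
        return cls(temperature=kBT / BOLTZMANN_PN_NM)


#: Default thermal energy used by the model modules (room temperature).
DEFAULT_SCALE = ThermalScale.from_kBT(4.11)


@dataclass(frozen=True)
class ReleaseEquilibrium:
    """Product-release equilibrium E·P ⇌ E + P.

    Exactly one of ``kd`` (dissociation constant, μM) or ``rate_ratio``
    (k_release / k_bind, dimensionless) must be given. With ``kd``, the
    off/on rate ratio at ambient concentration c is K_d / c.
    """

    kd: float | None = None
    rate_ratio: float | None = None
    ligand_concentration: float | None = None

    def __post_init__(self) -> None:
        if (self.kd is None) == (self.rate_ratio is None):
            raise ValueError("supply exactly one of kd or rate_ratio")
        if self.kd is not None:
            if self.kd <= 0:
                raise ValueError(f"kd must be positive, got {self.kd}")
            if self.ligand_concentration is None or self.ligand_concentration <= 0:
                raise ValueError("kd form requires a positive ligand_concentration")
        elif self.rate_ratio is not None and self.rate_ratio <= 0:
            raise ValueError(f"rate_ratio must be positive, got {self.rate_ratio}")

    @property
    def effective_ratio(self) -> float:
        if self.rate_ratio is not None:
            return self.rate_ratio
        assert self.kd is not None and self.ligand_concentration is not None
        return self.kd / self.ligand_concentration


def release_free_energy(eq: ReleaseEquilibrium, scale: ThermalScale = DEFAULT_SCALE) -> float:
    """Magnitude of the free energy released on product release, in kBT.

    ``ΔG = ln(k_rel / k_bind) = ln(K_d / [ligand])`` in kBT units; positive
    when release is favorable (ratio > 1). The ``scale`` argument is accepted
    for interface symmetry — the kBT-unit result is temperature-free.
    """
    del scale  # result is dimensionless in kBT units
    return math.log(eq.effective_ratio)


def power_stroke_work(
    force: float,
    step: float,
    bp_length: float = BP_RISE_NM,
    scale: ThermalScale = DEFAULT_SCALE,
) -> tuple[float, float]:
    """Mechanical work of one power stroke against ``force``.

    Parameters
    ----------
    force : opposing force, pN.
    step : step size, bp.
    bp_length : contour length per bp, nm.

    Returns
    -------
    (work_pN_nm, work_kBT)
    """
    if force < 0 or step < 0 or bp_length < 0:
        raise ValueError("force, step and bp_length must be non-negative")
    work = force * step * bp_length
    return work, work / scale.kBT


def step_to_nm(step: float, bp_length: float = BP_RISE_NM) -> float:
    """Convert a step size in bp to nm of contour."""
    if step < 0 or bp_length < 0:
        raise ValueError("step and bp_length must be non-negative")
    return step * bp_length
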