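"""Composition analysis of fitted slab densities.

A fitted slab electron density is a volume-weighted average of the
densities of its components.  For a hydrated lipid head group,

    ρ_measured = ρ_H·(1 − φ_w) + ρ_water·φ_w
    ⇒  φ_w = (ρ_H − ρ_measured)/(ρ_H − ρ_water)

with ρ_H the dry head-group density (obtainable from a dry monolayer
measurement) and ρ_water = 0.335 e⁻·Å⁻³.  For a protein layer bathed in
buffer the same rule, solved the other way, gives the protein volume
fraction

    ρ_measured = ρ_protein·φ + ρ_water·(1 − φ)
    ⇒  φ = (ρ_measured − ρ_water)/(ρ_protein − ρ_water).

A drop in head-group hydration Δφ_w translates into displaced water
molecules per lipid through the head-group volume (area per lipid ×
head-group thickness) divided by the volume of one water molecule (29 Å³).

Protein volume and electron density are computed from the amino-acid
sequence using a published table of mean residue volumes (Zamyatnin 1972)
and residue electron counts derived from the anhydrous (in-chain) residue
formulas; simple globular size estimates (equivalent-sphere diameter,
minimal anhydrous radius from molecular mass) complete the picture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "RHO_WATER",
    "WATER_VOLUME_A3",
    "MixingRuleInput",
    "LipidGeometry",
    "CompositionReport",
    "water_fraction",
    "protein_fraction",
    "displaced_waters",
    "protein_volume_from_sequence",
    "protein_electron_density_from_sequence",
    "sphere_diameter",
    "rmin_from_mass",
    "load_volume_table",
    "RESIDUE_ELECTRONS",
]

RHO_WATER = 0.335  # e-/A^3, aqueous buffer
WATER_VOLUME_A3 = 29.0  # volume of one water molecule

# Electrons per anhydrous (in-chain) amino-acid residue, from the residue
# molecular formulas (C=6, H=1, N=7, O=8, S=16 electrons per atom).  The
# loss of one water per peptide bond is thereby accounted for.
RESIDUE_ELECTRONS = {
    "G": 30, "A": 38, "S": 46, "P": 52, "V": 54, "T": 54, "C": 54,
    "L": 62, "I": 62, "N": 60, "D": 60, "Q": 68, "K": 70, "E": 68,
    "M": 70, "H": 72, "F": 78, "R": 84, "Y": 86, "W": 98,
}


def load_volume_table(path=None) -> dict[str, float]:
    """Load a per-residue volume table (Å³) from a two-column TSV.

    Defaults to the bundled Zamyatnin (1972) mean residue volumes.
    """
    if path is None:
        ref = resources.files("lipidxrr.data").joinpath(
            "residue_volumes_zamyatnin1972.tsv"
        )
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, vol = line.split()
        table[code] = float(vol)
    return table


class DegenerateContrastError(ValueError):
    """Component and water densities coincide: the mixing rule is singular."""


@dataclass(frozen=True)
class MixingRuleInput:
    """Inputs to the two-component density mixing rule (all e⁻·Å⁻³)."""

    rho_measured: float
    rho_component: float
    rho_water: float = RHO_WATER

    def __post_init__(self):
        for v in (self.rho_measured, self.rho_component, self.rho_water):
            if not math.isfinite(v) or v < 0:
                raise ValueError("mixing-rule densities must be finite and >= 0")
        if self.rho_component == self.rho_water:
            raise DegenerateContrastError(
                "component density equals water density: fraction undetermined"
            )


@dataclass(frozen=True)
class LipidGeometry:
    """Head-group geometry used for displaced-water bookkeeping.

    Defaults: 70 Å² per lipid, 11.5 Å head-group thickness (midrange of the
    11–12 Å typical of phosphatidylcholine heads), 29 Å³ per water.
    """

    area_per_lipid: float = 70.0
    headgroup_thickness: float = 11.5
    water_volume: float = WATER_VOLUME_A3

    def __post_init__(self):
        if min(self.area_per_lipid, self.headgroup_thickness, self.water_volume) <= 0:
            raise ValueError("lipid geometry parameters must be > 0")

    @property
    def headgroup_volume(self) -> float:
        """Volume sampled by one head group, Å³."""
        return self.area_per_lipid * self.headgroup_thickness


@dataclass
class CompositionReport:
    """Summary of the composition analysis of a before/after density pair."""

    phi_w_before: float
    phi_w_after: float
    delta_hydration: float  # percentage points (before - after)
    displaced_waters_exact: float
    displaced_waters: int
    phi_protein: float | None = None
    geometry: LipidGeometry = field(default_factory=LipidGeometry)

    def as_dict(self) -> dict:
        out = {
            "phi_w_before_percent": 100.0 * self.phi_w_before,
            "phi_w_after_percent": 100.0 * self.phi_w_after,
            "delta_hydration_percent_points": self.delta_hydration,
            "displaced_waters_per_lipid_exact": self.displaced_waters_exact,
            "displaced_waters_per_lipid": self.displaced_waters,
            "area_per_lipid_A2": self.geometry.area_per_lipid,
            "headgroup_thickness_A": self.geometry.headgroup_thickness,
            "water_volume_A3": self.geometry.water_volume,
        }
        if self.phi_protein is not None:
            out["phi_protein_percent"] = 100.0 * self.phi_protein
        return out


def _clip_fraction(phi: float, what: str) -> float:
    if not 0.0 <= phi <= 1.0:
        warnings.warn(
            f"{what} = {phi:.3f} outside [0, 1]; measured density lies outside "
            "the component/water interval — clipping",
            stacklevel=3,
        )
        phi = min(1.0, max(0.0, phi))
    return phi


def water_fraction(inp: MixingRuleInput) -> float:
    """Volume fraction of water in a hydrated slab.

    φ_w = (ρ_H − ρ_measured)/(ρ_H − ρ_water); 0 for a dry slab, 1 for pure
    water.  Measured densities outside the [ρ_water, ρ_H] interval are
    clipped with a warning.
    """
    phi = (inp.rho_component - inp.rho_measured) / (inp.rho_component - inp.rho_water)
    return _clip_fraction(phi, "water fraction")


def protein_fraction(inp: MixingRuleInput) -> float:
    """Volume fraction of protein in a buffer-bathed slab.

    φ = (ρ_measured − ρ_water)/(ρ_protein − ρ_water); exact algebraic
    inverse of the mixing rule ρ = ρ_protein·φ + ρ_water·(1 − φ).
    """
    phi = (inp.rho_measured - inp.rho_water) / (inp.rho_component - inp.rho_water)
    return _clip_fraction(phi, "protein fraction")


def displaced_waters(
    delta_phi_w: float, geometry: LipidGeometry = LipidGeometry()
) -> tuple[float, int]:
    """Waters displaced per lipid for a hydration drop Δφ_w.

    exact = Δφ_w · (area_per_lipid · headgroup_thickness) / water_volume;
    also returned rounded to the nearest integer (what is physically
    countable).
    """
    if not 0.0 <= delta_phi_w <= 1.0:
        raise ValueError("delta_phi_w must be a fraction in [0, 1]")
    exact = delta_phi_w * geometry.headgroup_volume / geometry.water_volume
    return exact, int(round(exact))


def _check_sequence(sequence: str, table: dict[str, float]) -> str:
    seq = "".join(sequence.split()).upper()
    unknown = sorted({c for c in seq if c not in table})
    if unknown:
        raise ValueError(f"unknown residue codes in sequence: {unknown}")
    if not seq:
        warnings.warn("empty sequence: volume/electron totals are 0", stacklevel=3)
    return seq


def protein_volume_from_sequence(
    sequence: str, volume_table: dict[str, float] | None = None
) -> float:
    """Anhydrous protein volume (Å³) as the sum of mean residue volumes."""
    table = volume_table if volume_table is not None else load_volume_table()
    seq = _check_sequence(sequence, table)
    return sum(table[c] for c in seq)


def protein_electron_density_from_sequence(
    sequence: str,
    volume_table: dict[str, float] | None = None,
    electron_table: dict[str, int] | None = None,
) -> float:
    """Mean electron density (e⁻·Å⁻³) of the anhydrous protein.

    Total in-chain residue electrons (peptide-bond water loss already in
    the residue formulas) divided by total residue volume; independent of
    sequence order.
    """
    vtable = volume_table if volume_table is not None else load_volume_table()
    etable = electron_table if electron_table is not None else RESIDUE_ELECTRONS
    seq = _check_sequence(sequence, vtable)
    if not seq:
        raise ValueError("cannot form a density for an empty sequence")
    missing = sorted({c for c in seq if c not in etable})
    if missing:
        raise ValueError(f"no electron count for residues: {missing}")
    volume = sum(vtable[c] for c in seq)
    electrons = sum(etable[c] for c in seq)
    return electrons / volume


def sphere_diameter(volume_A3: float) -> float:
    """Diameter (nm) of a sphere of the given volume (Å³): d = (6V/π)^⅓."""
    if volume_A3 <= 0:
        raise ValueError("volume must be > 0")
    return (6.0 * volume_A3 / math.pi) ** (1.0 / 3.0) / 10.0


def rmin_from_mass(mass_da: float) -> float:
    """Minimal anhydrous globular radius (nm) for a protein of given mass.

    R_min = 0.066·M^⅓ nm (M in Da), the standard relation following from a
    protein partial specific volume of ~0.73 cm³/g.
    """
    if mass_da <= 0:
        raise ValueError("mass must be > 0")
    return 0.066 * mass_da ** (1.0 / 3.0)


def hydration_report(
    rho_head_dry: float,
    rho_before: float,
    rho_after: float,
    geometry: LipidGeometry = LipidGeometry(),
    rho_protein: float | None = None,
    rho_protein_layer: float | None = None,
    rho_water: float = RHO_WATER,
) -> CompositionReport:
    """Full before/after composition analysis of an outer head group.

    Computes hydration fractions before and after protein incubation, the
    hydration change in percentage points, the displaced waters per lipid,
    and (when a protein layer density and protein density are supplied) the
    protein volume fraction of the adsorbed layer.
    """
    phi_before = water_fraction(MixingRuleInput(rho_before, rho_head_dry, rho_water))
    phi_after = water_fraction(MixingRuleInput(rho_after, rho_head_dry, rho_water))
    delta = phi_before - phi_after
    exact, rounded = displaced_waters(max(delta, 0.0), geometry)
    phi_p = None
    if rho_protein is not None and rho_protein_layer is not None:
        phi_p = protein_fraction(
            MixingRuleInput(rho_protein_layer, rho_protein, rho_water)
        )
    return CompositionReport(
        phi_w_before=phi_before,
        phi_w_after=phi_after,
        delta_hydration=100.0 * delta,
        displaced_waters_exact=exact,
        displaced_waters=rounded,
        phi_protein=phi_p,
        geometry=geometry,
    )
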