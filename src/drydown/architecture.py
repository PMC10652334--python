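"""Plant compartment network and pot-soil water relations.

The plant is discretized into a chain of compartments
(soil - root - trunk - branch - leaf).  Compartment dimensions come from a
simple fractal allometry: the trunk is a cylinder from measured height and
basal diameter, and branch/root dimensions follow fixed branching ratios.
The whole-plant hydraulic conductance ``k_plant * leaf_area`` is partitioned
in series as 50% of the resistance in the root segment, 12.5% each in the
trunk and branch segments, and 25% in the leaf segment.

The pot soil is a single layer (the pot surface is film-covered, so soil
evaporation is zero) with Campbell retention anchored so that the matric
potential at field capacity equals -0.033 MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .traits import SpeciesTraits

__all__ = [
    "SoilParams",
    "Compartment",
    "PlantNetwork",
    "build_fractal_tree",
    "soil_water_potential",
    "soil_root_conductance",
    "extractable_water_l",
    "MOL_PER_L",
    "DEFAULT_K_PLANT",
]

#: mol of water per litre (molar mass 18.015 g/mol).
MOL_PER_L = 1000.0 / 18.015
#: Default whole-plant hydraulic conductance per leaf area (mmol s^-1 m^-2 MPa^-1).
DEFAULT_K_PLANT = 1.5
#: Matric potential at field capacity (MPa), conventional value.
PSI_FIELD_CAPACITY = -0.033
#: Potential floor (MPa): soil at residual content is clipped here.
PSI_SOIL_CLIP = -50.0
#: Default soil-root conductance anchor: the interface passes this much
#: (mmol s^-1 MPa^-1, well above whole-plant conductance) at -1 MPa soil
#: potential, so it only becomes limiting in genuinely dry soil.
K_SOILROOT_ANCHOR = 50.0
K_SOILROOT_ANCHOR_PSI = -1.0  # MPa

# Fractal branching ratios (declared constants; the trait table gives only
# trunk allometry).  Volumes relative to the trunk cylinder; diameters
# relative to the basal diameter.
BRANCH_VOLUME_RATIO = 0.5
BRANCH_DIAMETER_RATIO = 0.4
ROOT_VOLUME_RATIO = 0.8

# Resistance partition of the whole-plant conductance (fractions of total
# resistance, series): root / trunk / branch / leaf.
RESISTANCE_FRACTIONS = (0.50, 0.125, 0.125, 0.25)

# Distribution of the total symplast volume across compartments.
SYMPLAST_FRACTIONS = {"root": 0.1, "trunk": 0.2, "branch": 0.2, "leaf": 0.5}


@dataclass(frozen=True)
class SoilParams:
    """Single-layer pot soil: Campbell retention and soil-to-root conductance."""

    pot_volume: float = 100.0  # L
    rwc_sat: float = 100.0  # % relative water content at saturation
    rwc_fc: float = 37.0  # % at field capacity
    rwc_res: float = 9.0  # % residual
    b_retention: float = 6.0  # Campbell exponent (sandy clay)
    #: soil-to-root interface conductance at saturation (mmol s^-1 MPa^-1).
    #: None (default) anchors the Campbell conductivity law so that the
    #: interface still passes K_SOILROOT_ANCHOR at a soil potential of
    #: -1 MPa: with k ~ theta_eff**(2b+3) the decline from saturation is so
    #: steep that any fixed desk-scale saturated value would hydraulically
    #: disconnect the plant while the soil is still wet.
    k_sat_soilroot: Optional[float] = None
    psi_e: float = field(init=False)  # air-entry potential, MPa (<0)

    def __post_init__(self) -> None:
        if self.pot_volume <= 0:
            raise ValueError(f"pot_volume must be > 0, got {self.pot_volume}")
        if not (self.rwc_res < self.rwc_fc < self.rwc_sat):
            raise ValueError(
                f"require rwc_res < rwc_fc < rwc_sat, got "
                f"{self.rwc_res}, {self.rwc_fc}, {self.rwc_sat}")
        if self.b_retention <= 0:
            raise ValueError(f"b_retention must be > 0, got {self.b_retention}")
        # anchor: psi(rwc_fc) = PSI_FIELD_CAPACITY
        te_fc = (self.rwc_fc - self.rwc_res) / (self.rwc_sat - self.rwc_res)
        object.__setattr__(self, "psi_e",
                           PSI_FIELD_CAPACITY * te_fc ** self.b_retention)
        if self.k_sat_soilroot is None:
            te_anchor = (-self.psi_e / -K_SOILROOT_ANCHOR_PSI) ** (1.0 / self.b_retention)
            k_sat = K_SOILROOT_ANCHOR / te_anchor ** (2.0 * self.b_retention + 3.0)
            object.__setattr__(self, "k_sat_soilroot", k_sat)

    def theta_eff(self, theta_rel: float) -> float:
        """Effective saturation in [0, 1] from relative water content (%)."""
        return (theta_rel - self.rwc_res) / (self.rwc_sat - self.rwc_res)


def soil_water_potential(theta_rel: float, soil: SoilParams) -> float:
    """Soil matric potential (MPa) via Campbell retention, clipped at -50 MPa.

    ``psi = psi_e * theta_eff**(-b)``, with ``psi_e`` solved so the curve
    passes through -0.033 MPa at field capacity.
    """
    if theta_rel > soil.rwc_sat:
        raise ValueError(f"theta_rel {theta_rel} exceeds saturation {soil.rwc_sat}")
    te = soil.theta_eff(theta_rel)
    if te <= 0.0:
        return PSI_SOIL_CLIP
    psi = soil.psi_e * te ** (-soil.b_retention)
    return max(psi, PSI_SOIL_CLIP)


def soil_root_conductance(theta_rel: float, soil: SoilParams) -> float:
    """Soil-to-root interface conductance (mmol s^-1 MPa^-1).

    Campbell unsaturated-conductivity scaling,
    ``k = k_sat * theta_eff**(2b + 3)``: monotone in water content, vanishing
    as the soil approaches residual.
    """
    te = soil.theta_eff(theta_rel)
    if te <= 0.0:
        return 0.0
    return soil.k_sat_soilroot * min(te, 1.0) ** (2.0 * soil.b_retention + 3.0)


def extractable_water_l(soil: SoilParams) -> float:
    """Pot extractable water (L) between field capacity and residual content."""
    return soil.pot_volume * (soil.rwc_fc - soil.rwc_res) / 100.0


@dataclass
class Compartment:
    """One plant compartment: water pools, surfaces, axial link to its parent."""

    name: str
    symplast_capacity_mol: float  # symplast water at full hydration
    apoplast_capacity_mol: float  # cavitation-releasable apoplast water
    surface_area_m2: float  # evaporating (bark) surface; 0 for root/leaf
    k_axial: float  # mmol s^-1 MPa^-1 conductance to the parent compartment


@dataclass
class PlantNetwork:
    """Discretized plant: ordered compartments from root to leaf."""

    compartments: list[Compartment]  # order: root, trunk, branch, leaf
    leaf_area: float  # m2 (initial canopy)
    bark_area: float  # m2 (trunk + branch lateral surfaces)
    k_plant: float  # mmol s^-1 m^-2 MPa^-1 (per leaf area)
    dimensions: dict = field(default_factory=dict)  # derived geometry (L, m2)

    def __getitem__(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def whole_plant_conductance(self) -> float:
        """Series conductance of the axial chain (mmol s^-1 MPa^-1)."""
        return 1.0 / sum(1.0 / c.k_axial for c in self.compartments)

    @property
    def total_water_mol(self) -> float:
        return sum(c.symplast_capacity_mol + c.apoplast_capacity_mol
                   for c in self.compartments)


def build_fractal_tree(traits: "SpeciesTraits",
                       k_plant: float = DEFAULT_K_PLANT) -> PlantNetwork:
    """Build the compartment network from trait allometry.

    Trunk volume is a cylinder from height and basal diameter; branch and root
    volumes follow the fixed fractal ratios.  Water pools scale with
    ``symplast_volume_per_area * leaf_area`` distributed across compartments,
    with apoplast reserves sized by ``apoplastic_fraction`` of total
    compartment water.  Axial conductances realize the documented series
    resistance partition of ``k_plant * leaf_area``.
    """
    if k_plant <= 0:
        raise ValueError(f"k_plant must be > 0, got {k_plant}")
    la = traits.leaf_area
    if la <= 0 or traits.height <= 0 or traits.basal_diameter <= 0:
        raise ValueError("leaf_area, height and basal_diameter must be > 0")

    radius_m = traits.basal_diameter / 100.0 / 2.0
    trunk_volume_m3 = math.pi * radius_m ** 2 * traits.height
    trunk_lateral_m2 = 2.0 * math.pi * radius_m * traits.height

    branch_volume_m3 = BRANCH_VOLUME_RATIO * trunk_volume_m3
    branch_radius_m = BRANCH_DIAMETER_RATIO * radius_m
    branch_length_m = branch_volume_m3 / (math.pi * branch_radius_m ** 2)
    branch_lateral_m2 = 2.0 * math.pi * branch_radius_m * branch_length_m

    k_total = k_plant * la  # mmol s^-1 MPa^-1
    k_root, k_trunk, k_branch, k_leaf = (k_total / f for f in RESISTANCE_FRACTIONS)

    symplast_total_mol = traits.symplast_volume_per_area * la * MOL_PER_L
    af = traits.apoplastic_fraction
    apoplast_per_symplast = af / (1.0 - af)

    def pools(name: str) -> tuple[float, float]:
        sym = symplast_total_mol * SYMPLAST_FRACTIONS[name]
        return sym, sym * apoplast_per_symplast

    comps = [
        Compartment("root", *pools("root"), surface_area_m2=0.0, k_axial=k_root),
        Compartment("trunk", *pools("trunk"), surface_area_m2=trunk_lateral_m2,
                    k_axial=k_trunk),
        Compartment("branch", *pools("branch"), surface_area_m2=branch_lateral_m2,
                    k_axial=k_branch),
        Compartment("leaf", *pools("leaf"), surface_area_m2=0.0, k_axial=k_leaf),
    ]
    return PlantNetwork(
        compartments=comps, leaf_area=la,
        bark_area=trunk_lateral_m2 + branch_lateral_m2, k_plant=k_plant,
        dimensions={
            "trunk_volume_l": trunk_volume_m3 * 1000.0,
            "branch_volume_l": branch_volume_m3 * 1000.0,
            "root_volume_l": ROOT_VOLUME_RATIO * trunk_volume_m3 * 1000.0,
            "branch_length_m": branch_length_m,
            "trunk_lateral_m2": trunk_lateral_m2,
            "branch_lateral_m2": branch_lateral_m2,
        })
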