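"""Species trait parameterizations.

A :class:`SpeciesTraits` object is the single parameter bundle consumed by the
network builder, the simulator and the sensitivity analysis.  Four builtin
parameter sets ship with the package (two conifers, *Pinus halepensis* and
*Cedrus atlantica*; two angiosperms, *Populus nigra* and *Quercus ilex*),
covering allometry, xylem vulnerability (P50, slope), pressure-volume traits
(pi0, epsilon), gas exchange (gs_max) and residual-conductance temperature
response (g_res, T_p, Q10a, Q10b).  User trait sets load from CSV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

__all__ = [
    "SheddingParams",
    "SpeciesTraits",
    "BUILTIN_SPECIES",
    "load_species_traits",
    "validate_traits",
    "write_traits_csv",
    "read_traits_csv",
    "TraitValidationError",
]

#: Reference temperature (degC) at which g_res is defined.
GRES_REFERENCE_T = 25.0


class TraitValidationError(ValueError):
    """Raised when a trait set violates its invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid traits: " + "; ".join(self.violations))


@dataclass(frozen=True)
class SheddingParams:
    """Sigmoid leaf-shedding response: PLF = 100 / (1 + exp(rate*(psi - psi_half)))."""

    rate: float = 4.0  # MPa^-1
    psi_half: float = -1.8  # MPa, 50% of leaves shed


@dataclass(frozen=True)
class SpeciesTraits:
    species_id: str
    leaf_area: float  # m2, projected canopy leaf area
    height: float  # m
    basal_diameter: float  # cm
    p50: float  # MPa, xylem potential at 50% conductivity loss (<0)
    vc_slope: float  # % MPa^-1, |dPLC/dpsi| at P50 (>0)
    pi0: float  # MPa, osmotic potential at full turgor (<0)
    epsilon: float  # MPa, bulk modulus of elasticity (>0)
    gs_max: float  # mmol m^-2 s^-1
    g_res: float  # mmol m^-2 s^-1 at GRES_REFERENCE_T
    t_p: float  # degC, phase-transition temperature of g_res
    q10_a: float  # Q10 of g_res below t_p
    q10_b: float  # Q10 of g_res above t_p
    tlp_measured: Optional[float] = None  # MPa, observational metadata only
    p_gs88_measured: Optional[float] = None  # MPa, observational metadata only
    deciduous: bool = False
    shedding_params: Optional[SheddingParams] = None
    # Not in the trait table; model parameters with documented defaults.
    apoplastic_fraction: float = 0.4  # fraction of compartment water in apoplast
    symplast_volume_per_area: float = 0.1  # L m^-2 leaf
    #: evaporating leaf surface per unit projected LA for residual losses
    #: (2 for broadleaf species whose g_res is normalized double-sided).
    leaf_surface_ratio: float = 1.0

    @property
    def turgor_loss_point(self) -> float:
        """TLP (MPa) derived from the two-parameter PV model, pi0/(1 + pi0/epsilon)."""
        return self.pi0 / (1.0 + self.pi0 / self.epsilon)

    def perturbed(self, **changes: float) -> "SpeciesTraits":
        """Return a copy with selected fields replaced (sensitivity runs)."""
        return replace(self, **changes)


def _builtin(**kw) -> SpeciesTraits:
    return SpeciesTraits(**kw)


#: Builtin fixtures: species means used to parameterize the simulations.
BUILTIN_SPECIES: dict[str, SpeciesTraits] = {
    "Pin_hale": _builtin(
        species_id="Pin_hale", leaf_area=3.64, height=2.08, basal_diameter=5.7,
        p50=-4.67, vc_slope=78.0, pi0=-1.26, epsilon=9.27, gs_max=60.0,
        g_res=0.58, t_p=42.1, q10_a=1.13, q10_b=2.99,
        tlp_measured=-2.15, p_gs88_measured=-2.96,
        deciduous=False, leaf_surface_ratio=1.0,
    ),
    "Pop_nigr": _builtin(
        species_id="Pop_nigr", leaf_area=1.94, height=1.24, basal_diameter=1.9,
        p50=-2.2, vc_slope=100.0, pi0=-1.52, epsilon=15.9, gs_max=220.0,
        g_res=4.5, t_p=35.0, q10_a=1.2, q10_b=4.8,
        tlp_measured=-2.07, p_gs88_measured=-1.14,
        deciduous=True, shedding_params=SheddingParams(4.0, -1.8),
        leaf_surface_ratio=2.0,
    ),
    "Que_ilex": _builtin(
        species_id="Que_ilex", leaf_area=1.77, height=1.49, basal_diameter=3.6,
        p50=-7.13, vc_slope=23.0, pi0=-1.89, epsilon=16.2, gs_max=100.0,
        g_res=1.19, t_p=43.2, q10_a=1.06, q10_b=1.52,
        tlp_measured=-2.83, p_gs88_measured=-4.04,
        deciduous=False, leaf_surface_ratio=2.0,
    ),
    "Ced_atla": _builtin(
        species_id="Ced_atla", leaf_area=1.24, height=1.14, basal_diameter=3.8,
        p50=-5.14, vc_slope=69.0, pi0=-2.14, epsilon=13.0, gs_max=120.0,
        g_res=1.21, t_p=41.3, q10_a=1.22, q10_b=1.83,
        tlp_measured=-3.14, p_gs88_measured=-2.57,
        deciduous=False, leaf_surface_ratio=1.0,
    ),
}


def validate_traits(t: SpeciesTraits) -> list[str]:
    """Check every trait invariant; return a list of human-readable violations.

    An empty list means the trait set is valid.
    """
    v: list[str] = []

    def req(cond: bool, msg: str) -> None:
        if not cond:
            v.append(msg)

    num_fields = [
        "leaf_area", "height", "basal_diameter", "p50", "vc_slope", "pi0",
        "epsilon", "gs_max", "g_res", "t_p", "q10_a", "q10_b",
        "apoplastic_fraction", "symplast_volume_per_area", "leaf_surface_ratio",
    ]
    for name in num_fields:
        val = getattr(t, name)
        if not isinstance(val, (int, float)) or not math.isfinite(val):
            v.append(f"{name}: must be a finite number, got {val!r}")
    if v:
        return v

    req(t.leaf_area > 0, f"leaf_area: must be > 0, got {t.leaf_area}")
    req(t.height > 0, f"height: must be > 0, got {t.height}")
    req(t.basal_diameter > 0, f"basal_diameter: must be > 0, got {t.basal_diameter}")
    req(t.p50 < 0, f"p50: must be < 0 (tension), got {t.p50}")
    req(t.vc_slope > 0, f"vc_slope: must be > 0, got {t.vc_slope}")
    req(t.pi0 < 0, f"pi0: must be < 0, got {t.pi0}")
    req(t.epsilon > 0, f"epsilon: must be > 0, got {t.epsilon}")
    req(t.g_res > 0, f"g_res: must be > 0, got {t.g_res}")
    req(t.gs_max > t.g_res, f"gs_max: must exceed g_res, got gs_max={t.gs_max} g_res={t.g_res}")
    req(t.q10_a >= 1, f"q10_a: must be >= 1, got {t.q10_a}")
    req(t.q10_b >= 1, f"q10_b: must be >= 1, got {t.q10_b}")
    req(t.t_p > 0, f"t_p: must be > 0 degC, got {t.t_p}")
    req(0 < t.apoplastic_fraction < 1,
        f"apoplastic_fraction: must be in (0,1), got {t.apoplastic_fraction}")
    req(t.symplast_volume_per_area > 0,
        f"symplast_volume_per_area: must be > 0, got {t.symplast_volume_per_area}")
    req(t.leaf_surface_ratio >= 1,
        f"leaf_surface_ratio: must be >= 1, got {t.leaf_surface_ratio}")
    if t.pi0 < 0 and t.epsilon > 0:
        # the derived TLP pi0/(1 + pi0/epsilon) is finite and below pi0 only
        # when the relative content at turgor loss, 1 + pi0/epsilon, is in (0,1)
        req(t.epsilon > -t.pi0,
            f"pi0/epsilon: epsilon ({t.epsilon}) must exceed -pi0 ({-t.pi0}) "
            "for a finite turgor-loss point")
    if t.deciduous:
        req(t.shedding_params is not None,
            "shedding_params: required for deciduous species")
    if t.shedding_params is not None:
        req(t.shedding_params.rate > 0,
            f"shedding_params.rate: must be > 0, got {t.shedding_params.rate}")
        req(t.shedding_params.psi_half < 0,
            f"shedding_params.psi_half: must be < 0, got {t.shedding_params.psi_half}")
    return v


_CSV_COLUMNS = [
    "species_id", "leaf_area", "height", "basal_diameter", "p50", "vc_slope",
    "pi0", "epsilon", "gs_max", "g_res", "t_p", "q10_a", "q10_b",
    "tlp_measured", "p_gs88_measured", "deciduous",
    "shedding_rate", "shedding_psi_half",
    "apoplastic_fraction", "symplast_volume_per_area", "leaf_surface_ratio",
]

_OPTIONAL_DEFAULTS = {
    "apoplastic_fraction": 0.4,
    "symplast_volume_per_area": 0.1,
    "leaf_surface_ratio": 1.0,
}


def _row_to_traits(row: dict[str, str]) -> SpeciesTraits:
    required = ["species_id", "leaf_area", "height", "basal_diameter", "p50",
                "vc_slope", "pi0", "epsilon", "gs_max", "g_res", "t_p",
                "q10_a", "q10_b"]
    missing = [c for c in required if c not in row or row[c] in ("", None)]
    if missing:
        raise TraitValidationError([f"{c}: missing required column/value" for c in missing])
    kw: dict = {"species_id": row["species_id"]}
    bad: list[str] = []
    for c in required[1:]:
        try:
            kw[c] = float(row[c])
        except (TypeError, ValueError):
            bad.append(f"{c}: non-numeric value {row[c]!r}")
    if bad:
        raise TraitValidationError(bad)
    for c in ("tlp_measured", "p_gs88_measured"):
        if row.get(c) not in (None, ""):
            kw[c] = float(row[c])
    for c, default in _OPTIONAL_DEFAULTS.items():
        kw[c] = float(row[c]) if row.get(c) not in (None, "") else default
    deciduous = str(row.get("deciduous", "")).strip().lower() in ("1", "true", "yes")
    kw["deciduous"] = deciduous
    if row.get("shedding_rate") not in (None, "") and row.get("shedding_psi_half") not in (None, ""):
        kw["shedding_params"] = SheddingParams(
            float(row["shedding_rate"]), float(row["shedding_psi_half"]))
    elif deciduous:
        kw["shedding_params"] = SheddingParams()
    t = SpeciesTraits(**kw)
    violations = validate_traits(t)
    if violations:
        raise TraitValidationError(violations)
    return t


def read_traits_csv(path: str | Path) -> dict[str, SpeciesTraits]:
    """Read a traits CSV (one row per species) into a dict keyed by species_id."""
    out: dict[str, SpeciesTraits] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            t = _row_to_traits(row)
            out[t.species_id] = t
    if not out:
        raise TraitValidationError(["CSV contains no species rows"])
    return out


def write_traits_csv(trait_sets: list[SpeciesTraits] | dict[str, SpeciesTraits],
                     path: str | Path) -> None:
    """Write trait sets to CSV using the documented column layout."""
    if isinstance(trait_sets, dict):
        trait_sets = list(trait_sets.values())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        w.writeheader()
        for t in trait_sets:
            row = {c: "" for c in _CSV_COLUMNS}
            for f in fields(t):
                if f.name in row:
                    val = getattr(t, f.name)
                    if val is None:
                        continue
                    row[f.name] = val
            row["deciduous"] = "true" if t.deciduous else "false"
            if t.shedding_params is not None:
                row["shedding_rate"] = t.shedding_params.rate
                row["shedding_psi_half"] = t.shedding_params.psi_half
            w.writerow(row)


def load_species_traits(source: str | Path) -> SpeciesTraits | dict[str, SpeciesTraits]:
    """Load a validated trait set.

    ``source`` is either a builtin species id (``Pin_hale``, ``Pop_nigr``,
    ``Que_ilex``, ``Ced_atla``) returning one :class:`SpeciesTraits`, or a path
    to a traits CSV returning a dict keyed by species id.
    """
    if isinstance(source, str) and source in BUILTIN_SPECIES:
        return BUILTIN_SPECIES[source]
    p = Path(source)
    if p.exists():
        return read_traits_csv(p)
    raise KeyError(
        f"unknown species id or missing file: {source!r}; "
        f"builtin ids are {sorted(BUILTIN_SPECIES)}"
    )
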