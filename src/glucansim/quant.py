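"""Stoichiometric accounting: unit conversions, difference formulas,
inhibition percentages and enzyme-activity arithmetic.

Conventions mirror the tabulated HPLC accounting they reproduce: µg and
nmol are reported to one decimal, percentages to the nearest integer,
and µg→nmol conversion uses integer molar masses (180 g/mol for Glc,
342 for LAM2, 504 for the trimer by-product, 1315 for the hybrid
octamer).  All internal arithmetic is unrounded; rounding happens only
at the reporting edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .glycan import AVERAGE_ANHYDROHEXOSE, AVERAGE_REDUCTION, AVERAGE_WATER, Glycan, molar_mass, species_label
from .pools import ProductPool


class AccountingError(ValueError):
    """Mass bookkeeping produced an impossible (negative) amount."""


def integer_molar_mass(dp: int, reduced: bool = False) -> int:
    """Integer molar mass convention for a hexose oligomer of DP ``dp``:
    round(dp × 162.141 + 18.015 [+ 2.016 if reduced])."""
    if dp < 1:
        raise ValueError(f"DP must be >= 1, got {dp}")
    m = dp * AVERAGE_ANHYDROHEXOSE + AVERAGE_WATER
    if reduced:
        m += AVERAGE_REDUCTION
    return round(m)


def to_nanomoles(mass_ug: float, species_dp: int, reduced: bool = False,
                 exact: bool = False, rounded: bool = True) -> float:
    """Convert µg of a hexose oligomer to nmol.

    Uses the integer molar-mass convention by default (``exact=True``
    switches to unrounded average masses); the result is reported at one
    decimal unless ``rounded=False``.
    """
    if mass_ug < 0:
        raise AccountingError(f"negative mass {mass_ug} µg")
    if exact:
        m: float = species_dp * AVERAGE_ANHYDROHEXOSE + AVERAGE_WATER
        if reduced:
            m += AVERAGE_REDUCTION
    else:
        m = integer_molar_mass(species_dp, reduced)
    nmol = mass_ug / m * 1000.0
    return round(nmol, 1) if rounded else nmol


def infer_hybrid_mass(start_ug: float, lam2_ug: float,
                      rounded: bool = True) -> float:
    """Hybrid-oligosaccharide mass inferred by difference: transfer
    converts substrate into LAM2 plus hybrids, so
    hybrid = start − LAM2 (µg)."""
    out = start_ug - lam2_ug
    if out < 0:
        raise AccountingError(
            f"LAM2 ({lam2_ug} µg) exceeds starting substrate ({start_ug} µg)")
    return round(out, 1) if rounded else out


def infer_byproduct_mass(start_ug: float, lam2_ug: float, glc_ug: float,
                         rounded: bool = True) -> float:
    """By-product X mass inferred by difference after exo digestion of a
    transfer-pretreated pool: X = start − LAM2 − Glc (µg)."""
    out = start_ug - lam2_ug - glc_ug
    if out < 0:
        raise AccountingError(
            f"LAM2 + Glc ({lam2_ug + glc_ug} µg) exceeds starting "
            f"substrate ({start_ug} µg)")
    return round(out, 1) if rounded else out


def percent_reduction(reference: float, treated: float) -> int:
    """Percentage reduction of ``treated`` relative to ``reference``,
    rounded to the nearest integer: (1 − treated/reference) × 100."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return round((1.0 - treated / reference) * 100.0)


@dataclass(frozen=True)
class ActivityMeasurement:
    """One enzyme-activity observation on the linear phase.

    product_umol
        µmol of product (reducing-sugar equivalents or glucose) released.
    time_min
        Incubation time in minutes.
    enzyme_mg
        Enzyme amount in mg.
    """

    product_umol: float
    time_min: float
    enzyme_mg: float

    def __post_init__(self) -> None:
        for name in ("product_umol", "time_min", "enzyme_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def specific_activity(m: ActivityMeasurement) -> float:
    """Specific activity in U/mg (U = µmol product per minute)."""
    return m.product_umol / m.time_min / m.enzyme_mg


def mean_specific_activity(measurements: Iterable[ActivityMeasurement]) -> float:
    """Average of per-timepoint unit values (linear-phase convention)."""
    values = [specific_activity(m) for m in measurements]
    if not values:
        raise ValueError("no measurements supplied")
    return sum(values) / len(values)


def relative_activity(units_x: float, units_opt: float) -> float:
    """Activity at condition x as a percentage of the optimum:
    units_x / units_opt × 100."""
    if units_opt <= 0:
        raise ValueError(f"units_opt must be > 0, got {units_opt}")
    return units_x / units_opt * 100.0


# -- pool quantification ------------------------------------------------

QUANT_COLUMNS = ["species", "label", "dp", "reduced", "nmol", "mass_ug"]


def pool_to_quant_table(pool: ProductPool, nmol_per_count: float = 1.0,
                        rounded: bool = False) -> pd.DataFrame:
    """Tabulate a pool as per-species amounts.

    Molecule counts are scaled to nmol by ``nmol_per_count``; µg follows
    from the exact average molar mass.  ``rounded=True`` applies the
    one-decimal reporting convention.
    """
    rows = []
    for g, n in pool.items():
        nmol = n * nmol_per_count
        ug = nmol * molar_mass(g, "average") / 1000.0
        rows.append({"species": g.canonical, "label": species_label(g),
                     "dp": g.dp, "reduced": g.reduced,
                     "nmol": round(nmol, 1) if rounded else nmol,
                     "mass_ug": round(ug, 1) if rounded else ug})
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def residue_nanomoles(table: pd.DataFrame) -> float:
    """Σ nmol × DP over a quant table — the anhydro-residue total that is
    conserved by any digestion or transfer."""
    if table.empty:
        return 0.0
    return float((table["nmol"] * table["dp"]).sum())
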