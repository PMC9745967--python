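"""Exo-1,3-β-glucanase digestion engine.

Models the sequential release of single glucose units from the
non-reducing ends of 1,3-β-glucans.  A terminal residue is removable iff

1. it bears no substituents (it is a leaf),
2. it is a glucosyl (glucitol ends are inert),
3. its bond to its parent is β1→3, and
4. the maximal run of consecutive β1→3-linked glucosyl residues from it
   toward the root has length >= ``min_run_length`` (default 3 — the
   enzyme needs a minimum of three 1,3-linked units to act).

The rootward run is terminated by a glucitol or by a β1→6 bond; it passes
through backbone residues that merely *bear* a β1→6 branch.  Residues
carrying a 1,6 substituent are themselves never removable (they are not
leaves), which is what leaves branched cores — the uncleavable
"by-product X" class — behind.

Two reporting modes exist for the 5+3 hybrid octamer.  ``rules`` mode
derives products mechanistically: 3 Glc plus one covalently intact
branched DP-5 residual.  ``scheme_mode`` instead applies the inferred
product stoichiometry for that substrate (3 Glc + LAM2 + branched
trimer), which presumes one internal hydrolysis that strict exo chemistry
cannot perform on a connected molecule; both modes are first-class and
the discrepancy is surfaced by the experiment layer, never silently
resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .glycan import (
    GLUCOSYL,
    O3,
    O6,
    Glycan,
    GlycanError,
    MONOISOTOPIC_WATER,
    enumerate_hybrid_isomers,
    make_linear,
    molar_mass,
    parse_glycan,
)
from .pools import ProductPool

_GLC = make_linear(1)
_LAM2 = make_linear(2)
#: Stated by-product X structure: a trimer carrying the β1→6 linkage at
#: its reducing residue; its terminal 1,3-run has length 2, so the exo
#: engine cannot attack it.
BYPRODUCT_X = parse_glycan("Glc(b1-3)Glc(b1-6)Glc")


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a molar ratio has an empty denominator."""


@dataclass(frozen=True)
class ExoRuleConfig:
    """Rewrite-rule parameters of the exo engine.

    min_run_length
        Minimum length of the terminal 1,3-linked glucosyl run required
        for cleavage (>= 2; default 3).
    attack_branch_chains
        When True (default) chains hanging from a β1→6 bond are attacked
        under the same run-length rule, as required for laminarin
        turnover; when False the enzyme acts on the main chain only.
    scheme_mode
        Apply the stated product stoichiometry for 5+3 hybrid octamers
        instead of rule derivation (see module docstring).
    """

    min_run_length: int = 3
    attack_branch_chains: bool = True
    scheme_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be >= 2")


@dataclass(frozen=True)
class TrajectoryStep:
    """One digestion step: the intermediate after ``step`` cleavages and
    the species released by that step (None for the initial state)."""

    step: int
    intermediate: Glycan
    released: Optional[str]


@dataclass
class DigestResult:
    """Products and step record of one complete digestion.

    ``released_glc`` counts glucose set free by cleavage; an undigested
    free Glc substrate appears in ``products`` but not here.
    """

    substrate: Glycan
    products: ProductPool
    trajectory: list[TrajectoryStep]
    n_cleavages: int
    released_glc: int


def _run_length(leaf_path: tuple[int, ...], ancestors: list) -> int:
    """Length of the maximal rootward run of β1→3-linked glucosyl
    residues starting at the leaf (the leaf counts as 1)."""
    run = 1
    for k in range(len(leaf_path) - 1, -1, -1):
        if leaf_path[k] != O3:
            break  # the bond rootward is β1→6
        parent = ancestors[k]
        if parent.kind != GLUCOSYL:
            break  # glucitol terminates the run
        run += 1
    return run


def removable_termini(g: Glycan, cfg: ExoRuleConfig = ExoRuleConfig()) -> list[tuple[int, ...]]:
    """Paths (root-to-leaf acceptor positions) of residues the enzyme can
    remove, sorted lexicographically (the canonical tie-break order)."""
    out = []
    for path, node, ancestors in g.leaves():
        if not path:
            continue  # a lone residue has no glycosidic bond to cleave
        if node.kind != GLUCOSYL:
            continue
        if path[-1] != O3:
            continue  # 1,6-linked termini are never cleaved
        if not cfg.attack_branch_chains and O6 in path:
            continue
        if _run_length(path, ancestors) >= cfg.min_run_length:
            out.append(path)
    return sorted(out)


def _is_53_hybrid(g: Glycan) -> bool:
    """A DP-8 hybrid octamer: linear pentamer backbone with one 1,6-linked
    linear trimer branch, at any backbone position."""
    if g.dp != 8 or g.reduced:
        return False
    return g in set(enumerate_hybrid_isomers(5, 3, model="all_o6"))


def digest(g: Glycan, cfg: ExoRuleConfig = ExoRuleConfig()) -> DigestResult:
    """Digest ``g`` to completion, releasing one Glc per cleavage.

    Rules mode removes the lexicographically smallest removable terminus
    until none remains (the final multiset is order-invariant, so the
    tie-break only fixes the trajectory).  In scheme mode a 5+3 hybrid
    octamer is instead mapped to the stated product table
    3 Glc + LAM2 + branched trimer (4 cleavages).
    """
    if cfg.scheme_mode and _is_53_hybrid(g):
        products = ProductPool()
        products.add(_GLC, 3)
        products.add(_LAM2, 1)
        products.add(BYPRODUCT_X, 1)
        # 4 hydrolyses turn one connected octamer into 5 fragments; the
        # water-corrected mass balance closes exactly with this count.
        trajectory = [TrajectoryStep(0, g, None)]
        return DigestResult(g, products, trajectory, n_cleavages=4,
                            released_glc=3)

    trajectory = [TrajectoryStep(0, g, None)]
    current = g
    n = 0
    while True:
        termini = removable_termini(current, cfg)
        if not termini:
            break
        current = current.without_leaf(termini[0])
        n += 1
        trajectory.append(TrajectoryStep(n, current, "Glc"))
    products = ProductPool()
    if n:
        products.add(_GLC, n)
    products.add(current, 1)
    return DigestResult(g, products, trajectory, n_cleavages=n,
                        released_glc=n)


def digest_pool(pool: ProductPool, cfg: ExoRuleConfig = ExoRuleConfig()) -> tuple[ProductPool, list[DigestResult]]:
    """Digest every molecule of ``pool``; returns the combined product
    pool and one :class:`DigestResult` per substrate species."""
    products = ProductPool()
    results = []
    for g, count in pool.items():
        res = digest(g, cfg)
        results.append(res)
        for p, k in res.products.items():
            products.add(p, k * count)
    return products, results


def glc_lam2_ratio(products: ProductPool) -> float:
    """Molar ratio Glc : LAM2 among ``products``."""
    lam2 = products.count(_LAM2)
    if lam2 == 0:
        raise UndefinedRatioError("product pool contains no LAM2")
    return products.count(_GLC) / lam2


def mass_balance_error(result: DigestResult) -> float:
    """| products − (substrate + n_cleavages × H2O) | in monoisotopic Da.

    Each hydrolysis incorporates one water, so a faithful digest closes
    this balance to numerical precision.
    """
    total = sum(molar_mass(g, "monoisotopic") * n
                for g, n in result.products.items())
    expected = (molar_mass(result.substrate, "monoisotopic")
                + result.n_cleavages * MONOISOTOPIC_WATER)
    return abs(total - expected)
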