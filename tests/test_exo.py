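"""Exo-glucanase engine: removability rules, digestion products,
order-invariance and conservation laws."""

from __future__ import annotations

import itertools
import random

import pytest

from glucansim.exo import (
    BYPRODUCT_X,
    DigestResult,
    ExoRuleConfig,
    UndefinedRatioError,
    digest,
    digest_pool,
    glc_lam2_ratio,
    mass_balance_error,
    removable_termini,
)
from glucansim.glycan import (
    GLUCOSYL,
    Glycan,
    enumerate_hybrid_isomers,
    make_hybrid,
    make_linear,
    parse_glycan,
    species_label,
)
from glucansim.pools import ProductPool, pool_from_counts

from conftest import build_random_glycan


# -- independent oracle -------------------------------------------------
# Re-derives removability from the rule text over the flat bond list and
# explores *every* removal order; used to check both order-invariance and
# the closed-form product laws.

def _oracle_removable(kinds: list[str], parents: dict[int, tuple[int, int]]) -> list[int]:
    children: dict[int, list[int]] = {i: [] for i in range(len(kinds))}
    for child, (parent, _) in parents.items():
        children[parent].append(child)
    out = []
    for i in range(len(kinds)):
        if children[i] or kinds[i] is None or kinds[i] != GLUCOSYL:
            continue
        if i not in parents or parents[i][1] != 3:
            continue
        run, node = 1, i
        while node in parents and parents[node][1] == 3 \
                and kinds[parents[node][0]] == GLUCOSYL:
            node = parents[node][0]
            run += 1
        if run >= 3:
            out.append(i)
    return out


def _oracle_outcomes(g: Glycan) -> set[tuple[int, str]]:
    """All (n released Glc, residual canonical) outcomes over every
    possible removal order."""
    kinds = [k for _, k in g.residues()]
    parents = {c: (p, pos) for c, p, pos in g.bonds()}

    def residual_canonical(kind_state: list) -> str:
        alive = [i for i, k in enumerate(kind_state) if k is not None]
        remap = {old: new for new, old in enumerate(alive)}
        bonds = [(remap[c], remap[p], pos) for c, (p, pos) in parents.items()
                 if kind_state[c] is not None]
        return Glycan.from_bonds([kind_state[i] for i in alive], bonds).canonical

    outcomes: set[tuple[int, str]] = set()
    seen: set[frozenset] = set()

    def explore(kind_state: list, removed: int) -> None:
        alive = frozenset(i for i, k in enumerate(kind_state) if k is not None)
        if alive in seen:
            return
        seen.add(alive)
        choices = _oracle_removable(kind_state, {c: v for c, v in parents.items()
                                                 if kind_state[c] is not None})
        if not choices:
            outcomes.add((removed, residual_canonical(kind_state)))
            return
        for i in choices:
            nxt = list(kind_state)
            nxt[i] = None
            explore(nxt, removed + 1)

    explore(list(kinds), 0)
    return outcomes


# -- removability -------------------------------------------------------

class TestRemovableTermini:
    @pytest.mark.parametrize("substrate, n_removable", [
        ("Glc", 0),
        ("LAM2", 0),          # run of 2 < minimum of three units
        ("LAM3", 1),
        ("LAM3ol", 0),        # glucitol terminates the run at length 2
        ("LAM4ol", 1),
        ("Glc(b1-6)Glc(b1-3)Glc", 0),   # 1,6-linked terminus is inert
    ])
    def test_examples(self, substrate, n_removable):
        g = parse_glycan(substrate)
        assert len(removable_termini(g)) == n_removable

    def test_min_run_length_validated(self):
        with pytest.raises(ValueError):
            ExoRuleConfig(min_run_length=1)

    def test_branch_chain_attack_switch(self):
        # H8 carries a removable trimer-branch terminus only when branch
        # chains may be attacked.
        h8 = parse_glycan("H8")
        on = removable_termini(h8, ExoRuleConfig(attack_branch_chains=True))
        off = removable_termini(h8, ExoRuleConfig(attack_branch_chains=False))
        assert any(6 in path for path in on)
        assert all(6 not in path for path in off)


# -- digestion ----------------------------------------------------------

class TestDigest:
    def test_lam5_products(self):
        result = digest(make_linear(5))
        assert result.products.label_counts() == {"Glc": 3, "LAM2": 1}
        assert glc_lam2_ratio(result.products) == 3.0

    def test_lam5ol_trajectory(self):
        result = digest(parse_glycan("LAM5ol"))
        assert result.products.label_counts() == {"Glc": 2, "LAM3ol": 1}
        labels = [species_label(s.intermediate) for s in result.trajectory]
        assert labels == ["LAM5ol", "LAM4ol", "LAM3ol"]

    @pytest.mark.parametrize("n", range(3, 13))
    def test_linear_closed_form_vs_oracle(self, n):
        # LAMn -> (n-2) Glc + LAM2, and the oracle agrees over all orders
        result = digest(make_linear(n))
        assert result.products.label_counts() == {"Glc": n - 2, "LAM2": 1}
        assert _oracle_outcomes(make_linear(n)) == {
            (n - 2, make_linear(2).canonical)}

    @pytest.mark.parametrize("n", range(4, 13))
    def test_reduced_closed_form_vs_oracle(self, n):
        result = digest(make_linear(n, reduced=True))
        assert result.products.label_counts() == {"Glc": n - 3, "LAM3ol": 1}
        assert _oracle_outcomes(make_linear(n, reduced=True)) == {
            (n - 3, make_linear(3, reduced=True).canonical)}

    def test_default_hybrid_octamer_rules_products(self):
        # the attachment geometry that reproduces the observed 3 Glc per
        # octamer: branched DP-5 residual stays covalently intact
        result = digest(parse_glycan("H8"))
        assert result.released_glc == 3
        residual = [g for g, _ in result.products.items() if g.dp > 1]
        assert len(residual) == 1 and residual[0].dp == 5
        assert residual[0].has_o6_bond

    def test_scheme_mode_applies_stated_stoichiometry(self):
        for iso in enumerate_hybrid_isomers(5, 3):
            result = digest(iso, ExoRuleConfig(scheme_mode=True))
            assert result.products.label_counts() == {
                "Glc": 3, "LAM2": 1, "X": 1}
            assert result.products.count(BYPRODUCT_X) == 1
            assert mass_balance_error(result) < 1e-9

    def test_scheme_mode_falls_back_to_rules_elsewhere(self):
        cfg = ExoRuleConfig(scheme_mode=True)
        assert digest(make_linear(5), cfg).products.label_counts() == {
            "Glc": 3, "LAM2": 1}

    def test_exo_signature_on_reduced_substrates(self):
        # every reducing-sugar product is a released Glc: the residuals
        # of LAMnol substrates are all reduced
        for n in range(4, 9):
            result = digest(make_linear(n, reduced=True))
            for g, _ in result.products.items():
                assert g.reduced or g.dp == 1


class TestInvariantsOnRandomStructures:
    def test_order_invariance_exhaustive(self, rng):
        # every removal order reaches the same final multiset
        cases = [make_linear(6), make_linear(7, reduced=True),
                 *enumerate_hybrid_isomers(5, 3, "all_o6"),
                 make_hybrid(4, {2: 2, 4: 2}),
                 parse_glycan("Glc(b1-3)Glc(b1-3)Glc(b1-6)Glc(b1-3)Glc(b1-3)Glc")]
        cases += [build_random_glycan(rng, max_dp=8) for _ in range(30)]
        for g in cases:
            outcomes = _oracle_outcomes(g)
            assert len(outcomes) == 1, f"order-dependent digest of {g}"
            result = digest(g)
            (n_removed, residual), = outcomes
            assert result.released_glc == n_removed
            assert result.products.count(parse_glycan(residual)) >= 1

    def test_residue_and_mass_conservation(self, rng):
        for _ in range(200):
            g = build_random_glycan(rng, max_dp=10)
            result = digest(g)
            assert result.products.total_residues == g.dp
            assert mass_balance_error(result) < 1e-9

    def test_hybrid_recalcitrance(self):
        # no DP-8 hybrid isomer releases more Glc than linear LAM8
        linear_yield = digest(make_linear(8)).released_glc
        assert linear_yield == 6
        for iso in enumerate_hybrid_isomers(5, 3):
            assert digest(iso).released_glc <= linear_yield


class TestRatioAndPools:
    def test_ratio_undefined_without_lam2(self):
        with pytest.raises(UndefinedRatioError):
            glc_lam2_ratio(digest(parse_glycan("LAM5ol")).products)

    def test_equal_moles_ratio_one(self):
        pool = pool_from_counts({"Glc": 4, "LAM2": 4})
        assert glc_lam2_ratio(pool) == 1.0

    def test_digest_pool_aggregates_counts(self):
        pool = pool_from_counts({"LAM5": 2, "LAM6": 1})
        products, results = digest_pool(pool)
        assert products.label_counts() == {"Glc": 2 * 3 + 4, "LAM2": 3}
        assert len(results) == 2
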