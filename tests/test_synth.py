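"""Synthetic-data generator: determinism, edge fractions, noise model
and parameter recovery through the accounting layer."""

from __future__ import annotations

import numpy as np
import pytest

from glucansim.exo import digest_pool
from glucansim.glycan import make_linear, molar_mass
from glucansim.pools import pool_from_counts
from glucansim.quant import infer_byproduct_mass, infer_hybrid_mass
from glucansim.synth import (
    GeneratorConfig,
    gen_laminarin_pool,
    gen_peak_list,
    gen_quant_table,
    gen_substrate_pool,
    write_fixtures,
)


class TestConfigValidation:
    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            GeneratorConfig(lam5_contamination_fraction=1.5)

    def test_bad_noise(self):
        with pytest.raises(ValueError):
            GeneratorConfig(quant_noise_sd=-0.1)

    def test_bad_mean_dp(self):
        with pytest.raises(ValueError):
            GeneratorConfig(laminarin_mean_dp=3)


class TestSubstratePool:
    def test_pure_pool_edges(self):
        cfg0 = GeneratorConfig(lam5_contamination_fraction=0.0, pool_size=50)
        assert gen_substrate_pool(cfg0).label_counts() == {"LAM5": 50}
        cfg1 = GeneratorConfig(lam5_contamination_fraction=1.0, pool_size=50)
        assert gen_substrate_pool(cfg1).label_counts() == {"LAM6": 50}

    def test_seeded_split_reproducible(self):
        cfg = GeneratorConfig(seed=9, pool_size=1000,
                              lam5_contamination_fraction=0.05)
        p1, p2 = gen_substrate_pool(cfg), gen_substrate_pool(cfg)
        assert p1 == p2
        counts = p1.label_counts()
        assert counts["LAM5"] + counts["LAM6"] == 1000
        assert 20 <= counts["LAM6"] <= 80  # ~5% of 1000


class TestLaminarinPool:
    def test_unbranched_reduces_to_linear_closed_form(self):
        cfg = GeneratorConfig(seed=2, laminarin_branch_prob=0.0, pool_size=40)
        pool = gen_laminarin_pool(cfg)
        products, _ = digest_pool(pool)
        labels = set(products.label_counts())
        assert labels == {"Glc", "LAM2"}

    def test_chain_dps_truncated_at_five(self):
        cfg = GeneratorConfig(seed=3, laminarin_mean_dp=6, pool_size=60)
        pool = gen_laminarin_pool(cfg)
        assert min(g.dp for g, _ in pool.items()) >= 5

    def test_mean_dp_5_unbranched_is_lam5_like(self):
        cfg = GeneratorConfig(seed=4, laminarin_mean_dp=5,
                              laminarin_branch_prob=0.0, pool_size=30)
        pool = gen_laminarin_pool(cfg)
        assert all(g.is_linear_13 for g, _ in pool.items())

    def test_branch_probability_controls_branching(self):
        cfg = GeneratorConfig(seed=5, laminarin_branch_prob=0.5, pool_size=30)
        pool = gen_laminarin_pool(cfg)
        assert any(g.has_o6_bond for g, _ in pool.items())

    def test_seed_determinism(self):
        cfg = GeneratorConfig(seed=6)
        assert gen_laminarin_pool(cfg) == gen_laminarin_pool(cfg)


class TestQuantTable:
    def test_zero_noise_equals_truth(self):
        pool = pool_from_counts({"Glc": 3, "LAM2": 2})
        cfg = GeneratorConfig(seed=0, quant_noise_sd=0.0, nmol_per_molecule=4.0)
        table = gen_quant_table(pool, cfg)
        truth = {"Glc": 3 * 4.0 * molar_mass(make_linear(1), "average") / 1000,
                 "LAM2": 2 * 4.0 * molar_mass(make_linear(2), "average") / 1000}
        for row in table.itertuples():
            assert row.mass_ug == pytest.approx(truth[row.label], abs=0.05)
            assert row.sd_ug == 0.0

    def test_empty_pool_empty_table(self):
        from glucansim.pools import ProductPool
        table = gen_quant_table(ProductPool(), GeneratorConfig())
        assert table.empty

    def test_noisy_table_reproducible(self):
        pool = pool_from_counts({"Glc": 6, "LAM2": 2, "H8": 1})
        cfg = GeneratorConfig(seed=12, nmol_per_molecule=2.0)
        t1 = gen_quant_table(pool, cfg)
        t2 = gen_quant_table(pool, cfg)
        assert t1.equals(t2)

    def test_parameter_recovery_within_three_sd(self):
        # simulate the pretreatment experiment, measure with noise,
        # recover hybrid and by-product masses by the difference formulas;
        # the reference is the zero-noise inference (the formulas share
        # the field convention of neglecting water of hydrolysis)
        from glucansim.exo import ExoRuleConfig
        from glucansim.transfer import react_batch

        scale = 6.17  # nmol per molecule: 2 molecules ~ 12.34 nmol LAM5
        start = pool_from_counts({"LAM5": 2})
        start_ug = 2 * scale * molar_mass(make_linear(5), "average") / 1000

        def measured(table, label):
            return float(table.loc[table.label == label, "mass_ug"].iloc[0])

        noisy = GeneratorConfig(seed=21, quant_noise_sd=0.1,
                                nmol_per_molecule=scale)
        clean = GeneratorConfig(seed=21, quant_noise_sd=0.0,
                                nmol_per_molecule=scale)

        pretreated, _ = react_batch(start)
        est_hybrid = infer_hybrid_mass(
            start_ug, measured(gen_quant_table(pretreated, noisy), "LAM2"),
            rounded=False)
        ref_hybrid = infer_hybrid_mass(
            start_ug, measured(gen_quant_table(pretreated, clean), "LAM2"),
            rounded=False)
        assert abs(est_hybrid - ref_hybrid) <= 3 * noisy.quant_noise_sd

        digested, _ = digest_pool(pretreated, ExoRuleConfig(scheme_mode=True))
        t_noisy = gen_quant_table(digested, noisy)
        t_clean = gen_quant_table(digested, clean)
        est_x = infer_byproduct_mass(start_ug, measured(t_noisy, "LAM2"),
                                     measured(t_noisy, "Glc"), rounded=False)
        ref_x = infer_byproduct_mass(start_ug, measured(t_clean, "LAM2"),
                                     measured(t_clean, "Glc"), rounded=False)
        # two measured terms: allow 3 sd on each
        assert abs(est_x - ref_x) <= 3 * np.sqrt(2) * noisy.quant_noise_sd


class TestPeakListAndFixtures:
    def test_peak_jitter_within_tolerance(self):
        pool = pool_from_counts({"LAM5": 4, "H8": 2})
        cfg = GeneratorConfig(seed=8, mz_noise_sd=0.05)
        noisy = gen_peak_list(pool, cfg)
        from glucansim.ms import predict_peaks
        clean = predict_peaks(pool)
        for n, c in zip(noisy, clean):
            assert abs(n.mz - c.mz) < 0.5

    def test_write_fixtures_files(self, tmp_path):
        cfg = GeneratorConfig(seed=13, pool_size=100)
        paths = write_fixtures(tmp_path, cfg)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        again = tmp_path / "again"
        paths2 = write_fixtures(again, cfg)
        assert paths["pool"].read_text() == paths2["pool"].read_text()
        assert paths["quant"].read_text() == paths2["quant"].read_text()
        assert paths["peaks"].read_text() == paths2["peaks"].read_text()
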