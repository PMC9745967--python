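"""Synthetic fixtures: contaminated substrate pools, laminarin-like
polymer ensembles, noisy quantification tables and noisy peak lists.

The generator emulates the measurement layer of the wet experiments it
stands in for: commercial LAM5 carrying a LAM6 contaminant, storage
laminarin as mostly-1,3 chains with sparse single-glucose 1,6 stubs, and
HPLC quantification with small homoscedastic gaussian error on µg read
in triplicate.  Every draw goes through one ``numpy.random.default_rng``
seeded from the config, so a fixed seed yields bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glycan import Glycan, make_linear, molar_mass, species_label
from .ms import Peak, predict_peaks
from .pools import ProductPool
from .quant import to_nanomoles


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the fixture generator.

    seed
        RNG seed; fixed seed ⇒ bit-identical output.
    lam5_contamination_fraction
        Fraction of LAM6 in a nominal LAM5 pool (default 0.05).
    quant_noise_sd
        Gaussian sd on measured µg (default 0.1, the scale of
        triplicate HPLC scatter).
    mz_noise_sd
        Gaussian sd on observed m/z in Da (default 0.05).
    laminarin_mean_dp
        Mean chain length of the laminarin ensemble (Poisson, truncated
        at DP >= 5; default 25).
    laminarin_branch_prob
        Per-internal-residue probability of a 1,6 branch (default 0.07).
    laminarin_branch_dp
        Branch stub length (default 1, single glucose).
    pool_size
        Molecules per generated pool (default 200).
    nmol_per_molecule
        Mole scale mapping pool counts to nmol in quant tables.
    """

    seed: int = 0
    lam5_contamination_fraction: float = 0.05
    quant_noise_sd: float = 0.1
    mz_noise_sd: float = 0.05
    laminarin_mean_dp: int = 25
    laminarin_branch_prob: float = 0.07
    laminarin_branch_dp: int = 1
    pool_size: int = 200
    nmol_per_molecule: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lam5_contamination_fraction", "laminarin_branch_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("quant_noise_sd", "mz_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.laminarin_mean_dp < 5:
            raise ValueError("laminarin_mean_dp must be >= 5")
        if self.laminarin_branch_dp < 1:
            raise ValueError("laminarin_branch_dp must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_substrate_pool(cfg: GeneratorConfig) -> ProductPool:
    """Nominal LAM5 pool with a multinomial LAM6 contaminant split."""
    rng = cfg.rng()
    f = cfg.lam5_contamination_fraction
    n5, n6 = rng.multinomial(cfg.pool_size, [1.0 - f, f])
    pool = ProductPool()
    if n5:
        pool.add(make_linear(5), int(n5))
    if n6:
        pool.add(make_linear(6), int(n6))
    return pool


def _laminarin_chain(rng: np.random.Generator, cfg: GeneratorConfig) -> Glycan:
    dp = 0
    while dp < 5:  # truncated Poisson: resample short chains
        dp = int(rng.poisson(cfg.laminarin_mean_dp))
    g = make_linear(dp)
    # internal residues: everything between root and non-reducing terminus
    for position in range(2, dp):
        if rng.random() < cfg.laminarin_branch_prob:
            g = g.with_o6_branch(position, make_linear(cfg.laminarin_branch_dp))
    return g


def gen_laminarin_pool(cfg: GeneratorConfig) -> ProductPool:
    """Laminarin-like ensemble: 1,3 chains (Poisson DP, >= 5) with sparse
    independent 1,6 stubs on internal residues."""
    rng = cfg.rng()
    pool = ProductPool()
    for _ in range(cfg.pool_size):
        pool.add(_laminarin_chain(rng, cfg))
    return pool


QUANT_FIXTURE_COLUMNS = ["species", "label", "dp", "reduced",
                         "mass_ug", "sd_ug", "nmol", "sd_nmol"]


def gen_quant_table(true_pool: ProductPool, cfg: GeneratorConfig,
                    n_replicates: int = 3) -> pd.DataFrame:
    """Noisy quantification table for ``true_pool``.

    True µg per species follow from counts × ``nmol_per_molecule`` and
    exact average masses; measured values are the mean of
    ``n_replicates`` gaussian draws (sd ``quant_noise_sd``, truncated at
    0), reported at one decimal with the replicate sd alongside.  nmol
    derive from the *unrounded* measured mean via integer molar masses.
    """
    rng = cfg.rng()
    rows = []
    for g, count in true_pool.items():
        true_ug = count * cfg.nmol_per_molecule * molar_mass(g, "average") / 1000.0
        reps = rng.normal(true_ug, cfg.quant_noise_sd, n_replicates).clip(min=0.0)
        mean_ug = float(reps.mean())
        sd_ug = float(reps.std(ddof=1)) if n_replicates > 1 else 0.0
        rows.append({
            "species": g.canonical, "label": species_label(g),
            "dp": g.dp, "reduced": g.reduced,
            "mass_ug": round(mean_ug, 1), "sd_ug": round(sd_ug, 1),
            "nmol": to_nanomoles(mean_ug, g.dp, g.reduced),
            "sd_nmol": round(to_nanomoles(sd_ug, g.dp, g.reduced,
                                          rounded=False), 1),
        })
    return pd.DataFrame(rows, columns=QUANT_FIXTURE_COLUMNS)


def gen_peak_list(pool: ProductPool, cfg: GeneratorConfig) -> list[Peak]:
    """Predicted peaks of ``pool`` with gaussian m/z jitter applied."""
    rng = cfg.rng()
    out = []
    for p in predict_peaks(pool):
        mz = float(p.mz + rng.normal(0.0, cfg.mz_noise_sd))
        out.append(Peak(mz=mz, intensity=p.intensity, annotation=p.annotation))
    return sorted(out, key=lambda p: p.mz)


def write_fixtures(out_dir, cfg: GeneratorConfig) -> dict[str, Path]:
    """Write pool CSV, quant CSV and peaks TSV fixtures under ``out_dir``.

    The substrate pool (with contaminant) seeds both the quant table and
    the peak list, so the three files describe one consistent sample.
    """
    from .ms import write_peaks  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool = gen_substrate_pool(cfg)
    paths = {
        "pool": out / "pool.csv",
        "quant": out / "quant.csv",
        "peaks": out / "peaks.tsv",
    }
    pool.to_frame().to_csv(paths["pool"], index=False)
    gen_quant_table(pool, cfg).to_csv(paths["quant"], index=False)
    write_peaks(gen_peak_list(pool, cfg), paths["peaks"])
    return paths
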