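"""MALDI-style peak prediction and +DP3 series detection.

Peaks are singly sodiated monoisotopic centroids ([M+Na]+) of neutral
hexose oligomers; intensities are relative pool abundances.  A +DP3
series — the diagnostic signature of iterative trisaccharide transfer —
is a maximal arithmetic run of peaks spaced by three anhydrohexose
masses (486.158 Da).  Peak lists here are tens of entries, so detection
is exhaustive subsequence search, not a heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .glycan import (
    DP3_MASS_SPACING,
    MONOISOTOPIC_ANHYDROHEXOSE,
    MONOISOTOPIC_REDUCTION,
    MONOISOTOPIC_SODIUM,
    MONOISOTOPIC_WATER,
    mz_sodiated,
    species_label,
)
from .pools import ProductPool

#: Default match tolerance (Da): externally calibrated MALDI-TOF scale.
DEFAULT_TOLERANCE = 0.5


@dataclass(frozen=True)
class Peak:
    """One centroid: m/z (Da), relative intensity, optional species label."""

    mz: float
    intensity: float
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class SeriesMatch:
    """A maximal +DP3 arithmetic run of peaks.

    ``start_dp`` is the hexose DP nearest the first member's neutral
    mass; ``spacing`` is the mean consecutive m/z difference.
    """

    member_peaks: tuple[Peak, ...]
    spacing: float
    start_dp: int

    @property
    def n_members(self) -> int:
        return len(self.member_peaks)


def predict_peaks(pool: ProductPool) -> list[Peak]:
    """One [M+Na]+ peak per distinct (DP, reduction state) in ``pool``,
    intensity proportional to abundance (base peak = 100)."""
    groups: dict[tuple[int, bool], dict] = {}
    for g, n in pool.items():
        key = (g.dp, g.reduced)
        entry = groups.setdefault(key, {"mz": mz_sodiated(g), "count": 0,
                                        "labels": set()})
        entry["count"] += n
        entry["labels"].add(species_label(g))
    if not groups:
        return []
    top = max(e["count"] for e in groups.values())
    peaks = [Peak(mz=e["mz"], intensity=100.0 * e["count"] / top,
                  annotation="/".join(sorted(e["labels"])))
             for e in groups.values()]
    return sorted(peaks, key=lambda p: p.mz)


def nearest_hexose_dp(mz: float, reduced: bool = False) -> int:
    """Hexose-oligomer DP whose [M+Na]+ lies nearest ``mz``."""
    neutral = mz - MONOISOTOPIC_SODIUM - MONOISOTOPIC_WATER
    if reduced:
        neutral -= MONOISOTOPIC_REDUCTION
    return max(1, round(neutral / MONOISOTOPIC_ANHYDROHEXOSE))


def detect_dp3_series(peaks: Iterable[Peak], tol: float = DEFAULT_TOLERANCE,
                      min_members: int = 3) -> list[SeriesMatch]:
    """All maximal arithmetic subsequences spaced by 486.158 ± ``tol`` Da.

    Detection ignores intensities and input order.  Runs shorter than
    ``min_members`` are discarded (two peaks a coincidental 3-hexose
    apart are not evidence of iterative transfer).
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    pts = sorted(peaks, key=lambda p: (p.mz, -p.intensity))
    n = len(pts)
    succ: dict[int, list[int]] = {
        i: [j for j in range(i + 1, n)
            if abs(pts[j].mz - pts[i].mz - DP3_MASS_SPACING) <= tol]
        for i in range(n)
    }
    has_pred = {j for nexts in succ.values() for j in nexts}

    chains: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        nexts = succ[path[-1]]
        if not nexts:
            chains.append(tuple(path))
            return
        for j in nexts:
            extend(path + [j])

    for i in range(n):
        if i not in has_pred and succ[i]:
            extend([i])

    out = []
    seen: set[tuple[int, ...]] = set()
    for chain in chains:
        if len(chain) < min_members or chain in seen:
            continue
        seen.add(chain)
        members = tuple(pts[i] for i in chain)
        diffs = [b.mz - a.mz for a, b in zip(members, members[1:])]
        out.append(SeriesMatch(
            member_peaks=members,
            spacing=sum(diffs) / len(diffs),
            start_dp=nearest_hexose_dp(members[0].mz),
        ))
    return sorted(out, key=lambda s: (s.start_dp, -s.n_members))


# -- TSV I/O ------------------------------------------------------------

def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mz": p.mz, "intensity": p.intensity, "annotation": p.annotation}
         for p in peaks],
        columns=["mz", "intensity", "annotation"])


def write_peaks(peaks: Sequence[Peak], path) -> None:
    """Write a peak list as TSV (columns mz, intensity, annotation)."""
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[Peak]:
    """Read a TSV peak list; an annotation column is optional."""
    df = pd.read_csv(path, sep="\t")
    if "mz" not in df.columns or "intensity" not in df.columns:
        raise ValueError("peak list needs 'mz' and 'intensity' columns")
    has_ann = "annotation" in df.columns
    return [Peak(mz=float(r.mz), intensity=float(r.intensity),
                 annotation=(str(r.annotation)
                             if has_ann and pd.notna(r.annotation) else None))
            for r in df.itertuples()]
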