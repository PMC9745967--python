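"""Multisets of glycan species with per-species molecule counts."""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Mapping, Optional, Union

import pandas as pd

from .glycan import Glycan, parse_glycan, species_label


class ProductPool:
    """Multiset of :class:`Glycan` species.

    Counts are molecule (or, equivalently, relative mole) numbers; the
    quantification layer converts them to µg/nmol when a mole scale is
    supplied.
    """

    def __init__(self, items: Union[Mapping[Glycan, int], Iterable[Glycan], None] = None) -> None:
        self._counts: dict[Glycan, int] = {}
        if isinstance(items, Mapping):
            for g, n in items.items():
                self.add(g, n)
        elif items is not None:
            for g in items:
                self.add(g)

    @classmethod
    def from_spec(cls, text: str) -> "ProductPool":
        """Parse a pool description such as ``"2xLAM5"`` or
        ``"2xLAM5, 1xH8"`` (``count x species``; bare species count once).
        """
        pool = cls()
        for part in re.split(r"[,+]", text):
            part = part.strip()
            if not part:
                continue
            m = re.fullmatch(r"(?:(\d+)\s*[xX]\s*)?(\S+)", part)
            if m is None:
                raise ValueError(f"cannot parse pool entry {part!r}")
            pool.add(parse_glycan(m.group(2)), int(m.group(1) or 1))
        return pool

    # -- mutation -------------------------------------------------------

    def add(self, g: Glycan, n: int = 1) -> None:
        if n < 0:
            raise ValueError("count must be non-negative")
        if n:
            self._counts[g] = self._counts.get(g, 0) + n

    def remove(self, g: Glycan, n: int = 1) -> None:
        have = self._counts.get(g, 0)
        if have < n:
            raise ValueError(f"pool holds {have} x {g}, cannot remove {n}")
        if have == n:
            del self._counts[g]
        else:
            self._counts[g] = have - n

    # -- queries --------------------------------------------------------

    def count(self, g: Glycan) -> int:
        return self._counts.get(g, 0)

    def species(self) -> list[Glycan]:
        return sorted(self._counts, key=lambda g: (g.dp, g.canonical))

    def items(self) -> Iterator[tuple[Glycan, int]]:
        for g in self.species():
            yield g, self._counts[g]

    @property
    def total_molecules(self) -> int:
        return sum(self._counts.values())

    @property
    def total_residues(self) -> int:
        return sum(g.dp * n for g, n in self._counts.items())

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g, n in self.items():
            lbl = species_label(g)
            out[lbl] = out.get(lbl, 0) + n
        return out

    def copy(self) -> "ProductPool":
        return ProductPool(self._counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species": g.canonical, "label": species_label(g),
                 "dp": g.dp, "reduced": g.reduced, "count": n}
                for g, n in self.items()]
        return pd.DataFrame(rows, columns=["species", "label", "dp",
                                           "reduced", "count"])

    # -- dunder ---------------------------------------------------------

    def __contains__(self, g: Glycan) -> bool:
        return g in self._counts

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other: object):
        if not isinstance(other, ProductPool):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}x{species_label(g)}" for g, n in self.items())
        return f"ProductPool({inner})"


def pool_from_counts(counts: Mapping[str, int]) -> ProductPool:
    """Build a pool from ``{glycan string or alias: count}``."""
    pool = ProductPool()
    for name, n in counts.items():
        pool.add(parse_glycan(name), n)
    return pool
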