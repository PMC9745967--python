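"""1,3-β-transglucanase (branching) engine.

Models the DP-dependent cleave-and-transfer reaction: a linear all-1,3
donor of DP X >= 5 is cleaved after the second glucosyl from the reducing
end, releasing laminaribiose (LAM2); the retained DP X−2 fragment is then
transferred onto an acceptor through one new β1→6 bond, extending the
acceptor by X−2 residues.  Iterated on a LAM5 pool this yields the +DP3
product ladder LAM5 → H8 → H11 → H14 (and LAM6 → H9 → H12 for a
contaminant hexamer).

Attachment models
-----------------
``near_terminal`` (default) draws the acceptor O6 from the three backbone
positions nearest the non-reducing end, innermost position first — the
placement whose subsequent exo digestion releases three glucose units per
hybrid octamer, as observed.  ``all_o6`` allows every free backbone O6,
preferring positions nearest the non-reducing end.

Hybrids act as acceptors but never as donors: transfer only ever
lengthens branched products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .glycan import (
    ATTACH_ALL_O6,
    ATTACH_NEAR_TERMINAL,
    Glycan,
    GlycanError,
    make_linear,
)
from .pools import ProductPool

_LAM2 = make_linear(2)


class SubstrateError(GlycanError):
    """Donor or acceptor not accepted by the enzyme model."""


@dataclass(frozen=True)
class ReactionConfig:
    """Transfer-reaction parameters.

    min_donor_dp
        Smallest linear 1,3 oligomer accepted as donor (default 5).
    attachment_model
        ``near_terminal`` or ``all_o6`` (see module docstring).
    mode
        ``exhaustive`` — one deterministic transfer per round, preferring
        the largest hybrid as acceptor; ``stochastic`` — donor, acceptor
        and attachment position are sampled under ``seed``.
    rounds
        Number of reaction rounds for :func:`react_batch`.
    seed
        RNG seed for stochastic mode (ignored in exhaustive mode).
    """

    min_donor_dp: int = 5
    attachment_model: str = ATTACH_NEAR_TERMINAL
    mode: str = "exhaustive"
    rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_donor_dp < 2:
            raise ValueError("min_donor_dp must be >= 2")
        if self.attachment_model not in (ATTACH_NEAR_TERMINAL, ATTACH_ALL_O6):
            raise ValueError(
                f"unknown attachment model {self.attachment_model!r}")
        if self.mode not in ("exhaustive", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class TransferEvent:
    """One cleave-and-transfer event.

    Residues are conserved exactly: donor DP + acceptor DP equals
    released DP (always 2) + product DP.
    """

    donor: Glycan
    acceptor: Glycan
    released: Glycan
    product: Glycan
    attachment_position: int


def is_donor_substrate(g: Glycan, cfg: ReactionConfig = ReactionConfig()) -> bool:
    """True iff ``g`` is a linear, all-β1→3, non-reduced oligomer with
    DP >= ``cfg.min_donor_dp``."""
    return g.is_linear_13 and not g.reduced and g.dp >= cfg.min_donor_dp


def is_acceptor_substrate(g: Glycan, cfg: ReactionConfig = ReactionConfig()) -> bool:
    """Acceptors are donor-eligible oligomers or previously formed
    (1,6-containing, non-reduced) hybrids."""
    return is_donor_substrate(g, cfg) or (g.has_o6_bond and not g.reduced)


def _attachment_positions(acceptor: Glycan, cfg: ReactionConfig) -> list[int]:
    """Free backbone O6 positions in preference order (innermost of the
    three near-terminal positions first, then outward / rootward)."""
    backbone_len = len(acceptor.backbone())
    near = [p for p in (backbone_len - 2, backbone_len - 1, backbone_len)
            if p >= 1]
    order = list(near)
    if cfg.attachment_model == ATTACH_ALL_O6:
        order += [p for p in range(backbone_len - 3, 0, -1)]
    free = set(acceptor.free_o6_backbone_positions())
    return [p for p in order if p in free]


def transglycosylate(donor: Glycan, acceptor: Glycan,
                     cfg: ReactionConfig = ReactionConfig(),
                     position: Optional[int] = None) -> TransferEvent:
    """Apply one cleave-and-transfer event.

    The donor is split after the 2nd glucosyl from the reducing end
    (releasing LAM2); the DP−2 remainder is attached to ``acceptor`` at
    ``position`` (default: first free position of the attachment model).
    """
    if not is_donor_substrate(donor, cfg):
        raise SubstrateError(
            f"{donor} is not a donor (need linear 1,3, non-reduced, "
            f"DP >= {cfg.min_donor_dp})")
    if not is_acceptor_substrate(acceptor, cfg):
        raise SubstrateError(f"{acceptor} is not an acceptor")
    candidates = _attachment_positions(acceptor, cfg)
    if not candidates:
        raise SubstrateError(
            f"{acceptor} has no free O6 under model {cfg.attachment_model!r}")
    if position is None:
        position = candidates[0]
    elif position not in candidates:
        raise SubstrateError(
            f"position {position} not free/eligible on {acceptor}")
    fragment_dp = donor.dp - 2
    product = acceptor.with_o6_branch(position, make_linear(fragment_dp))
    return TransferEvent(donor=donor, acceptor=acceptor, released=_LAM2,
                         product=product, attachment_position=position)


def _apply(pool: ProductPool, event: TransferEvent) -> None:
    pool.remove(event.donor)
    pool.remove(event.acceptor)
    pool.add(event.released)
    pool.add(event.product)


def _pick_exhaustive(pool: ProductPool, cfg: ReactionConfig) -> Optional[tuple[Glycan, Glycan]]:
    donors = [g for g, _ in pool.items() if is_donor_substrate(g, cfg)]
    if not donors:
        return None
    donor = donors[0]  # smallest DP, canonical order
    hybrids = sorted((g for g, _ in pool.items()
                      if g.has_o6_bond and not g.reduced
                      and _attachment_positions(g, cfg)),
                     key=lambda g: (-g.dp, g.canonical))
    if hybrids:
        return donor, hybrids[0]
    if pool.count(donor) >= 2:
        return donor, donor
    if len(donors) >= 2:
        return donor, donors[1]
    return None


def _pick_stochastic(pool: ProductPool, cfg: ReactionConfig,
                     rng: np.random.Generator) -> Optional[tuple[Glycan, Glycan, int]]:
    donors = [(g, n) for g, n in pool.items() if is_donor_substrate(g, cfg)]
    if not donors:
        return None
    weights = np.array([n for _, n in donors], dtype=float)
    donor = donors[rng.choice(len(donors), p=weights / weights.sum())][0]
    acceptors = []
    for g, n in pool.items():
        if g == donor:
            n -= 1
        if n > 0 and is_acceptor_substrate(g, cfg) and _attachment_positions(g, cfg):
            acceptors.append((g, n))
    if not acceptors:
        return None
    weights = np.array([n for _, n in acceptors], dtype=float)
    acceptor = acceptors[rng.choice(len(acceptors), p=weights / weights.sum())][0]
    positions = _attachment_positions(acceptor, cfg)
    if not positions:
        return None
    position = int(positions[rng.choice(len(positions))])
    return donor, acceptor, position


def react_batch(pool: ProductPool,
                cfg: ReactionConfig = ReactionConfig()) -> tuple[ProductPool, list[TransferEvent]]:
    """Run ``cfg.rounds`` reaction rounds on a copy of ``pool``.

    Each round performs at most one transfer.  Exhaustive mode is fully
    deterministic (smallest eligible donor, largest hybrid — else another
    donor — as acceptor, first free attachment position); stochastic mode
    samples all three choices with ``numpy.random.default_rng(cfg.seed)``
    and is bit-reproducible for a fixed seed.  Rounds with no eligible
    donor/acceptor pair leave the pool unchanged.
    """
    if cfg.rounds < 1:
        raise ValueError("rounds must be >= 1")
    out = pool.copy()
    events: list[TransferEvent] = []
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.rounds):
        if cfg.mode == "exhaustive":
            pair = _pick_exhaustive(out, cfg)
            if pair is None:
                break
            event = transglycosylate(pair[0], pair[1], cfg)
        else:
            pick = _pick_stochastic(out, cfg, rng)
            if pick is None:
                break
            event = transglycosylate(pick[0], pick[1], cfg, position=pick[2])
        _apply(out, event)
        events.append(event)
    return out, events


def predict_series(start_dp: int, n_rounds: int) -> list[int]:
    """DP ladder of iterative +3 transfer: start, start+3, …,
    start + 3·n_rounds."""
    if start_dp < 5:
        raise ValueError("series seeds require DP >= 5")
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    return [start_dp + 3 * k for k in range(n_rounds + 1)]
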