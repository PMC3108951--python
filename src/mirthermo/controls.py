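"""Shuffled-miRNA negative controls.

True-site energy distributions need a null to compare against.  The null
here is built from dinucleotide-shuffled miRNAs scanned against randomly
assigned UTRs: a first-order Markov walk consumes the miRNA's own
dinucleotide multiset (preserving composition and, largely, dinucleotide
content), leftovers are tolerated up to 15% of the length and inserted
at random, and any shuffle whose seed collides with a known miRNA seed
or a poly-A motif is discarded so the control cannot accidentally carry
real targeting signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seq_io import MiRNA, UtrRecord
from .site_scan import TargetSite


@dataclass(frozen=True)
class ShuffleConfig:
    """Control-set construction parameters.

    Defaults encode the 10-shuffles x 10-UTRs design with the 85%
    first-order rule; ``forbidden_seeds`` holds the position 2-8
    heptamers of the real miRNA set.
    """

    n_shuffles_per_mirna: int = 10
    n_utrs_per_shuffle: int = 10
    first_order_min_fraction: float = 0.85
    forbidden_seeds: frozenset[str] = frozenset()
    poly_a_motifs: frozenset[str] = frozenset({"AAAAAA", "AAUAAA"})
    max_retries: int = 1000
    #: also reject on 6-mer (positions 2-7) identity, stricter than default
    match_hexamer: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.first_order_min_fraction <= 1:
            raise ValueError("first_order_min_fraction must be in (0, 1]")
        if self.n_shuffles_per_mirna < 0:
            raise ValueError("n_shuffles_per_mirna must be >= 0")


@dataclass(frozen=True)
class ShuffleStats:
    """Instrumentation of one accepted shuffle attempt."""

    first_order_fraction: float  # bases placed by the Markov walk / length
    n_inserted: int
    n_attempts: int


class ShuffleError(RuntimeError):
    pass


def _attempt_shuffle(sequence: str, rng: np.random.Generator) -> tuple[str, float] | None:
    """One first-order walk; returns (sequence, first-order fraction) or None.

    The walk draws its start base from the mononucleotide frequencies,
    then repeatedly consumes a remaining dinucleotide starting with the
    current base (uniform over remaining instances) whose second base is
    still available in the mononucleotide budget — which guarantees exact
    composition conservation.  Returns None only in the impossible case
    of an empty draw at the start.
    """
    n = len(sequence)
    bases = list("ACGU")
    mono = Counter(sequence)
    start = rng.choice(
        [b for b in bases if mono[b]], p=[mono[b] / n for b in bases if mono[b]]
    )
    remaining = mono.copy()
    remaining[str(start)] -= 1
    dinucs = Counter(sequence[i : i + 2] for i in range(n - 1))
    out = [str(start)]
    while sum(remaining.values()) > 0:
        cur = out[-1]
        options = [
            d for d, c in dinucs.items() if c > 0 and d[0] == cur and remaining[d[1]] > 0
        ]
        if not options:
            break
        weights = np.array([dinucs[d] for d in options], dtype=float)
        choice = options[rng.choice(len(options), p=weights / weights.sum())]
        dinucs[choice] -= 1
        remaining[choice[1]] -= 1
        out.append(choice[1])
    placed = len(out)
    leftovers = [b for b, c in remaining.items() for _ in range(c)]
    for b in leftovers:
        pos = int(rng.integers(0, len(out) + 1))
        out.insert(pos, b)
    return "".join(out), placed / n


def dinucleotide_shuffle(
    mirna: MiRNA | str,
    config: ShuffleConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    return_stats: bool = False,
):
    """Dinucleotide-preserving shuffle of a miRNA sequence.

    Retries until the first-order walk places at least
    ``first_order_min_fraction`` of the bases before any random
    insertion; output always has the input's length and exact
    mononucleotide composition.
    """
    config = config or ShuffleConfig()
    rng = rng if rng is not None else np.random.default_rng()
    sequence = mirna.sequence if isinstance(mirna, MiRNA) else mirna
    if len(sequence) < 2:
        raise ValueError("sequence too short to shuffle")
    for attempt in range(1, config.max_retries + 1):
        result = _attempt_shuffle(sequence, rng)
        if result is None:
            continue
        shuffled, frac = result
        if frac >= config.first_order_min_fraction:
            assert Counter(shuffled) == Counter(sequence)
            if return_stats:
                n_inserted = len(sequence) - round(frac * len(sequence))
                return shuffled, ShuffleStats(frac, n_inserted, attempt)
            return shuffled
    raise ShuffleError(
        f"no acceptable shuffle of {sequence!r} within {config.max_retries} attempts"
    )


def seed_conflict_filter(shuffled: str, config: ShuffleConfig) -> bool:
    """True (accept) unless the shuffle's seed collides with known seeds
    or carries a poly-A motif in positions 1-8."""
    if len(shuffled) < 8:
        raise ValueError("shuffled sequence shorter than 8 nt")
    heptamer = shuffled[1:8]
    if heptamer in config.forbidden_seeds:
        return False
    if config.match_hexamer and any(
        heptamer[:6] == seed[:6] for seed in config.forbidden_seeds
    ):
        return False
    head = shuffled[:8]
    if any(motif in head for motif in config.poly_a_motifs):
        return False
    return True


def accepted_shuffle(
    mirna: MiRNA,
    config: ShuffleConfig,
    rng: np.random.Generator,
    index: int,
) -> MiRNA:
    """One shuffle passing both the 85% rule and the seed-conflict filter."""
    for _ in range(config.max_retries):
        candidate = dinucleotide_shuffle(mirna, config, rng)
        if seed_conflict_filter(candidate, config):
            return MiRNA(id=f"{mirna.id}|shuf{index}", sequence=candidate)
    raise ShuffleError(
        f"no shuffle of {mirna.id!r} passed the seed-conflict filter "
        f"within {config.max_retries} attempts"
    )


def generate_control_pairs(
    mirnas: Sequence[MiRNA],
    utr_pool: Sequence[UtrRecord],
    config: ShuffleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[MiRNA, UtrRecord]]:
    """Randomized control pairings: shuffles x randomly assigned UTRs.

    For each input miRNA, emits ``n_shuffles_per_mirna`` accepted
    shuffles, each paired with ``n_utrs_per_shuffle`` UTRs drawn without
    replacement.  Fully reproducible from the generator state.
    """
    config = config or ShuffleConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if len(utr_pool) < config.n_utrs_per_shuffle:
        raise ValueError("UTR pool smaller than n_utrs_per_shuffle")
    pairs: list[tuple[MiRNA, UtrRecord]] = []
    for mirna in mirnas:
        for k in range(config.n_shuffles_per_mirna):
            shuffled = accepted_shuffle(mirna, config, rng, k)
            idx = rng.choice(len(utr_pool), size=config.n_utrs_per_shuffle, replace=False)
            for i in idx:
                pairs.append((shuffled, utr_pool[int(i)]))
    return pairs


def sample_control_site(
    sites: Sequence[TargetSite], rng: np.random.Generator
) -> TargetSite | None:
    """Uniformly pick one site of a control pair (None when it has none)."""
    if not sites:
        return None
    return sites[int(rng.integers(0, len(sites)))]
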