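"""Stepwise duplex-formation energetics behind a pluggable engine contract.

The model: before a miRNA can bind, the local mRNA secondary structure
around the site must open (disruption energy, dG_open = RT ln P_unpaired,
always <= 0); the miRNA then hybridizes to the open site (hybridization
energy, dG_H).  The overall favorability of the site is

    ddG = dG_H - dG_open.

Lower ddG = better target.  Backends implement three primitives:
constrained bimolecular folding, structure re-evaluation, and the local
unpaired probability of a region inside a fixed window.  A ViennaRNA
adapter provides real thermodynamics; a deterministic toy engine makes
the full pipeline testable in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from .seq_io import MiRNA, UtrRecord
from .site_scan import (
    NucleusMatch,
    TargetSite,
    assign_seed_type,
    extract_duplex_context,
    find_nucleus_matches,
    resolve_overlaps,
    filter_by_seed,
)

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 0.0019872

#: Floor applied to unpaired probabilities before the log; probability 0
#: is an engine artifact, not a physical value.
P_UNPAIRED_FLOOR = 1e-12


@dataclass(frozen=True)
class ThermoEngineConfig:
    """Local-folding parameters for accessibility computation.

    ``window_W`` is the size of each local structure window, ``max_span_L``
    the maximum base-pair span inside it, and ``open_len_u`` the length of
    the region forced open.  Defaults follow the standard local-folding
    parameterization for 3'UTR scans (W=80, L=40, u=20) at 37 degC.
    """

    window_W: int = 80
    max_span_L: int = 40
    open_len_u: int = 20
    temperature: float = 310.15  # Kelvin
    #: open-region placements slide over the 4-mer nucleus ("nucleus")
    #: or over the whole extracted duplex span ("span").
    windows_over: str = "nucleus"
    #: flank rule: per-arm ("arm", default) or symmetric 2*(len-4) ("symmetric").
    flank_rule: str = "arm"

    def __post_init__(self) -> None:
        if not (0 < self.open_len_u <= self.max_span_L <= self.window_W):
            raise ValueError("require 0 < u <= L <= W")
        if self.windows_over not in ("nucleus", "span"):
            raise ValueError("windows_over must be 'nucleus' or 'span'")

    @property
    def RT(self) -> float:
        """kcal/mol; 0.6163 at 37 degC."""
        return GAS_CONSTANT * self.temperature


@dataclass(frozen=True)
class DuplexStructure:
    """Base pairs of a two-strand structure.

    Pairs are ((molecule, index), (molecule, index)) with molecule 0 =
    miRNA, 1 = mRNA context, indices 0-based.  Each base sits in at most
    one pair.
    """

    pairs: frozenset[tuple[tuple[int, int], tuple[int, int]]]

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[tuple[int, int], tuple[int, int]]]) -> "DuplexStructure":
        norm = frozenset(tuple(sorted(p)) for p in pairs)
        seen: set[tuple[int, int]] = set()
        for a, b in norm:
            for end in (a, b):
                if end in seen:
                    raise ValueError(f"base {end} in more than one pair")
                seen.add(end)
        return DuplexStructure(pairs=norm)

    def intramolecular(self) -> frozenset:
        return frozenset(p for p in self.pairs if p[0][0] == p[1][0])

    def intermolecular(self) -> frozenset:
        return frozenset(p for p in self.pairs if p[0][0] != p[1][0])


class ThermoEngine(Protocol):
    """Contract a thermodynamics backend must satisfy."""

    def constrained_cofold(
        self, seq_a: str, seq_b: str, forced_pairs: Sequence[tuple[int, int]]
    ) -> tuple[DuplexStructure, float]:
        """MFE bimolecular structure with (a_idx, b_idx) pairs forced; energy kcal/mol."""
        ...

    def evaluate(self, seq_a: str, seq_b: str, structure: DuplexStructure) -> float:
        """Free energy of a fixed structure (deterministic)."""
        ...

    def unpaired_probability(
        self, window_seq: str, region: tuple[int, int], max_span: int
    ) -> float:
        """P(region completely unpaired) in window_seq, pairs limited to max_span."""
        ...


# ---------------------------------------------------------------------------
# Toy engine


_PAIR_ENERGY = {
    frozenset(("A", "U")): -1.0,
    frozenset(("C", "G")): -1.0,
    frozenset(("G", "U")): -0.5,
}


@dataclass
class ToyEngine:
    """Deterministic pair-counting engine for tests and synthetic cohorts.

    Intermolecular WC pairs score -1.0 kcal/mol, G-U wobbles -0.5;
    intramolecular pairs are never formed.  ``constrained_cofold`` aligns
    the two strands antisense at the offset fixed by the forced nucleus
    pairs and pairs every complementary opposing base.

    Unpaired probabilities come in two deterministic flavors:
    ``unpaired_mode="constant"`` returns ``constant_p`` everywhere;
    ``"au"`` returns a logistic function of the AU fraction of the open
    region, so accessibility varies across sequence contexts (AU-rich =
    more accessible), which real local folding also exhibits.  In the
    "au" flavor, intermolecular pair energies are additionally modulated
    by the GC content of the mRNA-side neighborhood (stronger stacking
    in GC-rich context), so hybridization energies are not quantized to
    a coarse grid and site rankings by dG_H and ddG can genuinely differ
    — as they do under nearest-neighbor thermodynamics.
    """

    constant_p: float = 1.0
    unpaired_mode: str = "constant"

    def constrained_cofold(
        self, seq_a: str, seq_b: str, forced_pairs: Sequence[tuple[int, int]]
    ) -> tuple[DuplexStructure, float]:
        if not forced_pairs:
            raise ValueError("toy engine needs forced pairs to anchor the alignment")
        # Antisense alignment: a_idx + b_idx is constant across the duplex.
        anchor = forced_pairs[0][0] + forced_pairs[0][1]
        pairs = []
        for ai in range(len(seq_a)):
            bi = anchor - ai
            if 0 <= bi < len(seq_b):
                if frozenset((seq_a[ai], seq_b[bi])) in _PAIR_ENERGY:
                    pairs.append(((0, ai), (1, bi)))
        structure = DuplexStructure.from_pairs(pairs)
        return structure, self.evaluate(seq_a, seq_b, structure)

    def evaluate(self, seq_a: str, seq_b: str, structure: DuplexStructure) -> float:
        energy = 0.0
        seqs = (seq_a, seq_b)
        for (ma, ia), (mb, ib) in structure.pairs:
            if ma == mb:
                continue  # intramolecular pairs carry no energy here
            key = frozenset((seqs[ma][ia], seqs[mb][ib]))
            e = _PAIR_ENERGY.get(key, 0.0)
            if self.unpaired_mode == "au" and e:
                bi = ib if mb == 1 else ia
                hood = seq_b[max(0, bi - 3) : bi + 4]
                gc = sum(b in "GC" for b in hood) / len(hood)
                e *= 1.0 + 0.15 * gc
            energy += e
        return energy

    def unpaired_probability(
        self, window_seq: str, region: tuple[int, int], max_span: int
    ) -> float:
        start, end = region
        if end <= start:
            return 1.0
        if self.unpaired_mode == "constant":
            return self.constant_p
        sub = window_seq[start:end]
        au = sum(b in "AU" for b in sub) / len(sub)
        # Logistic in AU fraction: GC-rich regions fold up, AU-rich stay open.
        return 1.0 / (1.0 + math.exp(-6.0 * (au - 0.5)))


# ---------------------------------------------------------------------------
# ViennaRNA adapter


class ViennaEngine:
    """Thermodynamics via the ViennaRNA bindings.

    Bimolecular folding uses a fold compound over "mirna&context" with
    hard constraints forcing the nucleus pairs; re-evaluation scores a
    fixed dot-bracket structure; unpaired probabilities come from the
    partition-function ratio of the constrained (region open) and
    unconstrained folds of the W-sized window with the base-pair span
    capped at L.
    """

    def __init__(self) -> None:
        import RNA  # deferred: optional heavyweight dependency

        self._RNA = RNA

    def constrained_cofold(
        self, seq_a: str, seq_b: str, forced_pairs: Sequence[tuple[int, int]]
    ) -> tuple[DuplexStructure, float]:
        RNA = self._RNA
        fc = RNA.fold_compound(f"{seq_a}&{seq_b}")
        na = len(seq_a)
        for ai, bi in forced_pairs:
            fc.hc_add_bp(ai + 1, na + bi + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
        structure, energy = fc.mfe_dimer()
        return self._parse_structure(structure, na, len(seq_b)), energy

    def _parse_structure(self, dotbracket: str, na: int, nb: int) -> DuplexStructure:
        stack: list[int] = []
        pairs = []
        for i, ch in enumerate(dotbracket.replace("&", "")):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pairs.append(self._to_mol(j, na) + self._to_mol(i, na))
        return DuplexStructure.from_pairs(
            [((p[0], p[1]), (p[2], p[3])) for p in pairs]
        )

    @staticmethod
    def _to_mol(idx: int, na: int) -> tuple[int, int]:
        return (0, idx) if idx < na else (1, idx - na)

    def evaluate(self, seq_a: str, seq_b: str, structure: DuplexStructure) -> float:
        RNA = self._RNA
        na, nb = len(seq_a), len(seq_b)

        def flat(end: tuple[int, int]) -> int:
            return end[1] if end[0] == 0 else na + end[1]

        chars = ["."] * (na + nb)
        for p in structure.pairs:
            i, j = sorted(flat(e) for e in p)
            chars[i] = "("
            chars[j] = ")"
        db = "".join(chars[:na]) + "&" + "".join(chars[na:])
        fc = RNA.fold_compound(f"{seq_a}&{seq_b}")
        return fc.eval_structure(db)

    def unpaired_probability(
        self, window_seq: str, region: tuple[int, int], max_span: int
    ) -> float:
        RNA = self._RNA
        start, end = region
        if end <= start:
            return 1.0
        md = RNA.md()
        md.max_bp_span = max_span
        fc = RNA.fold_compound(window_seq, md)
        _, f_free = fc.pf()
        fc_open = RNA.fold_compound(window_seq, md)
        for i in range(start, end):
            fc_open.hc_add_up(i + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
        _, f_open = fc_open.pf()
        kT = RNA.GASCONST * (md.temperature + RNA.K0) / 1000.0  # cal -> kcal
        return math.exp(-(f_open - f_free) / kT)


def get_engine(name: str, **kwargs) -> ThermoEngine:
    """Engine registry: ``toy``, ``toy-au`` or ``vienna``."""
    if name == "toy":
        return ToyEngine(**kwargs)
    if name == "toy-au":
        return ToyEngine(unpaired_mode="au", **kwargs)
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown engine {name!r}")


# ---------------------------------------------------------------------------
# Energies


def nucleus_forced_pairs(
    match: NucleusMatch, mirna: MiRNA, context_nucleus_start: int
) -> list[tuple[int, int]]:
    """Forced (miRNA index, context index) pairs for the 4 nucleus bases.

    Pairing is antisense: miRNA nucleus 5' base pairs the context 4-mer's
    3' base.
    """
    p0 = match.mirna_pos - 1  # 0-based miRNA index of nucleus start
    return [(p0 + k, context_nucleus_start + 3 - k) for k in range(4)]


def repair_structure(
    structure: DuplexStructure, forced_pairs: Sequence[tuple[int, int]]
) -> DuplexStructure:
    """Enforce nucleus pairs, drop all intramolecular pairs, keep the rest.

    Idempotent: repairing a repaired structure changes nothing.
    """
    forced = {tuple(sorted(((0, ai), (1, bi)))) for ai, bi in forced_pairs}
    forced_ends = {end for p in forced for end in p}
    kept = [
        p
        for p in structure.intermolecular()
        if p not in forced and not (set(p) & forced_ends)
    ]
    return DuplexStructure.from_pairs(list(forced) + kept)


def hybridization_energy(
    mirna: MiRNA,
    context: str,
    forced_pairs: Sequence[tuple[int, int]],
    engine: ThermoEngine,
    config: ThermoEngineConfig | None = None,
) -> tuple[float, DuplexStructure]:
    """dG_H of miRNA binding to the extracted context, nucleus enforced.

    The constrained cofold must leave all four nucleus bases paired to
    their partners and form no intramolecular pairs; otherwise the
    structure is repaired (nucleus pairs enforced, intramolecular pairs
    removed, other intermolecular pairs kept) and re-evaluated.
    """
    structure, energy = engine.constrained_cofold(mirna.sequence, context, forced_pairs)
    wanted = {tuple(sorted(((0, ai), (1, bi)))) for ai, bi in forced_pairs}
    ok = wanted <= structure.pairs and not structure.intramolecular()
    if ok:
        return energy, structure
    repaired = repair_structure(structure, forced_pairs)
    return engine.evaluate(mirna.sequence, context, repaired), repaired


def disruption_energy(
    seq: str,
    nucleus_span: tuple[int, int],
    engine: ThermoEngine,
    config: ThermoEngineConfig,
) -> float:
    """dG_open = mean over open-region placements of RT ln P_unpaired.

    Every u-length open region that fully contains ``nucleus_span`` and
    fits in ``seq`` is evaluated inside its own exactly-W window
    (centered on the open region, shifted inward at sequence ends,
    shrunk only when the sequence itself is shorter than W).  The log is
    taken per window, then averaged — the expectation of a log is not
    the log of the expectation.
    """
    u, W, L, RT = config.open_len_u, config.window_W, config.max_span_L, config.RT
    n = len(seq)
    ns, ne = nucleus_span
    if n < u:
        placements = [(0, n)]
    elif ne - ns >= u:
        # open region cannot contain the whole span: one placement
        # centered on it, clipped to the sequence
        a = max(0, min((ns + ne) // 2 - u // 2, n - u))
        placements = [(a, a + u)]
    else:
        lo = max(0, ne - u)
        hi = min(ns, n - u)
        placements = [(a, a + u) for a in range(lo, hi + 1)]
    values = []
    for a, b in placements:
        if n <= W:
            win_start, win_end = 0, n
        else:
            center = (a + b) // 2
            win_start = min(max(0, center - W // 2), n - W)
            win_end = win_start + W
        window = seq[win_start:win_end]
        p = engine.unpaired_probability(window, (a - win_start, b - win_start), L)
        values.append(RT * math.log(max(p, P_UNPAIRED_FLOOR)))
    return sum(values) / len(values)


def total_energy(dG_H: float, dG_open: float) -> float:
    """ddG = dG_H - dG_open."""
    return dG_H - dG_open


def score_site(
    match: NucleusMatch,
    mirna: MiRNA,
    utr: UtrRecord,
    engine: ThermoEngine,
    config: ThermoEngineConfig,
) -> TargetSite:
    """Compute the three energies and seed type for one nucleus match."""
    context, span = extract_duplex_context(match, mirna, utr)
    # nucleus position within the extracted context string
    up_used = (match.utr_start - span[0]) + (
        len(context) - (span[1] - span[0])
    )  # UTR upstream flank + CDS part
    forced = nucleus_forced_pairs(match, mirna, up_used)
    dG_H, _ = hybridization_energy(mirna, context, forced, engine, config)
    full = utr.upstream_context + utr.sequence
    nuc_start = len(utr.upstream_context) + match.utr_start
    windows_span = (
        (nuc_start, nuc_start + 4)
        if config.windows_over == "nucleus"
        else (len(utr.upstream_context) + span[0], len(utr.upstream_context) + span[1])
    )
    dG_open = disruption_energy(full, windows_span, engine, config)
    return TargetSite(
        match=match,
        seed_type=assign_seed_type(match, mirna, utr),
        dG_H=dG_H,
        dG_open=dG_open,
        ddG=total_energy(dG_H, dG_open),
        site_span=span,
    )


def score_sites(
    mirna: MiRNA,
    utr: UtrRecord,
    engine: ThermoEngine,
    config: ThermoEngineConfig | None = None,
    seed_filter: str = "4mer",
) -> list[TargetSite]:
    """End-to-end per-pair scoring.

    Finds every nucleus match, computes energies, collapses overlapping
    nuclei to the best-ddG representative, and applies the seed filter.
    Deterministic for a fixed engine.
    """
    config = config or ThermoEngineConfig()
    matches = find_nucleus_matches(mirna, utr)
    sites = [score_site(m, mirna, utr, engine, config) for m in matches]
    sites = resolve_overlaps(sites)
    return filter_by_seed(sites, seed_filter)
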