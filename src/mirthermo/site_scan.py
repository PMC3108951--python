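"""Candidate target-site discovery and seed-type taxonomy.

A candidate site is any UTR position carrying a perfect Watson-Crick
4-mer match (the duplex "nucleus") to the miRNA seed region (positions
2-8).  G-U wobbles never count — neither in nucleus matching nor in
seed typing.  Each retained site is later assigned the three energies of
stepwise duplex formation (see :mod:`mirthermo.thermo`); overlapping
nuclei are collapsed to the energetically best representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seq_io import MiRNA, UtrRecord, reverse_complement

#: Seed-type labels from most to least stringent.  Consecutive-match
#: classes outrank gapped ("in-8") classes of equal pair count.
SEED_TYPE_ORDER = [
    "8mer",
    "7mer-A",
    "7mer",
    "6mer",
    "7in8",
    "6in8",
    "5mer",
    "5in8",
    "4mer",
]

_PRIORITY = {label: rank for rank, label in enumerate(SEED_TYPE_ORDER)}

#: Seed filter levels: which labels each level retains.
FILTER_LEVELS = {
    "4mer": set(SEED_TYPE_ORDER),
    "6in8": {"8mer", "7mer-A", "7mer", "6mer", "7in8", "6in8"},
    "6mer": {"8mer", "7mer-A", "7mer", "6mer"},
}


@dataclass(frozen=True)
class SeedType:
    label: str

    def __post_init__(self) -> None:
        if self.label not in _PRIORITY:
            raise ValueError(f"unknown seed type {self.label!r}")

    @property
    def priority(self) -> int:
        """Rank in SEED_TYPE_ORDER; smaller = more stringent."""
        return _PRIORITY[self.label]

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class NucleusMatch:
    """A perfect WC 4-mer between UTR and miRNA seed region.

    ``mirna_pos`` is the 1-based miRNA position of the nucleus 5' end and
    lies in {2..5} so the 4-mer sits wholly inside positions 2-8.
    ``utr_start`` is 0-based; the UTR 4-mer occupies
    [utr_start, utr_start+4).
    """

    utr_id: str
    mirna_id: str
    utr_start: int
    mirna_pos: int
    nucleus: str

    def __post_init__(self) -> None:
        if not 2 <= self.mirna_pos <= 5:
            raise ValueError("nucleus must lie within miRNA positions 2-8")


@dataclass(frozen=True)
class TargetSite:
    """A nucleus match with its three energies and seed type.

    Energies are kcal/mol; ddG = dG_H - dG_open (stepwise duplex
    formation: opening the local mRNA structure, then hybridizing).
    ``site_span`` is the 0-based half-open UTR interval covered by the
    extracted duplex context (UTR part only).
    """

    match: NucleusMatch
    seed_type: SeedType
    dG_H: float
    dG_open: float
    ddG: float
    site_span: tuple[int, int]


def find_nucleus_matches(mirna: MiRNA, utr: UtrRecord) -> list[NucleusMatch]:
    """Enumerate every perfect 4-mer WC match of the seed region in the UTR.

    Returns matches sorted by ``utr_start`` then ``mirna_pos``.
    """
    out: list[NucleusMatch] = []
    seq = utr.sequence
    # Precompute the UTR-side targets: reverse complement of each seed 4-mer.
    targets = []
    for pos in range(2, 6):  # 1-based start; nucleus = positions pos..pos+3
        nucleus = mirna.sequence[pos - 1 : pos + 3]
        targets.append((pos, nucleus, reverse_complement(nucleus)))
    for start in range(len(seq) - 3):
        word = seq[start : start + 4]
        for pos, nucleus, rc in targets:
            if word == rc:
                out.append(
                    NucleusMatch(
                        utr_id=utr.id,
                        mirna_id=mirna.id,
                        utr_start=start,
                        mirna_pos=pos,
                        nucleus=nucleus,
                    )
                )
    out.sort(key=lambda m: (m.utr_start, m.mirna_pos))
    return out


def flank_lengths(match: NucleusMatch, mirna: MiRNA) -> tuple[int, int]:
    """(upstream, downstream) UTR flank lengths for duplex context.

    Each flank is twice the length of the corresponding remaining miRNA
    arm.  Pairing is antisense, so the miRNA 5' arm (positions < nucleus)
    faces the downstream (3') UTR flank and the miRNA 3' remainder faces
    the upstream (5') flank.
    """
    five_arm = match.mirna_pos - 1
    three_arm = mirna.length - (match.mirna_pos + 3)
    return 2 * three_arm, 2 * five_arm


def extract_duplex_context(
    match: NucleusMatch, mirna: MiRNA, utr: UtrRecord
) -> tuple[str, tuple[int, int]]:
    """UTR context around the nucleus for hybridization-energy folding.

    Returns ``(context, site_span)`` where ``context`` is the nucleus
    4-mer plus flanks (possibly reaching into the upstream CDS context)
    and ``site_span`` is the 0-based half-open UTR interval actually used.
    Flanks are truncated at sequence ends ("up to twice" the arm length).
    """
    up_len, down_len = flank_lengths(match, mirna)
    s, e = match.utr_start, match.utr_start + 4
    span_start = max(0, s - up_len)
    span_end = min(len(utr.sequence), e + down_len)
    # 5' overhang may be served by the upstream CDS context.
    overhang = up_len - (s - span_start)
    cds_part = utr.upstream_context[len(utr.upstream_context) - overhang :] if overhang > 0 else ""
    context = cds_part + utr.sequence[span_start:span_end]
    return context, (span_start, span_end)


def pairing_pattern(
    match: NucleusMatch, mirna: MiRNA, utr: UtrRecord
) -> tuple[list[bool], bool]:
    """WC pairing state of miRNA positions 1-8 at this site.

    Returns ``(paired, a_opposite_1)`` where ``paired[i]`` says whether
    miRNA position i+1 forms a WC pair with its antisense UTR partner
    (G-U = mismatch; out-of-bounds UTR positions = mismatch), and
    ``a_opposite_1`` whether the UTR base across miRNA position 1 is A.
    """
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    s, p = match.utr_start, match.mirna_pos
    paired = []
    for i in range(1, 9):  # miRNA position, 1-based
        u_idx = s + 3 + (p - i)
        if 0 <= u_idx < len(utr.sequence) and i <= mirna.length:
            paired.append(utr.sequence[u_idx] == comp[mirna.sequence[i - 1]])
        else:
            paired.append(False)
    u1 = s + 3 + (p - 1)
    a_opposite_1 = 0 <= u1 < len(utr.sequence) and utr.sequence[u1] == "A"
    return paired, a_opposite_1


def _max_run(bits: Sequence[bool]) -> int:
    best = run = 0
    for b in bits:
        run = run + 1 if b else 0
        best = max(best, run)
    return best


def classify_pairing(paired: Sequence[bool], a_opposite_1: bool) -> SeedType:
    """Map a position 1-8 pairing pattern to its seed-type label.

    ``paired`` holds WC pairing flags for miRNA positions 1-8.  The
    highest-priority satisfied class wins: consecutive classes (8mer,
    7mer[-A], 6mer, 5mer) require unbroken WC runs; "in-8" classes count
    pairs anywhere in positions 1-8, with an A across position 1 counting
    as a pair.
    """
    if len(paired) != 8:
        raise ValueError("pattern must cover miRNA positions 1-8")
    run_2_8 = _max_run(paired[1:8])
    # A across position 1 counts as a pair in the in-8 classes; a WC pair
    # at position 1 must not be double-counted.
    in8 = sum(paired[1:8]) + (1 if (paired[0] or a_opposite_1) else 0)
    if all(paired):
        return SeedType("8mer")
    if run_2_8 == 7 and a_opposite_1:
        return SeedType("7mer-A")
    if run_2_8 == 7:
        return SeedType("7mer")
    if run_2_8 >= 6:
        return SeedType("6mer")
    if in8 >= 7:
        return SeedType("7in8")
    if in8 >= 6:
        return SeedType("6in8")
    if run_2_8 >= 5:
        return SeedType("5mer")
    if in8 >= 5:
        return SeedType("5in8")
    return SeedType("4mer")


def assign_seed_type(match: NucleusMatch, mirna: MiRNA, utr: UtrRecord) -> SeedType:
    """Seed type of a site from its maximal complement to positions 1-8."""
    paired, a1 = pairing_pattern(match, mirna, utr)
    return classify_pairing(paired, a1)


def filter_by_seed(sites: Iterable[TargetSite], level: str) -> list[TargetSite]:
    """Keep sites whose seed type passes the given stringency level.

    ``4mer`` keeps everything; ``6mer`` keeps >=6 consecutive WC pairs;
    ``6in8`` additionally keeps the gapped 7in8/6in8 classes.
    """
    if level not in FILTER_LEVELS:
        raise ValueError(f"unknown filter level {level!r}; choose from {sorted(FILTER_LEVELS)}")
    allowed = FILTER_LEVELS[level]
    return [s for s in sites if s.seed_type.label in allowed]


def resolve_overlaps(sites: Sequence[TargetSite]) -> list[TargetSite]:
    """Collapse overlapping 4-mer nuclei to the best-ddG representative.

    Sites from one miRNA-UTR pair whose nucleus intervals overlap
    (transitively) form a group; the minimum-ddG site represents the
    group.  Ties break by lower utr_start, then lower mirna_pos, so
    output is deterministic.
    """
    by_pair: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        by_pair.setdefault((s.match.mirna_id, s.match.utr_id), []).append(s)
    kept: list[TargetSite] = []
    for group_sites in by_pair.values():
        group_sites = sorted(group_sites, key=lambda s: (s.match.utr_start, s.match.mirna_pos))
        cluster: list[TargetSite] = []
        cluster_end = -1
        for s in group_sites:
            if cluster and s.match.utr_start < cluster_end:
                cluster.append(s)
                cluster_end = max(cluster_end, s.match.utr_start + 4)
            else:
                if cluster:
                    kept.append(_best_of(cluster))
                cluster = [s]
                cluster_end = s.match.utr_start + 4
        if cluster:
            kept.append(_best_of(cluster))
    kept.sort(key=lambda s: (s.match.mirna_id, s.match.utr_id, s.match.utr_start))
    return kept


def _best_of(cluster: Sequence[TargetSite]) -> TargetSite:
    return min(cluster, key=lambda s: (s.ddG, s.match.utr_start, s.match.mirna_pos))


def dedupe_isoform_sites(
    sites: Sequence[TargetSite],
    isoform_map: Mapping[str, Sequence[str]],
) -> list[TargetSite]:
    """Count a site shared by a gene's isoforms once.

    ``isoform_map`` maps gene id -> isoform (UTR) ids.  Within one gene
    and miRNA, sites with identical nucleus sequence position-in-context
    and identical extracted duplex context (energies equal) collapse to
    one record; isoform-specific context keeps both.  Isoform ids absent
    from the map are treated as single-isoform genes (warning).
    """
    gene_of: dict[str, str] = {}
    for gene, isoforms in isoform_map.items():
        for iso in isoforms:
            gene_of[iso] = gene
    seen: set[tuple] = set()
    out: list[TargetSite] = []
    for s in sites:
        gene = gene_of.get(s.match.utr_id)
        if gene is None:
            warnings.warn(
                f"isoform {s.match.utr_id!r} absent from isoform map; treated as its own gene"
            )
            gene = s.match.utr_id
        key = (
            gene,
            s.match.mirna_id,
            s.match.mirna_pos,
            s.match.nucleus,
            round(s.dG_H, 9),
            round(s.dG_open, 9),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


def sites_to_bed(sites: Sequence[TargetSite]) -> str:
    """BED6 export of site spans (name = seed type, score = scaled -ddG)."""
    lines = []
    for s in sites:
        start, end = s.site_span
        score = int(max(0, min(1000, round(-s.ddG * 10))))
        lines.append(
            f"{s.match.utr_id}\t{start}\t{end}\t{s.seed_type.label}\t{score}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
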