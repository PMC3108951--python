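"""Scanner, seed taxonomy, filters and overlap resolution."""

import numpy as np
import pytest

from mirthermo import MiRNA, UtrRecord
from mirthermo.seq_io import reverse_complement
from mirthermo.site_scan import (
    FILTER_LEVELS,
    SEED_TYPE_ORDER,
    NucleusMatch,
    SeedType,
    TargetSite,
    assign_seed_type,
    classify_pairing,
    dedupe_isoform_sites,
    extract_duplex_context,
    filter_by_seed,
    find_nucleus_matches,
    flank_lengths,
    pairing_pattern,
    resolve_overlaps,
)
from conftest import random_mirna_seq, random_rna


def brute_force_matches(mirna: MiRNA, utr: UtrRecord):
    """Independent oracle: enumerate all UTR 4-mers against all seed 4-mers."""
    hits = []
    for start in range(len(utr.sequence) - 3):
        for pos in range(2, 6):
            nucleus = mirna.sequence[pos - 1 : pos + 3]
            if utr.sequence[start : start + 4] == reverse_complement(nucleus):
                hits.append((start, pos))
    return hits


class TestScanner:
    def test_four_overlapping_matches(self, example_mirna):
        utr = UtrRecord(id="u", sequence="ACAUUCC")
        got = [(m.utr_start, m.mirna_pos, m.nucleus) for m in find_nucleus_matches(example_mirna, utr)]
        assert got == [(0, 5, "AUGU"), (1, 4, "AAUG"), (2, 3, "GAAU"), (3, 2, "GGAA")]

    def test_no_complement_no_match(self, example_mirna):
        utr = UtrRecord(id="u", sequence="A" * 50)
        assert find_nucleus_matches(example_mirna, utr) == []

    def test_gu_wobble_is_a_mismatch(self):
        # seed 4-mer at pos 2 is GGAA; WC complement UUCC; wobble variant UUUC
        m = MiRNA(id="m", sequence="UGGAACCCCCCCCC")
        utr = UtrRecord(id="u", sequence="CCGUUUCGG")  # contains UUUC, not UUCC
        assert find_nucleus_matches(m, utr) == []

    def test_matches_equal_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            m = MiRNA(id="m", sequence=random_mirna_seq(rng))
            utr = UtrRecord(id="u", sequence=random_rna(rng, int(rng.integers(10, 300))))
            got = [(x.utr_start, x.mirna_pos) for x in find_nucleus_matches(m, utr)]
            assert got == sorted(brute_force_matches(m, utr))


class TestDuplexContext:
    def test_flank_arithmetic_pos2(self, example_mirna):
        utr = UtrRecord(id="u", sequence="G" * 50 + "UUCC" + "G" * 50)
        match = find_nucleus_matches(example_mirna, utr)[0]
        assert (match.utr_start, match.mirna_pos) == (50, 2)
        # 5' arm = 1 nt -> downstream flank 2 nt; 3' remainder 17 nt -> upstream 34
        assert flank_lengths(match, example_mirna) == (34, 2)
        context, span = extract_duplex_context(match, example_mirna, utr)
        assert len(context) == 34 + 4 + 2 == 40
        assert span == (16, 56)

    def test_flank_arithmetic_pos5(self, example_mirna):
        utr = UtrRecord(id="u", sequence="G" * 50 + "ACAU" + "G" * 50)
        match = find_nucleus_matches(example_mirna, utr)[0]
        assert match.mirna_pos == 5
        # 5' arm = 4 -> downstream 8; 3' remainder 14 -> upstream 28
        assert flank_lengths(match, example_mirna) == (28, 8)
        context, _ = extract_duplex_context(match, example_mirna, utr)
        assert len(context) == 28 + 4 + 8

    def test_truncated_at_utr_start_without_context(self, example_mirna):
        utr = UtrRecord(id="u", sequence="UUCC" + "G" * 50)
        match = find_nucleus_matches(example_mirna, utr)[0]
        context, span = extract_duplex_context(match, example_mirna, utr)
        assert span[0] == 0
        assert len(context) == 4 + 2  # upstream flank fully truncated

    def test_reaches_into_cds_context(self, example_mirna):
        utr = UtrRecord(id="u", sequence="UUCC" + "G" * 50, upstream_context="C" * 100)
        match = find_nucleus_matches(example_mirna, utr)[0]
        context, span = extract_duplex_context(match, example_mirna, utr)
        assert len(context) == 34 + 4 + 2
        assert context.startswith("C" * 34)
        assert span == (0, 6)  # UTR part only


def _pattern_utr(mirna: MiRNA, paired_positions, opposite1="G"):
    """Build a UTR whose 8-nt window realizes the given pairing pattern."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    window = []
    for i in range(8, 0, -1):
        c = comp[mirna.sequence[i - 1]]
        if i in paired_positions:
            window.append(c)
        elif i == 1:
            window.append(opposite1)
        else:
            window.append({"A": "C", "C": "A", "G": "A", "U": "C"}[c])
    return UtrRecord(id="u", sequence="".join(window))


class TestSeedTypes:
    # example_mirna positions 1-8 = U G G A A U G U; pos1 complement = A,
    # so opposite1 must avoid both A (the A rule) and the complement.
    def mirna(self):
        return MiRNA(id="m", sequence="CGGAAUGUAAAGAAGUAUGUAU")  # pos1 = C

    def _assign(self, mirna, paired, opposite1="C"):
        utr = _pattern_utr(mirna, paired, opposite1)
        match = NucleusMatch(utr_id="u", mirna_id="m", utr_start=3, mirna_pos=2, nucleus=mirna.sequence[1:5])
        return assign_seed_type(match, mirna, utr).label

    def test_8mer(self):
        assert self._assign(self.mirna(), set(range(1, 9))) == "8mer"

    def test_7mer_a(self):
        assert self._assign(self.mirna(), set(range(2, 9)), opposite1="A") == "7mer-A"

    def test_7mer(self):
        assert self._assign(self.mirna(), set(range(2, 9)), opposite1="C") == "7mer"

    def test_6mer_with_wobble_at_8(self):
        # WC at 2-7; position 8 gets the G-U wobble partner, which must not count
        m = self.mirna()  # position 8 = U -> wobble partner G
        utr = _pattern_utr(m, set(range(2, 8)))
        seq = "G" + utr.sequence[1:]  # wobble G across position 8 (leftmost base)
        utr = UtrRecord(id="u", sequence=seq)
        match = NucleusMatch(utr_id="u", mirna_id="m", utr_start=3, mirna_pos=2, nucleus=m.sequence[1:5])
        assert assign_seed_type(match, m, utr).label == "6mer"

    def test_6in8_from_gapped_pairs(self):
        assert self._assign(self.mirna(), {2, 3, 4, 5, 7, 8}) == "6in8"

    def test_utr_edge_positions_count_as_mismatch(self):
        m = self.mirna()
        # nucleus at UTR start: positions beyond the 5' end cannot pair
        utr = UtrRecord(id="u", sequence=_pattern_utr(m, set(range(1, 9))).sequence[3:])
        match = NucleusMatch(utr_id="u", mirna_id="m", utr_start=0, mirna_pos=2, nucleus=m.sequence[1:5])
        label = assign_seed_type(match, m, utr).label
        # positions 1-5 still pair, 6-8 fall off the end: 5 pairs in 8, but
        # only a 4-run within 2-8 -> gapped 5in8, not 5mer
        assert label == "5in8"


def seed_type_oracle(paired, a1):
    """Reference classifier written straight from the taxonomy definitions."""

    def runs(bits):
        best = cur = 0
        for b in bits:
            cur = cur + 1 if b else 0
            best = max(best, cur)
        return best

    r = runs(paired[1:])
    n_in8 = sum(paired[1:]) + (1 if (paired[0] or a1) else 0)
    if all(paired):
        return "8mer"
    if r == 7 and a1:
        return "7mer-A"
    if r == 7:
        return "7mer"
    if r >= 6:
        return "6mer"
    if n_in8 >= 7:
        return "7in8"
    if n_in8 >= 6:
        return "6in8"
    if r >= 5:
        return "5mer"
    if n_in8 >= 5:
        return "5in8"
    return "4mer"


class TestTaxonomyTruthTable:
    def test_all_512_patterns(self):
        for bits in range(256):
            paired = [(bits >> i) & 1 == 1 for i in range(8)]
            for a1 in (False, True):
                assert classify_pairing(paired, a1).label == seed_type_oracle(paired, a1), (
                    paired,
                    a1,
                )

    def test_upgrading_a_mismatch_never_lowers_priority(self):
        for bits in range(256):
            paired = [(bits >> i) & 1 == 1 for i in range(8)]
            for a1 in (False, True):
                base = classify_pairing(paired, a1).priority
                for i in range(8):
                    if not paired[i]:
                        upgraded = paired.copy()
                        upgraded[i] = True
                        assert classify_pairing(upgraded, a1).priority <= base


def _typed_site(label, utr_start=0, ddG=-1.0, mirna_id="m", utr_id="u"):
    return TargetSite(
        match=NucleusMatch(utr_id=utr_id, mirna_id=mirna_id, utr_start=utr_start, mirna_pos=2, nucleus="GGAA"),
        seed_type=SeedType(label),
        dG_H=ddG - 1.0,
        dG_open=-1.0,
        ddG=ddG,
        site_span=(utr_start, utr_start + 4),
    )


class TestSeedFilters:
    def test_levels(self):
        sites = [_typed_site(l, utr_start=10 * i) for i, l in enumerate(["8mer", "6in8", "5mer"])]
        assert {s.seed_type.label for s in filter_by_seed(sites, "6mer")} == {"8mer"}
        assert {s.seed_type.label for s in filter_by_seed(sites, "6in8")} == {"8mer", "6in8"}
        assert filter_by_seed(sites, "4mer") == sites

    def test_unknown_level(self):
        with pytest.raises(ValueError, match="unknown filter level"):
            filter_by_seed([], "5mer")

    def test_filter_nesting_on_random_label_sets(self, rng):
        labels = list(SEED_TYPE_ORDER)
        for _ in range(50):
            sites = [
                _typed_site(str(rng.choice(labels)), utr_start=10 * i)
                for i in range(int(rng.integers(0, 12)))
            ]
            kept = {lvl: {id(s) for s in filter_by_seed(sites, lvl)} for lvl in FILTER_LEVELS}
            assert kept["6mer"] <= kept["6in8"] <= kept["4mer"]


class TestOverlapResolution:
    def test_best_ddG_represents_cluster(self):
        ddGs = [-3.0, -5.0, -4.0, -2.0]
        sites = [_typed_site("4mer", utr_start=i, ddG=d) for i, d in enumerate(ddGs)]
        kept = resolve_overlaps(sites)
        assert len(kept) == 1 and kept[0].ddG == -5.0

    def test_disjoint_sites_kept(self):
        sites = [_typed_site("4mer", utr_start=0), _typed_site("4mer", utr_start=10)]
        assert len(resolve_overlaps(sites)) == 2

    def test_tie_breaks_leftmost(self):
        sites = [_typed_site("4mer", utr_start=0, ddG=-2.0), _typed_site("4mer", utr_start=2, ddG=-2.0)]
        kept = resolve_overlaps(sites)
        assert len(kept) == 1 and kept[0].match.utr_start == 0

    def test_no_retained_intervals_intersect_and_minima_hold(self, rng):
        for _ in range(50):
            sites = [
                _typed_site("4mer", utr_start=int(rng.integers(0, 60)), ddG=float(rng.normal(-5, 2)))
                for _ in range(int(rng.integers(1, 15)))
            ]
            kept = resolve_overlaps(sites)
            spans = sorted((s.match.utr_start, s.match.utr_start + 4) for s in kept)
            assert all(a2 >= b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))
            for s in sites:
                overlapping = [
                    k for k in kept
                    if s.match.utr_start < k.match.utr_start + 4 and k.match.utr_start < s.match.utr_start + 4
                ]
                assert any(k.ddG <= s.ddG for k in overlapping) or not overlapping


class TestBedExport:
    def test_bed6_fields(self):
        from mirthermo.site_scan import sites_to_bed

        line = sites_to_bed([_typed_site("8mer", utr_start=5, ddG=-7.5)]).strip()
        chrom, start, end, name, score, strand = line.split("\t")
        assert (chrom, name, strand) == ("u", "8mer", "+")
        assert int(score) == 75  # scaled -ddG
        assert sites_to_bed([]) == ""


class TestIsoformDedup:
    def test_identical_context_collapses(self):
        s1 = _typed_site("6mer", utr_id="iso1")
        s2 = _typed_site("6mer", utr_id="iso2")
        kept = dedupe_isoform_sites([s1, s2], {"geneA": ["iso1", "iso2"]})
        assert len(kept) == 1

    def test_energy_difference_keeps_both(self):
        s1 = _typed_site("6mer", utr_id="iso1", ddG=-3.0)
        s2 = _typed_site("6mer", utr_id="iso2", ddG=-4.0)
        kept = dedupe_isoform_sites([s1, s2], {"geneA": ["iso1", "iso2"]})
        assert len(kept) == 2

    def test_unmapped_isoform_warns_and_stands_alone(self):
        s1 = _typed_site("6mer", utr_id="iso1")
        s2 = _typed_site("6mer", utr_id="lone")
        with pytest.warns(UserWarning, match="lone"):
            kept = dedupe_isoform_sites([s1, s2], {"geneA": ["iso1"]})
        assert len(kept) == 2
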