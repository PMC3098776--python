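import numpy as np
import pytest

from fernbz.repeats import (
    RepeatFamily,
    cluster_families,
    consensus_iupac,
    extract_span_seqs,
    find_repeats,
    mask_overlaps,
)
from fernbz.seq_io import reverse_complement

from ._oracles import repeat_matches_bruteforce
from .conftest import random_dna


def as_tuples(matches):
    return {(m.kind, m.pos1, m.pos2, m.length, m.mismatches) for m in matches}


class TestFindRepeats:
    def test_planted_exact_duplication(self, rng):
        bg = random_dna(rng, 200)
        seq = bg[:60] + bg[120:145] + bg[60:120] + bg[120:]
        hits = find_repeats(seq, min_len=25, max_hamming=0, kinds=("direct",))
        # the planted 25-mer pair is present (possibly extended by chance)
        assert any(
            m.pos1 <= 61 <= m.pos1 + m.length
            and m.pos2 <= 146 <= m.pos2 + m.length
            and m.length >= 25
            for m in hits
        )

    def test_planted_revcomp_match(self, rng):
        bg = random_dna(rng, 160)
        seq = bg[:100] + reverse_complement(bg[10:40]) + bg[100:]
        hits = find_repeats(seq, min_len=25, max_hamming=0, kinds=("revcomp",))
        assert len(hits) >= 1
        m = max(hits, key=lambda m: m.length)
        assert m.length >= 30

    def test_trivial_self_match_excluded(self, rng):
        seq = random_dna(rng, 50)
        assert all(
            m.pos1 != m.pos2
            for m in find_repeats(seq, min_len=5, max_hamming=0, kinds=("direct",))
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            find_repeats("ACGTACGT", kinds=("inverted",))

    @pytest.mark.parametrize("kind", ["direct", "reverse", "complement", "revcomp"])
    @pytest.mark.parametrize("max_hamming", [0, 1, 3])
    def test_equals_bruteforce_oracle(self, kind, max_hamming):
        rng = np.random.default_rng(hash((kind, max_hamming)) % 2**31)
        for _ in range(8):
            n = int(rng.integers(50, 150))
            seq = random_dna(rng, n, gc=float(rng.uniform(0.25, 0.6)))
            got = as_tuples(find_repeats(seq, 10, max_hamming, (kind,)))
            assert got == repeat_matches_bruteforce(seq, kind, 10, max_hamming)


class TestMaskOverlaps:
    def test_duplicate_coordinates_collapse(self, rng):
        seq = random_dna(rng, 100)
        matches = find_repeats(seq, 8, 0, ("direct",))
        assert mask_overlaps(matches + matches) == mask_overlaps(matches)

    def test_nested_match_removed(self, rng):
        bg = random_dna(rng, 300)
        unit = bg[200:240]
        seq = bg[:80] + unit + bg[80:160] + unit + bg[160:200]
        matches = find_repeats(seq, min_len=12, max_hamming=0, kinds=("direct",))
        kept = mask_overlaps(matches)
        # nested shorter hits inside the 40-mer pair do not survive
        spans = [s for m in kept for s in (m.span1, m.span2)]
        for a in range(len(spans)):
            for b in range(a + 1, len(spans)):
                lo = max(spans[a][0], spans[b][0])
                hi = min(spans[a][1], spans[b][1])
                overlap = max(0, hi - lo + 1)
                assert overlap <= 0.5 * (spans[a][1] - spans[a][0] + 1) or (
                    overlap <= 0.5 * (spans[b][1] - spans[b][0] + 1)
                )

    def test_order_invariance(self, rng):
        seq = random_dna(rng, 400)
        matches = find_repeats(seq, 8, 1, ("direct", "revcomp"))
        shuffled = list(matches)
        np.random.default_rng(0).shuffle(shuffled)
        assert mask_overlaps(shuffled) == mask_overlaps(matches)


class TestClusterFamilies:
    def test_identical_plus_outlier(self):
        fams = cluster_families(["ACGTACGTACGTACGTACGT"] * 3 + ["TTGGCCAATTGGCCAATTGG"])
        assert sorted(f.copy_number for f in fams) == [1, 3]
        assert fams[0].copy_number == 3  # sorted by copy number desc

    def test_twenty_percent_divergence_separates(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACCTACGAACGTTCGTACGA"  # 4 subs in 20 nt
        fams = cluster_families([a, b], max_dissimilarity=0.15)
        assert len(fams) == 2

    def test_single_linkage_chains(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:18] + "GA"  # 2 subs from a (10%)
        c = b[:2] + "GA" + b[4:]  # 2 subs from b, 4 from a
        fams = cluster_families([a, b, c], max_dissimilarity=0.15)
        assert len(fams) == 1 and fams[0].copy_number == 3

    def test_members_compatible_with_consensus(self, rng):
        from fernbz._align import iupac_match

        base = random_dna(rng, 24)
        members = [base]
        for _ in range(4):
            chars = list(base)
            for pos in rng.choice(24, size=2, replace=False):
                chars[pos] = "ACGT"[int(rng.integers(4))]
            members.append("".join(chars))
        (fam,) = cluster_families(members, max_dissimilarity=0.15)
        assert len(fam.consensus) == 24
        for m in fam.members:
            matches = sum(iupac_match(c, b) for c, b in zip(fam.consensus, m))
            assert matches / 24 >= 0.85


class TestConsensusIupac:
    def test_identical_members(self):
        assert consensus_iupac(RepeatFamily(members=["ACGT", "ACGT"])) == "ACGT"

    def test_two_fold_ambiguity(self):
        assert consensus_iupac(RepeatFamily(members=["ACGT", "ATGT"])) == "AYGT"

    def test_wobble_and_purine_codes(self):
        # A/T wobble at cols 1,4 and A/G at col 6 across four members
        members = ["AACGTAAC", "TACGAAAC", "AACGTGAC", "TACGAGAC"]
        cons = consensus_iupac(RepeatFamily(members=members))
        assert cons == "WACGWRAC"

    def test_rare_residue_below_threshold_ignored(self):
        members = ["AAAA"] * 9 + ["CAAA"]  # C at 10% < 20% cutoff
        assert consensus_iupac(RepeatFamily(members=members)) == "AAAA"

    def test_mostly_gapped_column_dropped(self):
        members = ["ACGT", "ACGT", "ACGGGGT"]  # alignment pads with gaps
        cons = consensus_iupac(RepeatFamily(members=members))
        assert 4 <= len(cons) <= 5


class TestEndToEndFamilies:
    def test_planted_family_recovered(self, rng):
        unit = random_dna(rng, 27)
        pieces = []
        for _ in range(6):
            chars = list(unit)
            for pos in rng.choice(27, size=1):
                chars[pos] = "ACGT"[int(rng.integers(4))]
            pieces.append("".join(chars) + random_dna(rng, 40))
        seq = random_dna(rng, 60) + "".join(pieces) + random_dna(rng, 60)
        matches = find_repeats(seq, min_len=20, max_hamming=3, kinds=("direct",))
        masked = mask_overlaps(matches)
        spans = extract_span_seqs(seq, masked)
        fams = cluster_families(spans, max_dissimilarity=0.15)
        assert fams[0].copy_number >= 2
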