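import numpy as np
import pytest

from fernbz.seq_io import reverse_complement
from fernbz.simulate import HairpinSpec, SimConfig, simulate_region
from fernbz.stemloops import (
    StemLoopHit,
    aaa_signature,
    census,
    scan_stemloops,
    stem_family,
)

from ._oracles import stemloops_bruteforce
from .conftest import random_dna


def _hit(loop="CTGTAAA", arm5="GGA"):
    return StemLoopHit(
        start=1,
        stem_len=len(arm5),
        loop_seq=loop,
        arm5=arm5,
        arm3=reverse_complement(arm5),
    )


class TestScanner:
    def test_minimal_construct(self):
        hits = scan_stemloops("GGAAAAAAAATCC")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.stem_len, h.loop_seq) == (1, 3, "AAAAAAA")
        assert h.arm5 == "GGA" and h.arm3 == "TCC"

    def test_too_short_for_loop(self):
        assert scan_stemloops("GGATCC") == []

    def test_planted_hairpins_recovered_with_exact_stems(self):
        cfg = SimConfig(
            seed=5,
            region_len=2000,
            hairpins=tuple(HairpinSpec(stem_len=s, count=1) for s in range(3, 14)),
        )
        aseq, truth = simulate_region(cfg)
        found = {(h.start + h.stem_len, h.stem_len) for h in scan_stemloops(aseq.residues)}
        for planted in truth.hairpins:
            assert (planted["loop_start"], planted["stem_len"]) in found

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 600))
        seq = random_dna(rng, n, gc=float(rng.uniform(0.25, 0.6)))
        got = {(h.start, h.stem_len) for h in scan_stemloops(seq)}
        assert got == stemloops_bruteforce(seq, 7, 3)

    def test_reverse_complement_bijection(self, rng):
        seq = random_dna(rng, 800)
        fwd = scan_stemloops(seq)
        rev = scan_stemloops(reverse_complement(seq))
        n = len(seq)
        mirrored = {(n - h.end + 1, h.stem_len) for h in rev}
        assert {(h.start, h.stem_len) for h in fwd} == mirrored
        # a stem is its own reverse complement outside the loop, so the
        # proximal base-pair triplet — and hence the family key — is stable
        by_pos_f = {h.start: h for h in fwd}
        for h in rev:
            assert h.family_key == by_pos_f[n - h.end + 1].family_key


class TestSignatures:
    def test_aaa_sides(self):
        h = _hit(loop="CTGTAAA")
        assert aaa_signature(h, "loop3") is True
        assert aaa_signature(h, "loop5") is False
        h2 = _hit(loop="AAACTGT")
        assert aaa_signature(h2, "loop3") is False
        assert aaa_signature(h2, "either") is True

    def test_trny_anticodon_analog(self):
        # anticodon arm of trnY: GGA/TCC stem core, 7-nt loop ending in AAA
        arm = "CAGGA" + "TGTAAAA" + "TCCTG"
        hits = scan_stemloops("T" + arm + "G")
        h = max(hits, key=lambda h: h.stem_len)
        assert h.stem_len == 5
        assert aaa_signature(h, "loop3") is True
        assert stem_family(h) == "GGA/TCC"

    def test_family_keys(self):
        assert _hit(arm5="TGGA").family_key == "GGA/TCC"
        assert _hit(arm5="TGAA").family_key == "GAA/TTC"

    def test_planted_family_multiset(self):
        cfg = SimConfig(
            seed=9,
            region_len=3000,
            hairpins=(HairpinSpec(stem_len=6, count=8),),
        )
        aseq, truth = simulate_region(cfg)
        hits = scan_stemloops(aseq.residues)
        by_loop_start = {h.start + h.stem_len: h for h in hits}
        for planted in truth.hairpins:
            h = by_loop_start[planted["loop_start"]]
            arm5 = aseq.residues[planted["start"] - 1 : planted["start"] - 1 + 6]
            assert h.family_key == f"{arm5[-3:]}/{reverse_complement(arm5[-3:])}"


class TestCensus:
    def test_fraction_single_hit(self):
        h = StemLoopHit(start=11, stem_len=5, loop_seq="CTGTAAA",
                        arm5="ACGTT", arm3="AACGT")
        cen = census([h], region_len=85)
        assert cen.covered_nt == 17
        assert cen.fraction == 17 / 85
        assert cen.histogram == {5: 1}

    def test_union_vs_sum_coverage(self):
        a = StemLoopHit(start=1, stem_len=3, loop_seq="CTGTAAA", arm5="GGA", arm3="TCC")
        b = StemLoopHit(start=1, stem_len=3, loop_seq="CTGTAAA", arm5="GGA", arm3="TCC")
        union = census([a, b], region_len=100, coverage="union")
        total = census([a, b], region_len=100, coverage="sum")
        assert union.covered_nt == 13
        assert total.covered_nt == 26

    def test_region_shorter_than_hits_rejected(self):
        h = StemLoopHit(start=95, stem_len=3, loop_seq="CTGTAAA", arm5="GGA", arm3="TCC")
        with pytest.raises(ValueError):
            census([h], region_len=100)

    def test_aaa_census_never_exceeds_unrestricted(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seq = random_dna(rng, 1500, gc=0.33)
            hits = scan_stemloops(seq)
            full = census(hits, len(seq))
            aaa = census(hits, len(seq), require_aaa=True)
            assert aaa.total <= full.total
            assert aaa.covered_nt <= full.covered_nt


class TestCoverageRecovery:
    def test_planted_coverage_recovered_within_three_points(self):
        # planted AAA-hairpin coverage vs AAA census estimate, 20 seeds
        deltas = []
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                region_len=4000,
                hairpins=(
                    HairpinSpec(stem_len=3, count=12),
                    HairpinSpec(stem_len=6, count=10),
                    HairpinSpec(stem_len=8, count=8),
                    HairpinSpec(stem_len=13, count=2),
                ),
            )
            aseq, truth = simulate_region(cfg)
            planted_nt = sum(h["end"] - h["start"] + 1 for h in truth.hairpins)
            cen = census(
                scan_stemloops(aseq.residues),
                len(aseq),
                require_aaa=True,
                coverage="sum",
            )
            deltas.append(100 * abs(cen.fraction - planted_nt / len(aseq)))
        assert max(deltas) <= 3.0
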