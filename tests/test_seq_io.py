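import warnings

import pytest

from fernbz.seq_io import (
    AnnotatedSequence,
    Feature,
    extract_gene_order,
    extract_igs,
    locus_to_symbol,
    read_fasta,
    read_feature_table,
    reverse_complement,
    write_feature_table,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record_uppercased(self, tmp_path):
        recs = read_fasta(_write(tmp_path, "a.fa", ">x\nacgt\n"))
        assert len(recs) == 1
        assert recs[0].seq_id == "x"
        assert recs[0].residues == "ACGT"

    def test_rna_normalised_to_dna(self, tmp_path):
        recs = read_fasta(_write(tmp_path, "a.fa", ">x\nACGU\n"))
        assert recs[0].residues == "ACGT"

    def test_multi_record_order_preserved(self, tmp_path):
        recs = read_fasta(
            _write(tmp_path, "a.fa", ">a\nAAAA\n>b\nCCCC\n>c\nGGGG\n")
        )
        assert [r.seq_id for r in recs] == ["a", "b", "c"]

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_fasta(_write(tmp_path, "a.fa", ""))


class TestFeatureTable:
    HEADER = "locus\tkind\tstrand\tstart\tend\n"

    def test_roundtrip_and_span(self, tmp_path):
        feats = read_feature_table(
            _write(tmp_path, "f.tsv", self.HEADER + "trnY-GUA\ttRNA\t-\t101\t184\n")
        )
        assert feats == [Feature("trnY-GUA", "tRNA", "-", 101, 184)]
        assert feats[0].length == 84
        out = tmp_path / "out.tsv"
        write_feature_table(feats, out)
        assert read_feature_table(out) == feats

    def test_unicode_minus_strand_accepted(self, tmp_path):
        feats = read_feature_table(
            _write(tmp_path, "f.tsv", self.HEADER + "trnD-GUC\ttRNA\t−\t5\t10\n")
        )
        assert feats[0].strand == "-"

    def test_start_after_end_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="start"):
            read_feature_table(
                _write(tmp_path, "f.tsv", self.HEADER + "rpoB\tgene\t+\t50\t10\n")
            )

    def test_nine_locus_table_maps_to_symbols(self, tmp_path):
        rows = [
            ("rpoB", "gene", "+", 1, 10),
            ("trnC-GCA", "tRNA", "+", 21, 30),
            ("petN", "gene", "-", 41, 50),
            ("psbM", "gene", "-", 61, 70),
            ("trnD-GUC", "tRNA", "-", 81, 90),
            ("trnY-GUA", "tRNA", "+", 101, 110),
            ("trnE-UUC", "tRNA", "+", 121, 130),
            ("trnG-GCC", "tRNA", "+", 141, 150),
            ("psbZ", "gene", "+", 161, 170),
        ]
        text = self.HEADER + "".join(
            f"{l}\t{k}\t{s}\t{a}\t{b}\n" for l, k, s, a, b in rows
        )
        feats = read_feature_table(_write(tmp_path, "f.tsv", text))
        assert [locus_to_symbol(f.locus) for f in feats] == list("BCNMDYEGZ")


def _record(order_rows, length):
    feats = [Feature(*row) for row in order_rows]
    seq = "".join(
        "ACGT"[(i + 1) % 4] for i in range(length)
    )  # deterministic non-uniform
    return AnnotatedSequence("rec", seq, feats)


class TestExtractIgs:
    def test_interior_spacer(self):
        rec = _record([("geneA", "gene", "+", 1, 10), ("geneB", "gene", "+", 31, 40)], 40)
        # geneA/geneB are not BZ loci; use explicit locus strings
        igs = extract_igs(rec, "geneA", "geneB")
        assert (igs.start, igs.end, igs.length) == (11, 30, 20)
        assert igs.residues == rec.residues[10:30]

    def test_abutting_genes_zero_length_with_warning(self):
        rec = _record([("geneA", "gene", "+", 1, 10), ("geneB", "gene", "+", 11, 20)], 20)
        with pytest.warns(UserWarning, match="abut"):
            igs = extract_igs(rec, "geneA", "geneB")
        assert igs.length == 0
        assert igs.residues == ""

    def test_argument_order_irrelevant(self):
        rec = _record([("geneA", "gene", "+", 1, 10), ("geneB", "gene", "+", 31, 40)], 40)
        a = extract_igs(rec, "geneA", "geneB")
        b = extract_igs(rec, "geneB", "geneA")
        assert (a.start, a.end) == (b.start, b.end)

    def test_missing_locus_raises(self):
        rec = _record([("geneA", "gene", "+", 1, 10)], 20)
        with pytest.raises(KeyError):
            extract_igs(rec, "geneA", "geneX")

    def test_strand_symmetry(self):
        rec = _record([("geneA", "gene", "+", 1, 10), ("geneB", "gene", "+", 31, 40)], 40)
        fwd = extract_igs(rec, "geneA", "geneB")
        rev = extract_igs(rec.reverse_complemented(), "geneA", "geneB")
        assert rev.length == fwd.length
        assert rev.residues == reverse_complement(fwd.residues)

    def test_gene_and_igs_spans_tile_the_region(self):
        rows = [
            ("geneA", "gene", "+", 5, 14),
            ("geneB", "gene", "+", 20, 29),
            ("geneC", "gene", "+", 33, 40),
        ]
        rec = _record(rows, 45)
        covered = []
        for f in rec.features:
            covered.append((f.start, f.end))
        for left, right in [("geneA", "geneB"), ("geneB", "geneC")]:
            igs = extract_igs(rec, left, right)
            if igs.length:
                covered.append((igs.start, igs.end))
        covered.sort()
        # exact tiling of [first feature start, last feature end]
        assert covered[0][0] == 5 and covered[-1][1] == 40
        for (a, b), (c, d) in zip(covered, covered[1:]):
            assert c == b + 1


class TestExtractGeneOrder:
    ROWS = [
        ("rpoB", "gene", "+", 1, 100),
        ("trnC-GCA", "tRNA", "+", 111, 180),
        ("petN", "gene", "-", 191, 260),
        ("psbM", "gene", "-", 271, 340),
        ("trnD-GUC", "tRNA", "-", 351, 420),
        ("trnY-GUA", "tRNA", "+", 431, 500),
        ("trnE-UUC", "tRNA", "+", 511, 580),
        ("trnG-GCC", "tRNA", "+", 591, 660),
        ("psbZ", "gene", "+", 671, 740),
    ]

    def test_signed_order_with_inverted_trnD(self):
        rec = _record(self.ROWS, 740)
        order = extract_gene_order(rec)
        assert str(order) == "B,C,-N,-M,-D,Y,E,G,Z"

    def test_invariant_under_reverse_complement(self):
        rec = _record(self.ROWS, 740)
        assert extract_gene_order(rec) == extract_gene_order(
            rec.reverse_complemented()
        )

    def test_unmappable_locus_reported(self):
        rows = self.ROWS[:4] + [("mysteryORF", "gene", "+", 345, 348)] + self.ROWS[4:]
        rec = _record(rows, 740)
        with pytest.raises(KeyError, match="mysteryORF"):
            extract_gene_order(rec)
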