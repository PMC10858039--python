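"""Panel construction: detection, canonicalization, filtering, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from estrpipe.errors import ParseError
from estrpipe.panel import (
    StrLocus,
    annotate_regions,
    apply_mask,
    build_panel,
    canonical_motif,
    detect_perfect_strs,
    is_primitive,
    load_gene_models,
    proximity_filter,
    resolve_redundancy,
    reverse_complement,
)

from helpers_oracles import brute_force_strs


def _locus(start, motif, units, chrom="chr1", region="unlabelled"):
    return StrLocus(
        chrom=chrom,
        start=start,
        end=start + len(motif) * units,
        motif=canonical_motif(motif),
        unit_size=len(motif),
        ref_length=units,
        region=region,
    )


class TestDetector:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("A" * 9, [(0, 9, 1)]),  # mononucleotide threshold: nine units
            ("A" * 8, []),
            ("AC" * 4, [(0, 8, 2)]),  # dinucleotide threshold: four units
            ("AC" * 3, []),
            ("ACG" * 4, [(0, 12, 3)]),
            ("ACG" * 3, []),
            ("ACGT" * 3, [(0, 12, 4)]),
            ("ACGT" * 2, []),
            ("ACGTA" * 3, [(0, 15, 5)]),
            ("ACGTAC" * 3, [(0, 18, 6)]),
            ("", []),
        ],
    )
    def test_minimum_length_thresholds(self, seq, expected):
        loci = detect_perfect_strs(seq)
        assert [(l.start, l.end, l.unit_size) for l in loci] == expected

    def test_run_broken_at_n(self):
        seq = "A" * 9 + "N" + "A" * 9
        loci = detect_perfect_strs(seq)
        assert [(l.start, l.end) for l in loci] == [(0, 9), (10, 19)]

    def test_partial_trailing_unit_is_trimmed(self):
        # nine full AC units plus a dangling A: span covers whole units only
        loci = detect_perfect_strs("AC" * 9 + "A")
        assert [(l.start, l.end, l.ref_length) for l in loci] == [(0, 18, 9)]

    def test_non_primitive_motifs_not_double_reported(self):
        loci = detect_perfect_strs("AC" * 8)
        assert len(loci) == 1 and loci[0].unit_size == 2

    def test_rejects_invalid_characters(self):
        with pytest.raises(ValueError):
            detect_perfect_strs("ACGTX")

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=300, p=[0.4, 0.2, 0.2, 0.2]))
            got = {(l.start, l.end, l.unit_size) for l in detect_perfect_strs(seq)}
            assert got == brute_force_strs(seq)

    def test_oracle_agreement_on_repeat_dense_sequence(self):
        rng = np.random.default_rng(7)
        parts = []
        for _ in range(40):
            motif = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            parts.append(motif * int(rng.integers(2, 14)))
            parts.append("".join(rng.choice(list("ACGTN"), size=rng.integers(1, 9))))
        seq = "".join(parts)
        got = {(l.start, l.end, l.unit_size) for l in detect_perfect_strs(seq)}
        assert got == brute_force_strs(seq)


MOTIFS = st.text(alphabet="ACGT", min_size=1, max_size=6).filter(is_primitive)


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected", [("A", "A"), ("TTC", "AAG"), ("AT", "AT"), ("GT", "AC")]
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            canonical_motif("ACX")

    @settings(deadline=None)
    @given(MOTIFS)
    def test_idempotent(self, motif):
        canon = canonical_motif(motif)
        assert canonical_motif(canon) == canon

    @settings(deadline=None)
    @given(MOTIFS)
    def test_strand_invariant(self, motif):
        assert canonical_motif(reverse_complement(motif)) == canonical_motif(motif)

    @settings(deadline=None)
    @given(MOTIFS, st.integers(0, 5))
    def test_rotation_invariant(self, motif, shift):
        shift %= len(motif)
        rotated = motif[shift:] + motif[:shift]
        assert canonical_motif(rotated) == canonical_motif(motif)


class TestResolveRedundancy:
    def test_smaller_unit_size_wins(self):
        mono = _locus(0, "A", 12)
        di = StrLocus("chr1", 0, 12, "AT", 2, 6)
        assert resolve_redundancy([di, mono]) == [mono]

    def test_disjoint_loci_both_kept(self):
        a, b = _locus(0, "A", 12), _locus(100, "AC", 6)
        assert resolve_redundancy([a, b]) == [a, b]

    def test_equal_unit_size_longer_span_wins(self):
        long = _locus(0, "AC", 6)  # 12 bp
        short = StrLocus("chr1", 4, 14, "AG", 2, 5)  # 10 bp, overlapping
        assert resolve_redundancy([short, long]) == [long]


class TestProximityFilter:
    def test_close_pair_both_removed(self):
        a, b = _locus(0, "A", 10), _locus(20, "AC", 5)  # 10 bp gap
        assert proximity_filter([a, b]) == []

    def test_distant_pair_kept(self):
        a, b = _locus(0, "A", 10), _locus(110, "AC", 5)  # 100 bp gap
        assert proximity_filter([a, b]) == [a, b]

    def test_boundary_gap_inclusive(self):
        a = _locus(0, "A", 10)
        exactly = _locus(60, "AC", 5)  # gap exactly 50 bp
        just_over = _locus(61, "AC", 5)  # gap 51 bp
        assert proximity_filter([a, exactly]) == []
        assert proximity_filter([a, just_over]) == [a, just_over]

    def test_idempotent_with_detection(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=5000, p=[0.45, 0.2, 0.15, 0.2]))
        once = proximity_filter(resolve_redundancy(detect_perfect_strs(seq)))
        twice = proximity_filter(resolve_redundancy(once))
        assert once == twice


def _gene_frame(rows):
    return pd.DataFrame(
        rows, columns=["feature", "chrom", "start", "end", "strand", "gene_id"]
    )


class TestAnnotateRegions:
    models = _gene_frame(
        [
            ("gene", "chr1", 10000, 20000, "+", "GENE1"),
            ("CDS", "chr1", 12000, 12500, "+", "GENE1"),
            ("UTR", "chr1", 10000, 10200, "+", "GENE1"),
        ]
    )

    def test_intron_label(self):
        loci = annotate_regions([_locus(15000, "A", 10)], self.models)
        assert loci[0].region == "intron"

    def test_promoter_within_5kb_upstream(self):
        loci = annotate_regions([_locus(9000, "A", 10)], self.models)
        assert loci[0].region == "promoter"

    def test_promoter_window_boundary(self):
        inside = _locus(5000, "A", 10)  # overlaps [5000, 10000) promoter
        outside = _locus(4990, "A", 10)  # ends exactly at 5000: no overlap
        got = annotate_regions([inside, outside], self.models)
        assert [(l.start, l.region) for l in got] == [(5000, "promoter")]

    def test_cds_priority_over_intron(self):
        # locus straddling the CDS/intron boundary gets the CDS label
        loci = annotate_regions([_locus(12490, "A", 20)], self.models)
        assert loci[0].region == "CDS"

    def test_utr_label(self):
        loci = annotate_regions([_locus(10100, "A", 10)], self.models)
        assert loci[0].region == "UTR"

    def test_intergenic_dropped(self):
        assert annotate_regions([_locus(50000, "A", 10)], self.models) == []

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        models = _gene_frame([("gene", "chr1", 10000, 20000, "-", "G")])
        loci = annotate_regions([_locus(21000, "A", 10)], models)
        assert loci[0].region == "promoter"


class TestApplyMask:
    def test_masked_locus_removed(self):
        assert apply_mask([_locus(100, "A", 10)], mask=[("chr1", 105, 200)]) == []

    def test_non_autosome_removed(self):
        assert apply_mask([_locus(100, "A", 10, chrom="chrX")]) == []

    def test_empty_mask_unchanged(self):
        loci = [_locus(100, "A", 10)]
        assert apply_mask(loci) == loci


class TestGffIO:
    def test_malformed_gff_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t100\t.\t+\t.\n")
        with pytest.raises(ParseError, match="line 2"):
            load_gene_models(str(path))

    def test_non_integer_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr1\tsrc\tgene\tone\t100\t.\t+\t.\tID=g1\n")
        with pytest.raises(ParseError, match="line 1"):
            load_gene_models(str(path))

    def test_roundtrip_through_gff3(self, tmp_path):
        from estrpipe.simulate import write_gene_models_gff3

        models = _gene_frame([("gene", "chr1", 10000, 20000, "+", "GENE1")])
        path = tmp_path / "genes.gff3"
        write_gene_models_gff3(models, str(path))
        loaded = load_gene_models(str(path))
        gene = loaded[loaded["feature"] == "gene"].iloc[0]
        assert (gene["start"], gene["end"], gene["gene_id"]) == (10000, 20000, "GENE1")


def test_build_panel_end_to_end(tmp_path):
    rng = np.random.default_rng(11)
    background = "".join(rng.choice(list("ACGT"), size=2000))
    seq = background[:500] + "A" * 15 + "C" + background[500:1000] + "AG" * 8 + background[1000:]
    models = _gene_frame([("gene", "chr1", 0, len(seq), "+", "G1")])
    panel = build_panel({"chr1": seq}, models)
    spans = {(l.start, l.end) for l in panel}
    assert (500, 515) in spans
    assert all(l.region != "unlabelled" for l in panel)
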