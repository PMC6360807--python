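"""Exon selection, splice-relative annotation and consensus composition."""

import numpy as np
import pandas as pd
import pytest

from splicesel import (
    ExonRecord, LABELS, POLYPY_LABELS, annotate_positions, classify_change,
    composition_matrix, parse_gtf_exons, select_exons,
)
from splicesel.rates import revcomp


def _exon(**kw):
    base = dict(chrom="chr1", start=101, end=250, strand="+", gene_id="G1",
                transcript_id="G1.T1", level="2", tags=frozenset({"CCDS"}))
    base.update(kw)
    return ExonRecord(**base)


def _depth(e, dacc, ddon, capture="V3"):
    return {"chrom": e.chrom, "start": e.start, "end": e.end, "strand": e.strand,
            "capture": capture, "depth_acc": dacc, "depth_don": ddon}


class TestSelectExons:
    def test_qualifying_exon_is_kept_with_good_depth(self):
        e = _exon()
        out = select_exons([e], pd.DataFrame([_depth(e, 20, 22)]))
        assert len(out) == 1

    @pytest.mark.parametrize("kw", [
        {"level": "3"},
        {"gene_type": "lincRNA"},
        {"transcript_type": "retained_intron"},
        {"gene_status": "NOVEL"},
        {"transcript_status": "PUTATIVE"},
        {"tags": frozenset({"basic"})},
        {"end": 113},  # 13 bp exon
    ])
    def test_disqualifying_annotations_drop_the_exon(self, kw):
        assert len(select_exons([_exon(**kw)])) == 0

    def test_minimum_length_boundary(self):
        assert len(select_exons([_exon(end=114)])) == 1  # exactly 14 bp

    def test_low_depth_at_either_end_in_any_capture_drops_the_exon(self):
        e = _exon()
        assert len(select_exons([e], pd.DataFrame([_depth(e, 14, 30)]))) == 0
        assert len(select_exons([e], pd.DataFrame([_depth(e, 30, 14.9)]))) == 0
        two = pd.DataFrame([_depth(e, 30, 30, "V3"), _depth(e, 15, 14, "V5")])
        assert len(select_exons([e], two)) == 0
        ok = pd.DataFrame([_depth(e, 15, 15, "V3"), _depth(e, 16, 99, "V5")])
        assert len(select_exons([e], ok)) == 1

    def test_duplicate_exons_are_merged_with_tags_unioned(self):
        a = _exon(tags=frozenset({"basic"}), transcript_id="T1")
        b = _exon(tags=frozenset({"appris_principal"}), transcript_id="T2")
        out = select_exons([a, b])
        assert len(out) == 1
        assert "appris_principal" in out.iloc[0]["tags"]
        assert set(out.iloc[0]["transcripts"].split(";")) == {"T1", "T2"}

    def test_malformed_gtf_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tsim\texon\t10\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_gtf_exons(p)

    def test_gtf_round_trip_preserves_repeated_tags(self, tmp_path, study):
        p = tmp_path / "sim.gtf"
        study.genome.write_gtf(p)
        recs = parse_gtf_exons(p)
        assert any(len(r.tags) >= 2 for r in recs)
        assert {r.level for r in recs} >= {"2", "3"}


def _toy_genome(seq):
    return {"chr1": seq}


class TestAnnotatePositions:
    def test_plus_strand_labels_are_definitional(self):
        seq = "".join("ACGT"[(i * 7) % 4] for i in range(400))
        ex = pd.DataFrame([{"chrom": "chr1", "start": 101, "end": 200,
                            "strand": "+", "gene": "G1"}])
        pos = annotate_positions(ex, _toy_genome(seq))
        lab = pos.set_index("pos")["label"]
        assert lab[101] == "acc"
        assert lab[100] == "acc-1"
        assert lab[200] == "don"
        assert lab[205] == "don+5"
        assert lab[111] == "acc+10"
        assert lab[190] == "don-10"

    def test_minus_strand_labels_mirror(self):
        seq = "".join("ACGT"[(i * 5) % 4] for i in range(400))
        ex = pd.DataFrame([{"chrom": "chr1", "start": 101, "end": 200,
                            "strand": "-", "gene": "G1"}])
        pos = annotate_positions(ex, _toy_genome(seq))
        lab = pos.set_index("pos")["label"]
        assert lab[200] == "acc"
        assert lab[201] == "acc-1"
        assert lab[101] == "don"
        assert lab[96] == "don+5"

    def test_minus_strand_equals_reverse_complemented_plus_annotation(self):
        """Brute-force oracle: annotating a minus-strand exon must equal
        annotating the reverse-complemented locus as plus strand."""
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        start, end = 130, 260
        L = len(seq)
        minus = annotate_positions(
            pd.DataFrame([{"chrom": "chr1", "start": start, "end": end,
                           "strand": "-", "gene": "G"}]),
            _toy_genome(seq))
        rc_start, rc_end = L - end + 1, L - start + 1
        plus = annotate_positions(
            pd.DataFrame([{"chrom": "chr1", "start": rc_start, "end": rc_end,
                           "strand": "+", "gene": "G"}]),
            _toy_genome(revcomp(seq)))
        remapped = {L - p + 1: l for p, l in zip(plus["pos"], plus["label"])}
        assert dict(zip(minus["pos"], minus["label"])) == remapped
        tx_plus = {L - p + 1: b for p, b in zip(plus["pos"], plus["tx_ref"])}
        assert dict(zip(minus["pos"], minus["tx_ref"])) == tx_plus

    def test_short_exon_positions_with_two_labels_are_dropped(self):
        seq = "A" * 400
        ex = pd.DataFrame([{"chrom": "chr1", "start": 101, "end": 115,
                            "strand": "+", "gene": "G1"}])  # 15 bp
        pos = annotate_positions(ex, _toy_genome(seq))
        # acc+4..acc+10 coincide with don-10..don-4: all dropped
        inside = pos[(pos["pos"] >= 105) & (pos["pos"] <= 111)]
        assert len(inside) == 0
        assert set(pos["pos"]).isdisjoint(range(105, 112))
        # unambiguous positions survive
        assert (pos["pos"] == 101).any() and (pos["pos"] == 115).any()

    def test_positions_outside_contig_are_dropped_with_warning(self):
        seq = "A" * 120
        ex = pd.DataFrame([{"chrom": "chr1", "start": 20, "end": 110,
                            "strand": "+", "gene": "G1"}])
        with pytest.warns(UserWarning, match="outside contig"):
            pos = annotate_positions(ex, _toy_genome(seq))
        assert pos["pos"].min() >= 2
        assert pos["pos"].max() <= 119

    def test_every_label_is_in_the_vocabulary_and_positions_unique(self, study):
        pos = study.positions
        assert set(pos["label"]) <= set(LABELS)
        assert not pos.duplicated(["chrom", "pos"]).any()


class TestClassifyChange:
    def test_polypy_pyrimidine_to_purine(self):
        assert classify_change("acc-8", "+", "C", "A") == "polypy_PyPu"

    def test_polypy_pyrimidine_to_pyrimidine_is_other(self):
        assert classify_change("acc-8", "+", "C", "T") == "polypy_other"

    def test_minus_strand_complements_before_classifying(self):
        # genomic G>T at a minus-strand polypy position is transcript C>A
        assert classify_change("acc-10", "-", "G", "T") == "polypy_PyPu"
        assert classify_change("acc-10", "-", "G", "A") == "polypy_other"

    @pytest.mark.parametrize("label", ["acc-2", "acc-1", "don+1", "don+2"])
    def test_canonical_dinucleotides(self, label):
        assert classify_change(label, "+", "A", "G") == "CSS"

    def test_other_labels_classify_as_themselves(self):
        assert classify_change("don+5", "+", "G", "A") == "don+5"
        assert classify_change(None, "+", "G", "A") == "non-splice"

    def test_bad_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_change("acc-8", "+", "N", "A")
        with pytest.raises(ValueError):
            classify_change("acc-8", "+", "C", "C")


class TestCompositionMatrix:
    def test_columns_are_stochastic_and_consensus_degenerate(self, study):
        mat, consensus = composition_matrix(study.positions)
        np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-12)
        assert mat.loc["G", "don+1"] == 1.0
        assert mat.loc["T", "don+2"] == 1.0
        assert mat.loc["A", "acc-2"] == 1.0
        assert mat.loc["G", "acc-1"] == 1.0

    def test_polypy_columns_are_pyrimidine_rich(self, study):
        mat, _ = composition_matrix(study.positions)
        for label in POLYPY_LABELS:
            if label in mat.columns:
                assert mat.loc[["C", "T"], label].sum() > 0.7

    def test_empty_label_columns_are_omitted_with_warning(self, study):
        few = study.positions[study.positions["label"].isin(["don+1", "don+2"])]
        with pytest.warns(UserWarning, match="empty label"):
            mat, consensus = composition_matrix(few)
        assert list(mat.columns) == ["don+1", "don+2"]
        assert consensus == "GT"
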