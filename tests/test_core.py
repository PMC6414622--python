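"""Domain types, table readers/writers and chromosome summarization."""

import pytest
from hypothesis import given, settings, strategies as st

from clonevo import (CNASegment, SchemaError, ValidationError, VariantCall,
                     summarize_chromosomes)
from clonevo.io import (read_segment_table, read_variant_table,
                        write_segment_table, write_variant_table)
from conftest import make_variant

HEADER = "patient_id\tchrom\tpos\tref\talt\tgene\teffect\talt_id\tdepth_id\talt_rel\tdepth_rel\n"


def _write(tmp_path, body, name="v.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestVariantTable:
    def test_vafs_recomputed_from_counts(self, tmp_path):
        path = _write(tmp_path,
                      "P1\t1\t100\tA\tT\tKRAS\tmissense\t9\t20\t9\t20\n"
                      "P1\t2\t200\tC\tG\tTP53\tnonsense\t0\t30\t0\t30\n"
                      "P1\t3\t300\tG\tA\tNRAS\tsilent\t2\t25\t2\t25\n")
        records = read_variant_table(path)
        assert [v.vaf_id for v in records] == [0.45, 0.0, 0.08]

    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_variant_table(_write(tmp_path, "")) == []

    def test_alt_exceeding_depth_is_reported_with_row(self, tmp_path):
        path = _write(tmp_path, "P1\t1\t100\tA\tT\tKRAS\tmissense\t21\t20\t0\t20\n")
        with pytest.raises(ValidationError, match="row 1"):
            read_variant_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER.replace("\tgene", ""))
        with pytest.raises(SchemaError, match="gene"):
            read_variant_table(path)

    def test_roundtrip_and_unicode_gene(self, tmp_path):
        records = [make_variant(pos=10, gene="HÖX-α1", alt_id=5),
                   make_variant(pos=20, chrom="X", alt_id=9, alt_rel=12)]
        path = tmp_path / "out.tsv"
        write_variant_table(records, path)
        assert sorted(read_variant_table(path), key=lambda v: v.sort_key()) \
            == sorted(records, key=lambda v: v.sort_key())

    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_variant_table([], path)
        assert read_variant_table(path) == []
        assert path.read_text().count("\n") == 1

    @settings(max_examples=50, deadline=None)
    @given(rows=st.lists(st.tuples(st.integers(1, 5), st.integers(0, 200),
                                   st.integers(0, 200)), max_size=20))
    def test_roundtrip_property(self, rows, tmp_path_factory):
        cohort = []
        seen = set()
        for chrom, alt, depth in rows:
            pos = len(seen) * 17 + 1
            seen.add(pos)
            cohort.append(make_variant(chrom=str(chrom), pos=pos,
                                       alt_id=min(alt, depth), depth_id=depth,
                                       alt_rel=min(alt, depth), depth_rel=depth))
        path = tmp_path_factory.mktemp("rt") / "c.tsv"
        write_variant_table(cohort, path)
        assert sorted(read_variant_table(path), key=lambda v: v.sort_key()) \
            == sorted(cohort, key=lambda v: v.sort_key())


class TestVariantInvariants:
    def test_vaf_zero_when_depth_zero(self):
        v = make_variant(alt_id=0, depth_id=0)
        assert v.vaf_id == 0.0

    def test_position_must_be_positive(self):
        with pytest.raises(ValidationError):
            make_variant(pos=0)

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValidationError):
            make_variant(effect="nonsense_mediated")


class TestVcfDialect:
    def test_vcf_matches_tsv_equivalent(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="e">\n'
            '##INFO=<ID=PATIENT,Number=1,Type=String,Description="p">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tID\tREL\n"
            "1\t100\t.\tA\tT\t.\t.\tGENE=KRAS;EFFECT=missense;PATIENT=P1\tAD\t11,9\t12,8\n")
        path = tmp_path / "two_sample.vcf"
        path.write_text(vcf_text)
        (v,) = read_variant_table(path, dialect="vcf")
        assert (v.patient_id, v.gene, v.alt_id, v.depth_id,
                v.alt_rel, v.depth_rel) == ("P1", "KRAS", 9, 20, 8, 20)
        assert v.vaf_id == 0.45


class TestSegments:
    def test_bed_dialect_start_converted(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("patient_id\ttimepoint\tchrom\tstart\tend\tstate\tgene_overlaps\n"
                        "P1\tID\t9\t0\t1000\tloss_het\tCDKN2A;CDKN2B\n")
        (seg,) = read_segment_table(path, zero_based=True)
        assert (seg.start, seg.end) == (1, 1000)
        assert seg.gene_overlaps == ("CDKN2A", "CDKN2B")

    def test_segment_roundtrip(self, tmp_path):
        segs = [CNASegment("P1", "REL", "9", 100, 5000, "loss_hom", ("CDKN2A",)),
                CNASegment("P1", "ID", "21", 1, 48129895, "gain")]
        path = tmp_path / "s.tsv"
        write_segment_table(segs, path)
        assert sorted(read_segment_table(path), key=lambda s: s.chrom) \
            == sorted(segs, key=lambda s: s.chrom)


class TestSummarizeChromosomes:
    LENGTHS = {"2": 1000, "4": 1000, "21": 1000}

    def test_single_segment_at_95_percent_calls_gain(self):
        segs = [CNASegment("P1", "ID", "21", 1, 950, "gain")]
        states = {s.chrom: s.whole_chrom_state
                  for s in summarize_chromosomes(segs, self.LENGTHS)}
        assert states["21"] == "gain"

    def test_union_of_two_segments_reaches_threshold(self):
        segs = [CNASegment("P1", "ID", "4", 1, 500, "gain"),
                CNASegment("P1", "ID", "4", 501, 950, "gain")]
        states = {s.chrom: s.whole_chrom_state
                  for s in summarize_chromosomes(segs, self.LENGTHS)}
        assert states["4"] == "gain"

    def test_chromosome_without_segments_is_neutral(self):
        segs = [CNASegment("P1", "ID", "21", 1, 950, "gain")]
        states = {s.chrom: s.whole_chrom_state
                  for s in summarize_chromosomes(segs, self.LENGTHS)}
        assert states["2"] == "neutral"

    def test_exactly_one_state_per_chromosome(self):
        segs = [CNASegment("P1", "ID", "21", 1, 950, "gain"),
                CNASegment("P1", "REL", "2", 1, 999, "loss_het")]
        states = summarize_chromosomes(segs, self.LENGTHS)
        keys = [(s.patient_id, s.timepoint, s.chrom) for s in states]
        assert len(keys) == len(set(keys)) == 2 * len(self.LENGTHS)

    def test_contradictory_overlap_raises(self):
        segs = [CNASegment("P1", "ID", "4", 1, 600, "gain"),
                CNASegment("P1", "ID", "4", 400, 950, "loss_het")]
        with pytest.raises(ValidationError, match="overlap"):
            summarize_chromosomes(segs, self.LENGTHS)

    def test_loss_het_and_loss_hom_share_a_class(self):
        segs = [CNASegment("P1", "ID", "2", 1, 500, "loss_het"),
                CNASegment("P1", "ID", "2", 450, 950, "loss_hom")]
        states = {s.chrom: s.whole_chrom_state
                  for s in summarize_chromosomes(segs, self.LENGTHS)}
        assert states["2"] == "loss"
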