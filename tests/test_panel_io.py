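import pytest
from hypothesis import given, settings, strategies as st

from domestiscan.errors import AlignmentError, MetadataError
from domestiscan.panel_io import (
    AccessionMeta,
    Panel,
    column_to_upstream,
    read_panel,
    upstream_to_column,
    write_panel,
    write_variant_table,
    read_variant_table,
    write_vcf,
)
from domestiscan.variants import segregating_sites


def _write_inputs(tmp_path, records, meta_rows):
    fa = tmp_path / "a.fa"
    fa.write_text("".join(f">{i}\n{s}\n" for i, s in records))
    tsv = tmp_path / "m.tsv"
    lines = ["id\tgroup\tphenotype\torigin"]
    lines += [f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3] if len(r) > 3 else ''}" for r in meta_rows]
    tsv.write_text("\n".join(lines) + "\n")
    return fa, tsv


class TestReadPanel:
    def test_well_formed(self, tmp_path):
        fa, tsv = _write_inputs(
            tmp_path,
            [("W1", "ACGTACGTAC"), ("W2", "ACGTACGTAC"), ("C1", "ACGTTCGTAC")],
            [("W1", "wild", "spread", "China"), ("W2", "wild", "spread"),
             ("C1", "cultivated", "compact")],
        )
        panel = read_panel(fa, tsv, 13300)
        assert panel.length == 10
        assert len(panel.ids) == 3
        assert panel.meta_of("W1").origin == "China"
        assert panel.members("cultivated") == ["C1"]

    def test_length_mismatch_is_alignment_error(self, tmp_path):
        fa, tsv = _write_inputs(
            tmp_path,
            [("W1", "ACGTACGTAC"), ("C1", "ACGTACGTA")],
            [("W1", "wild", "spread"), ("C1", "cultivated", "compact")],
        )
        with pytest.raises(AlignmentError):
            read_panel(fa, tsv, 13300)

    def test_missing_metadata_names_the_accession(self, tmp_path):
        fa, tsv = _write_inputs(
            tmp_path,
            [("W22", "ACGT"), ("C1", "ACGT")],
            [("C1", "cultivated", "compact")],
        )
        with pytest.raises(MetadataError, match="W22"):
            read_panel(fa, tsv, 13300)

    def test_duplicate_metadata_id_rejected(self, tmp_path):
        fa, tsv = _write_inputs(
            tmp_path,
            [("W1", "ACGT")],
            [("W1", "wild", "spread"), ("W1", "wild", "spread")],
        )
        with pytest.raises(MetadataError, match="duplicate"):
            read_panel(fa, tsv, 13300)

    def test_unknown_symbols_masked_to_n(self, tmp_path):
        fa, tsv = _write_inputs(
            tmp_path,
            [("W1", "acgrWacgta"), ("C1", "ACGTACGTAC")],
            [("W1", "wild", "spread"), ("C1", "cultivated", "compact")],
        )
        panel = read_panel(fa, tsv, 13300)
        assert panel.sequences["W1"] == "ACGNNACGTA"

    def test_anchor_must_cover_region(self, tmp_path):
        fa, tsv = _write_inputs(
            tmp_path, [("W1", "ACGTACGTAC")], [("W1", "wild", "spread")]
        )
        with pytest.raises(AlignmentError):
            read_panel(fa, tsv, 5)


def test_panel_roundtrip(tmp_path, paper_panel):
    panel, _ = paper_panel
    write_panel(panel, tmp_path / "p.fa", tmp_path / "p.tsv")
    back = read_panel(tmp_path / "p.fa", tmp_path / "p.tsv", panel.anchor_upstream_bp)
    assert back.sequences == panel.sequences
    assert back.meta == panel.meta


class TestCoordinates:
    def test_definition(self, tiny_panel):
        assert column_to_upstream(0, tiny_panel) == 13300

    def test_proximal_end(self):
        meta = [AccessionMeta("W1", "wild", "spread"), AccessionMeta("C1", "cultivated", "compact")]
        panel = Panel({"W1": "A" * 3300, "C1": "A" * 3300}, meta, 13300)
        assert column_to_upstream(3299, panel) == 10001

    def test_causal_position_class(self):
        # the causal-site analog sits ~11 kb upstream: col 2300 with anchor 13300
        meta = [AccessionMeta("W1", "wild", "spread"), AccessionMeta("C1", "cultivated", "compact")]
        panel = Panel({"W1": "A" * 3300, "C1": "A" * 3300}, meta, 13300)
        assert column_to_upstream(2300, panel) == 11000

    def test_out_of_range(self, tiny_panel):
        with pytest.raises(IndexError):
            column_to_upstream(10, tiny_panel)
        with pytest.raises(IndexError):
            column_to_upstream(-1, tiny_panel)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(anchor_offset=st.integers(0, 5000), length=st.integers(1, 400), data=st.data())
    def test_bijection(self, anchor_offset, length, data):
        """column -> upstream -> column is identity; mapping strictly decreasing."""
        meta = [
            AccessionMeta("W1", "wild", "spread"),
            AccessionMeta("C1", "cultivated", "compact"),
        ]
        panel = Panel(
            {"W1": "A" * length, "C1": "A" * length}, meta, length + anchor_offset
        )
        col = data.draw(st.integers(0, length - 1))
        up = column_to_upstream(col, panel)
        assert up >= 1
        assert upstream_to_column(up, panel) == col
        if col > 0:
            assert column_to_upstream(col - 1, panel) == up + 1


class TestVariantTableIO:
    def test_empty_table_header_only(self, tmp_path, tiny_panel):
        vt = segregating_sites(tiny_panel)
        vt.variants = []
        out = tmp_path / "v.tsv"
        write_variant_table(vt, out)
        df = read_variant_table(out)
        assert len(df) == 0
        assert "position_upstream_bp" in df.columns

    def test_snp_row_roundtrip(self, tmp_path, tiny_panel):
        vt = segregating_sites(tiny_panel)
        out = tmp_path / "v.tsv"
        write_variant_table(vt, out)
        df = read_variant_table(out)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["position_upstream_bp"] == 13300 - 5
        assert row["W1"] == "A" and row["C1"] == "T"

    def test_vcf_snp_roundtrip(self, tmp_path, tiny_panel):
        pysam = pytest.importorskip("pysam")
        vt = segregating_sites(tiny_panel)
        out = tmp_path / "v.vcf"
        write_vcf(vt, tiny_panel, out)
        with pysam.VariantFile(str(out)) as vf:
            recs = list(vf)
        assert len(recs) == 1
        assert recs[0].pos == 6  # col 5, 1-based
        assert recs[0].ref == "A" and recs[0].alts == ("T",)
        assert recs[0].info["UPS"] == 13300 - 5

    def test_vcf_indel_left_anchored(self, tmp_path):
        """A 6-bp deletion becomes one VCF record with REF length 7, ALT length 1."""
        pysam = pytest.importorskip("pysam")
        from conftest import make_panel

        base = "ACGTACGTACGTACGTACGT"
        deleted = base[:8] + "------" + base[14:]
        panel = make_panel({"wild": [base, base], "cultivated": [deleted, deleted]})
        vt = segregating_sites(panel)
        (indel,) = [v for v in vt if v.vtype == "INDEL"]
        assert indel.columns == (8, 14)
        out = tmp_path / "indel.vcf"
        write_vcf(vt, panel, out)
        with pysam.VariantFile(str(out)) as vf:
            recs = list(vf)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.pos == 8  # 1-based position of the context base at col 7
        assert len(rec.ref) == 7 and len(rec.alts[0]) == 1
        assert rec.ref[0] == rec.alts[0]
        # genotypes round-trip to the original alleles
        gts = {name: s["GT"][0] for name, s in rec.samples.items()}
        assert all(gts[w] == 0 for w in ("W1", "W2"))
        assert all(gts[c] == 1 for c in ("C1", "C2"))
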