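"""Format readers/writers: parsing rules, round trips, coordinate conventions."""

import numpy as np
import pytest

from wsmeth.array_io import (
    BetaMatrix,
    FormatError,
    Group,
    ProbeAnnotation,
    Relation,
    read_beta_matrix,
    read_gmt,
    read_manifest,
    read_series_matrix,
    read_table,
    write_beta_matrix,
    write_dmr_bed,
    write_gmt,
    write_manifest,
    write_sample_sheet,
    write_table,
)
from wsmeth.dmr import DMRResult

from conftest import make_matrix


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


class TestManifest:
    def test_annotated_open_sea_probe(self, tmp_path):
        # a gene-associated probe outside any island
        p = tmp_path / "m.tsv"
        write_lines(
            p,
            [
                "probe_id\tchrom\tposition\tgenes\tisland_name\trelation",
                "cg15294279\tchr3\t174842010\tNAALADL2\t\t",
            ],
        )
        (a,) = read_manifest(p)
        assert a.relation is Relation.OPEN_SEA
        assert a.genes == {"NAALADL2"}
        assert a.position == 174842010

    def test_empty_gene_and_island_fields(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(
            p,
            [
                "probe_id\tchrom\tposition\tgenes\tisland_name\trelation",
                "cg06052372\tchr16\t83967808\t\t\t",
            ],
        )
        (a,) = read_manifest(p)
        assert a.genes == frozenset()
        assert a.relation is Relation.OPEN_SEA

    def test_shore_probe_with_island(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(
            p,
            [
                "probe_id\tchrom\tposition\tgenes\tisland_name\trelation",
                "cg00597723\tchr5\t158691793\tUBLCP1\tchr5:158690013-158690541\tS_Shore",
            ],
        )
        (a,) = read_manifest(p)
        assert a.relation is Relation.S_SHORE
        assert a.cpg_rich

    def test_count_and_uniqueness(self, tmp_path):
        p = tmp_path / "m.tsv"
        rows = ["probe_id\tchrom\tposition\tgenes\tisland_name\trelation"]
        rows += [f"cg{i:08d}\tchr1\t{1000 + i}\t\t\t" for i in range(10)]
        write_lines(p, rows)
        annotations = read_manifest(p)
        assert len(annotations) == 10
        assert len({a.probe_id for a in annotations}) == 10

    def test_unparseable_position_dropped(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(
            p,
            [
                "probe_id\tchrom\tposition\tgenes\tisland_name\trelation",
                "cgA\tchr1\t100\t\t\t",
                "cgB\tchr1\toops\t\t\t",
            ],
        )
        assert [a.probe_id for a in read_manifest(p)] == ["cgA"]

    def test_missing_required_column_fatal(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(p, ["probe_id\tchrom", "cgA\tchr1"])
        with pytest.raises(FormatError, match="position"):
            read_manifest(p)

    def test_epic_dialect_and_multigene_split(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(
            p,
            [
                "IlmnID\tCHR\tMAPINFO\tUCSC_RefGene_Name\tUCSC_CpG_Islands_Name\tRelation_to_UCSC_CpG_Island",
                "cgX\t17\t46620500\tHOXB2;HOXB-AS1;HOXB2\tchr17:46620367-46621373\tS_Shore",
            ],
        )
        (a,) = read_manifest(p, dialect="EPIC")
        assert a.chrom == "chr17"
        assert a.genes == {"HOXB2", "HOXB-AS1"}

    def test_roundtrip(self, tmp_path):
        annotations = [
            ProbeAnnotation("cgA", "chr2", 5, frozenset({"G1", "G2"}), "chr2:1-9", Relation.ISLAND),
            ProbeAnnotation("cgB", "chr2", 50),
        ]
        path = tmp_path / "m.tsv"
        write_manifest(annotations, path)
        assert read_manifest(path) == annotations

    def test_invariant_relation_vs_island(self):
        with pytest.raises(ValueError):
            ProbeAnnotation("cgA", "chr1", 10, relation=Relation.ISLAND)  # no island name
        with pytest.raises(ValueError):
            ProbeAnnotation("cgA", "chr1", 10, island_name="chr1:1-5")  # open sea with island


class TestBetaMatrix:
    def test_read_with_groups(self, tmp_path):
        (tmp_path / "b.tsv").write_text(
            "probe_id\tS1\tS2\ncgA\t0.1\t0.9\ncgB\t0.2\t0.8\ncgC\t0.3\t0.7\n"
        )
        (tmp_path / "s.tsv").write_text("sample_id\tgroup\nS1\tCASE\nS2\tCTRL\n")
        m = read_beta_matrix(tmp_path / "b.tsv", tmp_path / "s.tsv")
        assert m.groups == {"S1": Group.CASE, "S2": Group.CTRL}
        assert m.values.shape == (3, 2)

    def test_out_of_bounds_value_names_coordinates(self, tmp_path):
        (tmp_path / "b.tsv").write_text("probe_id\tS1\tS2\ncgA\t0.5\t1.2\n")
        (tmp_path / "s.tsv").write_text("sample_id\tgroup\nS1\tCASE\nS2\tCTRL\n")
        with pytest.raises(ValueError, match="cgA.*S2"):
            read_beta_matrix(tmp_path / "b.tsv", tmp_path / "s.tsv")

    def test_non_numeric_cell_fatal(self, tmp_path):
        (tmp_path / "b.tsv").write_text("probe_id\tS1\tS2\ncgA\t0.5\txyz\n")
        (tmp_path / "s.tsv").write_text("sample_id\tgroup\nS1\tCASE\nS2\tCTRL\n")
        with pytest.raises(FormatError, match="cgA.*S2"):
            read_beta_matrix(tmp_path / "b.tsv", tmp_path / "s.tsv")

    def test_sample_missing_from_sheet_fatal(self, tmp_path):
        (tmp_path / "b.tsv").write_text("probe_id\tS1\tS9\ncgA\t0.5\t0.5\n")
        (tmp_path / "s.tsv").write_text("sample_id\tgroup\nS1\tCASE\n")
        with pytest.raises(FormatError, match="S9"):
            read_beta_matrix(tmp_path / "b.tsv", tmp_path / "s.tsv")

    def test_roundtrip_to_1e12(self, tmp_path, rng):
        m = make_matrix(rng.random((20, 6)))
        write_beta_matrix(m, tmp_path / "b.tsv")
        write_sample_sheet(m.groups, tmp_path / "s.tsv")
        m2 = read_beta_matrix(tmp_path / "b.tsv", tmp_path / "s.tsv")
        assert m2.probe_ids == m.probe_ids
        assert np.allclose(m2.values, m.values, atol=1e-12, rtol=0)

    def test_drop_incomplete_counts(self):
        m = make_matrix([[0.1, 0.2, 0.3, 0.4], [0.1, np.nan, 0.3, 0.4]])
        kept = m.drop_incomplete()
        assert kept.probe_ids == [m.probe_ids[0]]


class TestGMT:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "k.gmt"
        p.write_text("HSA-00600\tSphingolipid metabolism\tCERS3\tCERS1\n")
        lib = read_gmt(p)
        assert lib.terms["HSA-00600"] == ("Sphingolipid metabolism", {"CERS3", "CERS1"})

    def test_short_line_skipped(self, tmp_path):
        p = tmp_path / "k.gmt"
        p.write_text("ONLY_TWO\tfields\nOK\tdesc\tGENEA\n")
        lib = read_gmt(p)
        assert list(lib.terms) == ["OK"]

    def test_empty_library(self, tmp_path):
        p = tmp_path / "k.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0

    def test_symbols_uppercased_roundtrip(self, tmp_path):
        p = tmp_path / "k.gmt"
        p.write_text("T1\tdesc\tabc\tDef\n")
        lib = read_gmt(p)
        assert lib.terms["T1"][1] == {"ABC", "DEF"}
        write_gmt(lib, tmp_path / "out.gmt")
        assert read_gmt(tmp_path / "out.gmt").terms == lib.terms


class TestBedAndTables:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        dmr = DMRResult(
            chrom="chr15",
            start=101084428,
            end=101085178,
            probe_ids=("a", "b", "c"),
            genes=frozenset({"CERS3"}),
            island_name="chr15:101084428-101085178",
            relations=("Island",),
            p_value=0.000341282,
            direction="HYPER",
        )
        write_dmr_bed([dmr], tmp_path / "d.bed")
        chrom, start, end, name, score = (tmp_path / "d.bed").read_text().split("\t")
        assert (chrom, int(start), int(end)) == ("chr15", 101084427, 101085178)
        assert int(start) >= 0 and int(start) < int(end)
        assert name == "CERS3;chr15:101084428-101085178"

    def test_table_roundtrip(self, tmp_path):
        records = [{"a": 1, "b": 0.123456789012345, "c": "x"}, {"a": 2, "b": 1e-9, "c": "y"}]
        write_table(records, tmp_path / "t.tsv")
        df = read_table(tmp_path / "t.tsv")
        assert df["a"].tolist() == [1, 2]
        assert np.allclose(df["b"], [0.123456789012345, 1e-9], rtol=0, atol=1e-12)

    def test_series_matrix_reader(self, tmp_path):
        p = tmp_path / "gse.txt"
        p.write_text(
            "!Series_title\t\"x\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"cgA"\t0.1\t0.2\n'
            "!series_matrix_table_end\n"
        )
        df = read_series_matrix(p)
        assert df.loc["cgA", "GSM1"] == pytest.approx(0.1)
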