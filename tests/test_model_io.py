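import numpy as np
import pandas as pd
import pytest

import redoxtmt.io as rio
from redoxtmt import (
    SampleDesign,
    SiteId,
    ValidationError,
    SimulationConfig,
    simulate,
)
from redoxtmt.model import DESIGN_COLUMNS

from conftest import make_design_frame, make_peptide_table


class TestSiteId:
    @pytest.mark.parametrize(
        "text,residue,position",
        [("C105", "C", 105), ("S536", "S", 536), ("Y1", "Y", 1), ("M23", "M", 23)],
    )
    def test_parse_and_render(self, text, residue, position):
        site = SiteId.parse(text)
        assert (site.residue, site.position) == (residue, position)
        assert str(site) == text

    @pytest.mark.parametrize("bad", ["X10", "C0", "C-5", "105", "C1.5", ""])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValidationError):
            SiteId.parse(bad)


class TestDesignValidation:
    def test_default_design_has_12_replicates(self):
        design = simulate(SimulationConfig(seed=0, n_proteins=5)).design
        assert len(design.replicates()) == 12
        assert design.timepoints == ["4h", "24h"]

    def test_duplicate_mix_channel_rejected(self):
        rows = [
            ("m1", "126", 1, 1, "4h", "control", "NA", "proteome"),
            ("m1", "126", 1, 1, "4h", "treated", "NA", "proteome"),
        ]
        with pytest.raises(ValidationError, match=r"duplicate \(mix, channel\)"):
            SampleDesign(make_design_frame(rows))

    def test_redox_sample_without_twin_rejected(self):
        rows = [
            ("m1", "126", 1, 1, "4h", "control", "TMT1", "redoxome"),
            ("m1", "127", 1, 1, "4h", "treated", "TMT1", "redoxome"),
            ("m1", "128", 1, 1, "4h", "treated", "TMT2", "redoxome"),
        ]
        with pytest.raises(ValidationError, match="TMT1/TMT2 twin"):
            SampleDesign(make_design_frame(rows))

    def test_unknown_tokens_rejected(self):
        rows = [("m1", "126", 1, 1, "4h", "dosed", "NA", "proteome")]
        with pytest.raises(ValidationError, match="unknown treatment"):
            SampleDesign(make_design_frame(rows))

    def test_unpaired_treatment_rejected(self):
        rows = [
            ("m1", "126", 1, 1, "4h", "treated", "NA", "proteome"),
            ("m1", "127", 1, 1, "24h", "control", "NA", "proteome"),
        ]
        with pytest.raises(ValidationError, match="pairing"):
            SampleDesign(make_design_frame(rows))

    def test_empty_design_file(self, tmp_path):
        path = tmp_path / "design.tsv"
        path.write_text("\t".join(DESIGN_COLUMNS) + "\n")
        with pytest.raises(ValidationError, match="no design rows"):
            rio.read_design(str(path))


class TestPeptideTableIO:
    def _write(self, tmp_path, body):
        header = "mix_id\tprotein_accession\tpeptide_sequence\tsites\t126\t127\n"
        path = tmp_path / "peptides.tsv"
        path.write_text(header + body)
        return str(path)

    def test_multisite_row_and_missing_cell(self, tmp_path, mini_design):
        path = self._write(
            tmp_path,
            "prot-1\tP04406\tLISWYDNEK\tC152;C156\t100\t50\n"
            "prot-1\tP04406\tAVGKVIPEK\t\t\t40\n",
        )
        table = rio.read_peptide_table(path, mini_design)
        records = table.to_records()
        assert [str(s) for s in records[0].sites] == ["C152", "C156"]
        assert records[0].channel_intensities == {"126": 100.0, "127": 50.0}
        # blank cell is missing, not zero
        assert records[1].channel_intensities == {"127": 40.0}

    def test_unknown_intensity_column_rejected(self, tmp_path, mini_design):
        path = tmp_path / "p.tsv"
        path.write_text(
            "mix_id\tprotein_accession\tpeptide_sequence\tsites\t999\n"
            "prot-1\tP1\tPEPK\t\t5\n"
        )
        with pytest.raises(ValidationError, match="no design entry"):
            rio.read_peptide_table(str(path), mini_design)

    def test_negative_intensity_rejected(self, tmp_path, mini_design):
        path = self._write(tmp_path, "prot-1\tP1\tPEPK\t\t-3\t1\n")
        with pytest.raises(ValidationError, match="negative intensity"):
            rio.read_peptide_table(str(path), mini_design)

    def test_bad_site_reports_row_number(self, tmp_path, mini_design):
        path = self._write(
            tmp_path,
            "prot-1\tP1\tPEPK\t\t1\t2\nprot-1\tP2\tPEPC\tX10\t1\t2\n",
        )
        with pytest.raises(ValidationError, match="row 2"):
            rio.read_peptide_table(str(path), mini_design)

    def test_intensity_in_foreign_channel_rejected(self, tmp_path):
        rows = [
            ("m1", "126", 1, 1, "4h", "control", "NA", "proteome"),
            ("m1", "127", 1, 1, "4h", "treated", "NA", "proteome"),
            ("m2", "128", 1, 2, "4h", "control", "NA", "proteome"),
            ("m2", "129", 1, 2, "4h", "treated", "NA", "proteome"),
        ]
        design = SampleDesign(make_design_frame(rows))
        path = tmp_path / "p.tsv"
        path.write_text(
            "mix_id\tprotein_accession\tpeptide_sequence\tsites\t126\t127\t128\t129\n"
            "m1\tP1\tPEPK\t\t1\t2\t3\t\n"
        )
        with pytest.raises(ValidationError, match="not part of that mix"):
            rio.read_peptide_table(str(path), design)


class TestRoundTrips:
    def test_design_round_trip(self, tmp_path, small_experiment):
        path = tmp_path / "design.tsv"
        rio.write_design(small_experiment.design, str(path))
        again = rio.read_design(str(path))
        assert again == small_experiment.design

    def test_peptide_table_round_trip(self, tmp_path, small_experiment):
        table = small_experiment.tables["redoxome"]
        path = tmp_path / "peptides.tsv"
        rio.write_peptide_table(table, str(path))
        again = rio.read_peptide_table(str(path), small_experiment.design)
        a = table.frame[table.channels].to_numpy()
        b = again.frame[again.channels].to_numpy()
        assert np.allclose(a, b, rtol=1e-8, equal_nan=True)
        pd.testing.assert_frame_equal(
            table.frame[["mix_id", "protein_accession", "sites"]],
            again.frame[["mix_id", "protein_accession", "sites"]],
        )

    def test_result_table_round_trip(self, tmp_path):
        res = pd.DataFrame(
            {
                "entity": ["A", "B"],
                "p": [0.123456789123, 1e-15],
                "significant": [True, False],
            }
        )
        path = tmp_path / "res.tsv"
        rio.write_table(res, str(path))
        again = rio.read_table(str(path))
        assert list(again.columns) == list(res.columns)
        assert np.allclose(again["p"], res["p"], rtol=1e-8)
        assert again["significant"].tolist() == [True, False]

    def test_empty_result_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        rio.write_table(pd.DataFrame(columns=["entity", "p"]), str(path))
        assert path.read_text() == "entity\tp\n"

    def test_gmt_round_trip(self, tmp_path, small_experiment):
        path = tmp_path / "sets.gmt"
        rio.write_gmt(small_experiment.gene_sets, str(path))
        again = rio.read_gmt(str(path))
        assert again.sets == small_experiment.gene_sets.sets

    def test_annotations_round_trip(self, tmp_path, small_experiment):
        path = tmp_path / "ann.tsv"
        rio.write_annotations(small_experiment.annotations, str(path))
        again = rio.read_annotations(str(path))
        pd.testing.assert_frame_equal(again.frame, small_experiment.annotations.frame)
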