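"""FASTA, Stockholm, prediction tables, coordinate conventions, config."""

import warnings

import pytest

from cloverscan.config import ScanConfig, read_config
from cloverscan.formats import (
    SeedAlignment,
    parse_pairs,
    parse_stockholm,
    read_fasta,
    read_predictions,
    write_predictions,
    write_stockholm,
)
from cloverscan.records import FormatError, NucSequence, StructureError, \
    TRNAPrediction, revcomp


class TestFasta:
    def test_normalisation_and_order(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgu\n>y\nTTnRY\n")
        seqs = read_fasta(p)
        assert [s.id for s in seqs] == ["x", "y"]
        assert seqs[0].residues == "ACGT"          # lowercase + U -> T
        assert seqs[1].residues == "TTNRY"          # ambiguity retained

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_invalid_residue(self, tmp_path):
        p = tmp_path / "b.fa"
        p.write_text(">z\nACGZ\n")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_empty_record(self, tmp_path):
        p = tmp_path / "b.fa"
        p.write_text(">z\n>y\nACGT\n")
        with pytest.raises(FormatError):
            read_fasta(p)


class TestStockholm:
    def test_bracket_variants_and_roundtrip(self):
        aln = SeedAlignment(
            rows=[("s1", "GGAC-CC"), ("s2", "GGACACC")],
            ss_cons="<<...>>", anticodon_cols=(2, 3, 4),
            name="fam", domain="archaea", isotype="Ala", fold="standard",
        )
        text = write_stockholm(aln)
        back = parse_stockholm(text)
        assert back == aln
        assert write_stockholm(back) == text

    def test_all_pair_brackets_accepted(self):
        pairs = parse_pairs("<([{..}])>")
        assert pairs[0] == 9 and pairs[3] == 6

    def test_unbalanced(self):
        with pytest.raises(StructureError):
            parse_stockholm("s1 ACGTAC\n#=GC SS_cons <<...>\n")

    def test_ragged_rows(self):
        with pytest.raises(FormatError):
            SeedAlignment(rows=[("a", "ACGT"), ("b", "ACG")], ss_cons="....")

    def test_anticodon_marker_constraints(self):
        with pytest.raises(FormatError):
            SeedAlignment(rows=[("a", "ACGT")], ss_cons="....",
                          anticodon_cols=(0, 2, 3))
        with pytest.raises(StructureError):
            SeedAlignment(rows=[("a", "ACGTA")], ss_cons="<...>",
                          anticodon_cols=(0, 1, 2))


class TestPredictionTables:
    def _pred(self, strand, flags=()):
        return TRNAPrediction(
            seq_id="chr1", begin=99, end=172, strand=strand,
            overall_bits=66.0, anticodon="TGC", isotype_by_anticodon="Ala",
            flags=set(flags))

    def test_plus_strand_conventions(self):
        text = write_predictions([self._pred("+")], style="tabular")
        fields = text.splitlines()[1].split("\t")
        assert (fields[2], fields[3]) == ("100", "172")
        bed = write_predictions([self._pred("+")], style="bed")
        assert bed.split("\t")[1:3] == ["99", "172"]

    def test_minus_strand_swaps_tabular(self):
        text = write_predictions([self._pred("-")], style="tabular")
        fields = text.splitlines()[1].split("\t")
        assert (fields[2], fields[3]) == ("172", "100")

    def test_pseudo_flag_in_note(self):
        text = write_predictions([self._pred("+", {"pseudo"})],
                                 style="tabular")
        assert "pseudo" in text.splitlines()[1].split("\t")[9]

    def test_unknown_style(self):
        with pytest.raises(ValueError):
            write_predictions([], style="sam")

    @pytest.mark.parametrize("strand", "+-")
    def test_coordinate_roundtrip(self, tmp_path, strand):
        p = tmp_path / "t.tsv"
        write_predictions([self._pred(strand)], path=p, style="tabular")
        rec = read_predictions(p)[0]
        assert (rec.begin, rec.end, rec.strand) == (99, 172, strand)
        # write again: identity
        pred2 = TRNAPrediction(
            seq_id=rec.seq_id, begin=rec.begin, end=rec.end,
            strand=rec.strand, overall_bits=rec.score,
            anticodon=rec.anticodon, isotype_by_anticodon=rec.isotype)
        assert write_predictions([pred2], style="tabular") == \
            write_predictions([self._pred(strand)], style="tabular")


class TestConfig:
    def test_defaults(self, tmp_path):
        p = tmp_path / "c.ini"
        p.write_text("")
        cfg = read_config(p)
        assert cfg.scan.report_cutoff == 20.0
        assert cfg.scan.first_pass_cutoff == 10.0
        assert cfg.filters.pseudo_overall == 55.0

    def test_override_score_30(self, tmp_path):
        p = tmp_path / "c.ini"
        p.write_text("[scan]\nreport_cutoff = 30\n")
        assert read_config(p).scan.report_cutoff == 30.0

    def test_alternate_models(self, tmp_path):
        p = tmp_path / "c.ini"
        p.write_text("[models]\nalternate = a.model b.model\n")
        assert read_config(p).alternate_models == ["a.model", "b.model"]

    def test_unknown_key_warns(self, tmp_path):
        p = tmp_path / "c.ini"
        p.write_text("[scan]\nbogus = 1\n")
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            read_config(p)
        assert any("unknown" in str(x.message) for x in w)

    def test_non_numeric_threshold(self, tmp_path):
        p = tmp_path / "c.ini"
        p.write_text("[scan]\nreport_cutoff = high\n")
        with pytest.raises(FormatError):
            read_config(p)


def test_revcomp_involution():
    s = "ACGTRYN"
    assert revcomp(revcomp(s)) == s


def test_invalid_scan_config():
    with pytest.raises(ValueError):
        ScanConfig(first_pass_cutoff=30, report_cutoff=20)
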