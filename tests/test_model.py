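"""Guide trees, training arithmetic, masking, marginals, sampling, I/O."""

import numpy as np
import pytest

from cloverscan import guide as G
from cloverscan.dp import score_sequence
from cloverscan.formats import SeedAlignment
from cloverscan.model import (
    TrainingError,
    marginalize,
    mask_anticodons,
    sample_sequence,
    train_model,
)
from cloverscan.model_io import read_model, write_model
from cloverscan.records import StructureError


class TestGuideTree:
    def test_hairpin(self):
        t = G.build_guide_tree("<<...>>")
        assert t.count(G.PAIR) == 2
        assert t.count(G.MATL) + t.count(G.MATR) == 3
        assert t.count(G.BIF) == 0

    def test_all_singles(self):
        t = G.build_guide_tree(".......")
        assert t.count(G.MATL) + t.count(G.MATR) == 7
        assert t.count(G.PAIR) == 0

    def test_cloverleaf_has_two_bifurcations(self):
        ss = "((((..((..))..((..))..((..))..))))"
        t = G.build_guide_tree(ss)
        assert t.count(G.BIF) == 2

    def test_inorder_recovers_columns(self):
        for ss in ["<<...>>", "..<.>.", "((..))((..)).."]:
            t = G.build_guide_tree(ss)
            assert t.columns_inorder() == list(range(len(ss)))

    def test_crossing_rejected(self):
        with pytest.raises(StructureError):
            G.build_guide_tree("<(>)")


class TestTraining:
    def test_single_column_laplace(self):
        m = train_model(SeedAlignment(rows=[("x", "A")], ss_cons="."))
        expected = np.log2((2 / 5) / 0.25)
        assert m.esl[1][0] == pytest.approx(expected, abs=1e-9)
        assert m.esl[1][1] == pytest.approx(np.log2((1 / 5) / 0.25), abs=1e-9)

    def test_pair_laplace(self):
        m = train_model(SeedAlignment(rows=[("x", "GC")], ss_cons="<>"))
        assert m.ep[1, 2, 1] == pytest.approx(np.log2((2 / 17) / 0.0625),
                                              abs=1e-9)

    def test_majority_gap_column_excluded(self):
        # 3 of 5 rows gapped at column 1: not a consensus column
        rows = [("a", "AAC"), ("b", "A-C"), ("c", "A-C"),
                ("d", "A-C"), ("e", "AGC")]
        m = train_model(SeedAlignment(rows=rows, ss_cons="..."))
        assert m.ncols == 2

    def test_no_consensus_columns(self):
        rows = [("a", "--"), ("b", "--")]
        with pytest.raises(TrainingError):
            train_model(SeedAlignment(rows=rows, ss_cons=".."))

    def test_emission_tables_normalise(self, fixture_set):
        m = fixture_set.domain_model
        bg = m.background
        for v in range(m.nnodes):
            if m.ntype[v] in (G.MATL, G.MATR):
                assert np.exp2(m.esl[v, :4]) @ bg == pytest.approx(1.0,
                                                                   abs=1e-9)
            elif m.ntype[v] == G.PAIR:
                p = np.exp2(m.ep[v, :4, :4]) * np.outer(bg, bg)
                assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_transition_probabilities_normalise(self, hairpin_model):
        m = hairpin_model
        for v in range(m.nnodes):
            if m.ntype[v] in (G.MATL, G.MATR):
                assert np.exp2(m.trans[v, :2]).sum() == pytest.approx(1.0)
            elif m.ntype[v] == G.PAIR:
                assert np.exp2(m.trans[v]).sum() == pytest.approx(1.0)


class TestMasking:
    def _aln(self):
        return SeedAlignment(
            rows=[("a", "GCATG"), ("b", "GC-TG")], ss_cons=".....",
            anticodon_cols=(1, 2, 3))

    def test_mask_replaces_and_keeps_gaps(self):
        masked = mask_anticodons(self._aln())
        assert masked.rows[0][1] == "GNNNG"
        assert masked.rows[1][1] == "GN-NG"   # gap retained

    def test_mask_idempotent(self):
        once = mask_anticodons(self._aln())
        twice = mask_anticodons(once)
        assert once == twice

    def test_no_marker_warns_noop(self):
        aln = SeedAlignment(rows=[("a", "GCATG")], ss_cons=".....")
        with pytest.warns(UserWarning):
            out = mask_anticodons(aln)
        assert out == aln


class TestMarginalize:
    def test_no_pairs_identical(self):
        m = train_model(SeedAlignment(rows=[("a", "ACGT")], ss_cons="...."))
        lp = marginalize(m)
        for c in range(4):
            v = int(m.col_node[c])
            assert np.allclose(lp.em[c], m.esl[v])

    def test_concentrated_pair_marginals(self):
        rows = [("r%d" % k, "GC") for k in range(50)]
        m = train_model(SeedAlignment(rows=rows, ss_cons="<>"))
        lp = marginalize(m)
        assert np.argmax(lp.em[0, :4]) == 2   # G on the left
        assert np.argmax(lp.em[1, :4]) == 1   # C on the right
        assert lp.ncols == m.ncols


class TestSampling:
    def test_deterministic_under_seed(self, hairpin_model):
        a = sample_sequence(hairpin_model, 42)
        b = sample_sequence(hairpin_model, 42)
        assert a.residues == b.residues

    def test_samples_score_above_random(self, fixture_set):
        m = fixture_set.family_models["Ala-TGC"]
        rng = np.random.default_rng(0)
        own, rand = [], []
        for s in range(60):
            res = sample_sequence(m, s).residues
            own.append(score_sequence(m, res, mode="global").score)
            shuffled = "".join(rng.choice(list("ACGT"), size=len(res)))
            rand.append(score_sequence(m, shuffled, mode="global").score)
        assert np.mean(own) > np.mean(rand) + 50

    def test_single_sequence_model_recovers_consensus(self):
        from cloverscan.model import sample
        rows = [(f"r{k}", "GGGACACCC") for k in range(200)]
        m = train_model(SeedAlignment(rows=rows, ss_cons="<<<...>>>"))
        rng = np.random.default_rng(8)
        exact = sum(
            "".join(b or "-" for b in sample(m, rng).col_residues)
            == "GGGACACCC"
            for _ in range(200)
        )
        assert exact > 100   # consensus columns recovered most of the time


class TestModelIO:
    def test_roundtrip_scores_and_bytes(self, hairpin_model, tmp_path):
        p = tmp_path / "m.model"
        text = write_model(hairpin_model, p)
        back = read_model(p)
        assert write_model(back) == text     # byte-stable at 3 decimals
        s1 = score_sequence(hairpin_model, "GGACACC", mode="global").score
        s2 = score_sequence(back, "GGACACC", mode="global").score
        assert s2 == pytest.approx(s1, abs=0.05)

    def test_meta_preserved(self, fixture_set, tmp_path):
        m = fixture_set.family_models["Ala-TGC"]
        back = read_model(text=write_model(m))
        assert back.anticodon_cols == m.anticodon_cols
        assert (back.name, back.isotype, back.fold) == \
            (m.name, m.isotype, m.fold)
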