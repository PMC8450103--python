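"""Structural scoring: oracle spot-checks, decomposition, N rule, trunc."""

import numpy as np
import pytest

from conftest import random_seq, random_tiny_model
from oracle import oracle_global, oracle_local

from cloverscan.dp import score_sequence
from cloverscan.formats import SeedAlignment
from cloverscan.model import sample_sequence, seq_to_codes, train_model
from cloverscan.records import revcomp


class TestOracleSpotChecks:
    """A fast slice of the exhaustive equivalence check (the full-size run
    lives in the acceptance suite)."""

    def test_kernel_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            m = random_tiny_model(rng)
            for _ in range(10):
                seq = random_seq(rng)
                codes = seq_to_codes(seq)
                for mode, fn in (("global", oracle_global),
                                 ("local", oracle_local)):
                    for trunc in (False, True):
                        got = score_sequence(m, seq, mode=mode,
                                             allow_trunc=trunc).score
                        exp = fn(m, codes, allow_trunc=trunc)
                        if got < -1e29 and exp < -1e29:
                            continue
                        assert got == pytest.approx(exp, abs=1e-9)


class TestDecomposition:
    def test_score_is_primary_plus_secondary(self):
        rng = np.random.default_rng(3)
        for _ in range(6):
            m = random_tiny_model(rng)
            for _ in range(6):
                p = score_sequence(m, random_seq(rng), mode="global")
                assert p.score == pytest.approx(
                    p.primary_bits + p.secondary_bits, abs=1e-9)

    def test_no_pairs_means_zero_secondary(self):
        m = train_model(SeedAlignment(rows=[("a", "ACGTA")], ss_cons="....."))
        p = score_sequence(m, "ACGTA", mode="global")
        assert p.secondary_bits == pytest.approx(0.0, abs=1e-9)

    def test_independent_pair_table_zero_secondary(self):
        # all 16 pair combinations equally observed: the (pseudocounted)
        # joint stays the product of its marginals, so no covariation signal
        combos = [a + b for a in "ACGT" for b in "ACGT"]
        rows = [("r%d" % k, lr) for k, lr in enumerate(combos)]
        m = train_model(SeedAlignment(rows=rows, ss_cons="<>"))
        p = score_sequence(m, "AC", mode="global")
        assert p.secondary_bits == pytest.approx(0.0, abs=1e-9)

    def test_covariant_pairs_positive_secondary(self, hairpin_model):
        p = score_sequence(hairpin_model, "GGACACC", mode="global")
        assert p.secondary_bits > 0


class TestNScoring:
    def test_all_n_scores_transitions_only(self, hairpin_model):
        m = hairpin_model
        p = score_sequence(m, "N" * m.ncols, mode="global")
        # emissions contribute exactly zero bits; what remains is the
        # best all-match transition path
        total = 0.0
        from cloverscan import guide as G
        for v in range(m.nnodes):
            if m.ntype[v] in (G.MATL, G.MATR):
                total += m.trans[v, 0]
            elif m.ntype[v] == G.PAIR:
                total += m.trans[v, 0]
            total += m.insc0[v, 0] + m.insc0[v, 1]
        assert p.score >= total - 1e-9
        assert p.primary_bits == pytest.approx(p.score, abs=1e-9)


class TestEdgeCases:
    def test_empty_sequence_defined(self, hairpin_model):
        p = score_sequence(hairpin_model, "", mode="global")
        assert np.isfinite(p.score) and p.score < 0

    def test_deterministic_repeat(self, hairpin_model):
        a = score_sequence(hairpin_model, "GGTCACCGG", mode="local")
        b = score_sequence(hairpin_model, "GGTCACCGG", mode="local")
        assert (a.score, a.begin, a.end, a.col_assign) == \
            (b.score, b.begin, b.end, b.col_assign)


class TestStrandSymmetry:
    def test_revcomp_model_scores_revcomp_seq(self):
        rows = [("a", "GGACACC"), ("b", "GGTCACC"), ("c", "GGACTCC")]
        ss = "<<...>>"
        m_fwd = train_model(SeedAlignment(rows=rows, ss_cons=ss))
        rows_rc = [(sid, revcomp(t)) for sid, t in rows]
        m_rev = train_model(SeedAlignment(rows=rows_rc, ss_cons=ss))
        rng = np.random.default_rng(9)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=9))
            s1 = score_sequence(m_fwd, seq, mode="local").score
            s2 = score_sequence(m_rev, revcomp(seq), mode="local").score
            assert s1 == pytest.approx(s2, abs=1e-6)


class TestTruncation:
    def test_five_prime_truncated_sample_flags_trunc5(self, fixture_set):
        m = fixture_set.family_models["Ala-TGC"]
        full = sample_sequence(m, 77).residues
        cut = full[12:]
        p = score_sequence(m, cut, mode="global", allow_trunc=True)
        p_plain = score_sequence(m, cut, mode="global", allow_trunc=False)
        assert p.trunc5
        # free deletion beats paying the (rare) delete transitions
        assert p.score > p_plain.score
        p3 = score_sequence(m, full[:-12], mode="global", allow_trunc=True)
        assert p3.trunc3

    def test_trunc_never_hurts(self, hairpin_model):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=7))
            plain = score_sequence(hairpin_model, seq, mode="global").score
            trunc = score_sequence(hairpin_model, seq, mode="global",
                                   allow_trunc=True).score
            assert trunc >= plain - 1e-9
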