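"""Canonical and bulge-helix-bulge intron detection."""

import numpy as np
import pytest

from cloverscan.config import IntronConfig
from cloverscan.dp import score_sequence
from cloverscan.introns import detect_canonical, search_noncanonical, splice
from cloverscan.model import sample_sequence
from cloverscan.simulate import _sample_compact, _sample_gene


class TestSplice:
    def test_lengths(self):
        assert len(splice("A" * 100, 40, 60)) == 80

    def test_zero_length_identity(self):
        assert splice("ACGT", 2, 2) == "ACGT"

    def test_disjoint_commutes(self):
        s = "ABCDEFGHIJ"
        # right-then-left equals left-then-right with shifted bounds
        a = splice(splice(s, 6, 8), 1, 3)
        b = splice(splice(s, 1, 3), 4, 6)
        assert a == b

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            splice("ACGT", 3, 1)


def _gene_with_canonical_intron(fixture_set, ilen, seed=101):
    model = fixture_set.family_models["Tyr-GTA"]
    rng = np.random.default_rng(seed)
    res, colpos = _sample_gene(model, rng)
    c37 = model.anticodon_cols[2] + 1
    while c37 not in colpos:
        res, colpos = _sample_gene(model, rng)
    intron = "".join(rng.choice(list("ACGT"), size=ilen))
    at = colpos[c37] + 1
    return model, res[:at] + intron + res[at:], at, ilen


class TestCanonical:
    def test_long_insert_at_37_38_reported_exactly(self, fixture_set):
        model, gene, at, ilen = _gene_with_canonical_intron(fixture_set, 16)
        parse = score_sequence(model, gene, mode="global")
        introns = detect_canonical(parse, model)
        assert len(introns) == 1
        it = introns[0]
        assert it.kind == "canonical"
        assert abs(it.begin - at) <= 1 and abs(it.end - (at + ilen)) <= 1

    def test_short_insert_below_threshold_ignored(self, fixture_set):
        model, gene, *_ = _gene_with_canonical_intron(fixture_set, 5)
        parse = score_sequence(model, gene, mode="global")
        assert detect_canonical(parse, model) == []

    def test_insert_elsewhere_not_canonical(self, fixture_set):
        model = fixture_set.family_models["Tyr-GTA"]
        rng = np.random.default_rng(5)
        res, colpos = _sample_gene(model, rng)
        at = colpos[5] + 1     # acceptor stem region, far from 37/38
        gene = res[:at] + "".join(rng.choice(list("ACGT"), size=16)) + res[at:]
        parse = score_sequence(model, gene, mode="global")
        assert detect_canonical(parse, model) == []


def _bhb_consensus(aln):
    """Majority-base consensus of a BHB intron family alignment."""
    from collections import Counter
    out = []
    for c in range(aln.width):
        top = Counter(t[c] for _, t in aln.rows
                      if t[c] not in ".-").most_common(1)
        out.append(top[0][0])
    return "".join(out)


class TestNoncanonical:
    def test_consensus_bhb_intron_recovered_exactly(self, fixture_set):
        model = fixture_set.family_models["Gly-GCC"]
        bhb = fixture_set.bhb_models
        rng = np.random.default_rng(31)
        res, colpos = _sample_gene(model, rng)
        intron = _bhb_consensus(fixture_set.bhb_alignments["bhb_cren"])
        at = colpos[model.anticodon_cols[2] + 2]
        precursor = res[:at] + intron + res[at:]
        unspliced = score_sequence(model, precursor, mode="local").score
        parse, introns, mature, _ = search_noncanonical(
            precursor, model, bhb)
        assert len(introns) == 1
        assert (introns[0].begin, introns[0].end) == (at, at + len(intron))
        assert parse.score > unspliced       # strict improvement
        assert mature == res

    def test_two_proximal_introns_need_two_iterations(self, fixture_set):
        model = fixture_set.family_models["Gly-GCC"]
        bhb = fixture_set.bhb_models
        rng = np.random.default_rng(37)
        res, colpos = _sample_gene(model, rng)
        outer = _sample_compact(bhb["bhb_thaum"], rng)
        inner = _sample_compact(bhb["bhb_cren"], rng)
        at = colpos[model.anticodon_cols[2] + 2]
        mid = at + len(outer) // 2
        precursor = (res[:at] + outer[:len(outer) // 2] + inner
                     + outer[len(outer) // 2:] + res[at:])
        parse, introns, mature, _ = search_noncanonical(precursor, model, bhb)
        assert len(introns) == 2
        assert [it.iteration for it in introns] == [1, 2]
        assert mature == res
        assert (introns[0].begin, introns[0].end) == (mid, mid + len(inner))

    def test_decoy_that_hurts_score_rejected(self, fixture_set):
        # a BHB-like motif inside an intact gene: removal breaks the
        # cloverleaf, so the splice must be rejected
        model = fixture_set.family_models["Gly-GCC"]
        bhb = fixture_set.bhb_models
        rng = np.random.default_rng(41)
        res, _ = _sample_gene(model, rng)
        parse, introns, mature, _ = search_noncanonical(res, model, bhb)
        assert introns == []
        assert mature == res

    def test_iteration_bounded(self, fixture_set):
        model = fixture_set.family_models["Gly-GCC"]
        bhb = fixture_set.bhb_models
        rng = np.random.default_rng(43)
        res, colpos = _sample_gene(model, rng)
        at = colpos[model.anticodon_cols[2] + 2]
        ins = "".join(_sample_compact(bhb["bhb_cren"],
                                      np.random.default_rng(50 + k))
                      for k in range(4))
        precursor = res[:at] + ins + res[at:]
        cfg = IntronConfig(max_iterations=3)
        _, introns, _, _ = search_noncanonical(precursor, model, bhb, cfg)
        assert len(introns) <= 3
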