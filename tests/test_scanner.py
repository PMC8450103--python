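"""Two-pass scanning, exhaustive mode, overlap resolution."""

import numpy as np
import pytest

from cloverscan.config import ScanConfig
from cloverscan.dp import ParseResult
from cloverscan.model import marginalize, sample_sequence
from cloverscan.records import NucSequence, revcomp
from cloverscan.scanner import (
    Hit,
    first_pass_scan,
    merge_candidates,
    resolve_overlaps,
    scan_max,
    scan_sequences,
)


def _implant_genome(model, rng, length=6000, pos=2500, strand="+",
                    seed=55):
    trna = sample_sequence(model, seed).residues
    bg = "".join(rng.choice(list("ACGT"), size=length))
    ins = trna if strand == "+" else revcomp(trna)
    genome = bg[:pos] + ins + bg[pos + len(trna):]
    return NucSequence("g", genome), pos, pos + len(trna)


class TestFirstPass:
    def test_implant_yields_covering_candidate(self, fixture_set):
        rng = np.random.default_rng(2)
        model = fixture_set.family_models["Ala-TGC"]
        genome, b, e = _implant_genome(model, rng)
        cands = first_pass_scan(marginalize(model), genome)
        assert any(c.begin <= b and c.end >= e and c.strand == "+"
                   for c in cands)

    def test_random_sequence_no_candidates(self, fixture_set):
        rng = np.random.default_rng(7)
        genome = NucSequence("r", "".join(rng.choice(list("ACGT"), size=1000)))
        cands = first_pass_scan(marginalize(fixture_set.domain_model), genome)
        assert cands == []

    def test_cutoff_monotone(self, fixture_set):
        rng = np.random.default_rng(2)
        model = fixture_set.family_models["Ala-TGC"]
        genome, _, _ = _implant_genome(model, rng)
        lo = first_pass_scan(marginalize(model), genome,
                             ScanConfig(first_pass_cutoff=10))
        hi = first_pass_scan(marginalize(model), genome,
                             ScanConfig(first_pass_cutoff=10_000,
                                        report_cutoff=10_000))
        assert len(hi) <= len(lo) and hi == []


class TestTwoPass:
    @pytest.mark.parametrize("strand", "+-")
    def test_implant_recovered_with_tight_bounds(self, fixture_set, strand):
        rng = np.random.default_rng(3)
        model = fixture_set.family_models["Tyr-GTA"]
        genome, b, e = _implant_genome(model, rng, strand=strand, seed=99)
        hits = scan_sequences(model, [genome])
        ours = [h for h in hits if h.strand == strand]
        assert len(ours) == 1
        h = ours[0]
        assert abs(h.begin - b) <= 3 and abs(h.end - e) <= 3
        assert h.score >= 20

    def test_report_cutoff_monotone(self, fixture_set):
        rng = np.random.default_rng(3)
        model = fixture_set.family_models["Tyr-GTA"]
        genome, _, _ = _implant_genome(model, rng, seed=99)
        base = scan_sequences(model, [genome])
        strict = scan_sequences(model, [genome],
                                ScanConfig(report_cutoff=10_000))
        assert len(strict) <= len(base)

    def test_hits_lie_inside_candidate_windows(self, fixture_set):
        rng = np.random.default_rng(3)
        model = fixture_set.family_models["Tyr-GTA"]
        genome, _, _ = _implant_genome(model, rng, seed=99)
        cands = first_pass_scan(marginalize(model), genome)
        span = marginalize(model).ncols + 2 * ScanConfig().candidate_flank
        windows = [(c.begin, c.end) for c in cands]
        windows += [(0, span), (len(genome) - span, len(genome))]
        for h in scan_sequences(model, [genome]):
            assert any(h.begin >= wb and h.end <= we for wb, we in windows)

    def test_revcomp_genome_mirrors_hits(self, fixture_set):
        rng = np.random.default_rng(3)
        model = fixture_set.family_models["Tyr-GTA"]
        genome, _, _ = _implant_genome(model, rng, seed=99)
        L = len(genome)
        rc = NucSequence("g", revcomp(genome.residues))
        fwd = scan_sequences(model, [genome])
        rev = scan_sequences(model, [rc])
        mirrored = sorted((L - h.end, L - h.begin,
                           "-" if h.strand == "+" else "+",
                           round(h.score, 6)) for h in fwd)
        got = sorted((h.begin, h.end, h.strand, round(h.score, 6))
                     for h in rev)
        assert mirrored == got


class TestScanMax:
    def test_superset_of_two_pass(self, fixture_set):
        rng = np.random.default_rng(11)
        model = fixture_set.family_models["Gly-GCC"]
        genome, _, _ = _implant_genome(model, rng, length=2500, pos=1200,
                                       seed=5)
        two = scan_sequences(model, [genome])
        mx = scan_max(model, genome)
        spans_mx = {(h.strand, h.begin, h.end) for h in mx}
        for h in two:
            assert any(s == h.strand and abs(b - h.begin) <= 3
                       and abs(e - h.end) <= 3 for s, b, e in spans_mx)

    def test_empty_sequence(self, hairpin_model):
        assert scan_max(hairpin_model, NucSequence("e", "A")) == []

    def test_window_smaller_than_model_rejected(self, fixture_set):
        model = fixture_set.domain_model
        with pytest.raises(ValueError):
            scan_max(model, NucSequence("g", "ACGT" * 30),
                     ScanConfig(max_mode_window=40, max_mode_overlap=20))


def _hit(begin, end, score, model="m1", strand="+"):
    parse = ParseResult(score=score, primary_bits=score, secondary_bits=0.0,
                        col_assign=[], inserts=[], begin=0, end=end - begin)
    return Hit("c", strand, begin, end, parse, model)


class TestResolveOverlaps:
    def test_top_score_wins(self):
        kept = resolve_overlaps([_hit(100, 170, 80.0, "m1"),
                                 _hit(105, 175, 60.0, "m2")])
        assert len(kept) == 1 and kept[0].score == 80.0

    def test_disjoint_retained(self):
        kept = resolve_overlaps([_hit(0, 70, 50.0), _hit(200, 270, 40.0)])
        assert len(kept) == 2

    def test_opposite_strands_not_merged(self):
        kept = resolve_overlaps([_hit(0, 70, 50.0, strand="+"),
                                 _hit(10, 60, 40.0, strand="-")])
        assert len(kept) == 2

    def test_exact_tie_lexicographic_model(self):
        kept = resolve_overlaps([_hit(0, 70, 50.0, "zeta"),
                                 _hit(0, 70, 50.0, "alpha")])
        assert kept[0].model == "alpha"


def test_merge_candidates_same_strand_only():
    from cloverscan.scanner import Candidate
    cands = [Candidate("c", "+", 0, 100, 12.0),
             Candidate("c", "+", 50, 180, 15.0),
             Candidate("c", "-", 60, 160, 11.0)]
    merged = merge_candidates(cands)
    plus = [c for c in merged if c.strand == "+"]
    assert len(plus) == 1 and (plus[0].begin, plus[0].end) == (0, 180)
    assert plus[0].first_pass_bits == 15.0
    assert len(merged) == 2
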