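"""Two-pass genome scanning plus the exhaustive single-pass mode.

The default pipeline mirrors a filter-then-confirm design: a structure-free
linear profile is swept over both strands at a permissive 10-bit cutoff to
gather candidate windows (extended by a flank and merged when overlapping),
and each window is then re-scored with the full structural model; hits at
or above the 20-bit reporting threshold are emitted with exact coordinates.
The exhaustive mode slides fixed windows over the whole sequence instead,
trading time for independence from the first-pass filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScanConfig
from .dp import ParseResult, score_sequence
from .model import NEG, LinearProfile, ProfileSCFG, marginalize, seq_to_codes
from .records import NucSequence, revcomp


@dataclass
class Candidate:
    seq_id: str
    strand: str
    begin: int          # window, forward internal coordinates
    end: int
    first_pass_bits: float


@dataclass
class Hit:
    seq_id: str
    strand: str
    begin: int          # exact span, forward internal coordinates
    end: int
    parse: ParseResult
    model: str
    window_begin: int = 0     # the scored window (forward coordinates)
    window_end: int = 0

    @property
    def score(self) -> float:
        return self.parse.score


# ---------------------------------------------------------------------------
# First pass: structure-free glocal Viterbi (local in sequence, global in
# the profile), vectorised over positions.

def _insert_transform(S: np.ndarray, c0: float, a: float, b: float) -> np.ndarray:
    # out[p] = max(c0 + S[p], a + max_{m>=1} (m-1)*b + S[p-m])
    L = len(S) - 1
    out = c0 + S
    if a <= NEG / 2:
        return out
    drift = S - b * np.arange(L + 1)
    run = np.maximum.accumulate(drift)
    t = np.full(L + 1, NEG)
    t[1:] = a + b * np.arange(L) + run[:-1]
    return np.maximum(out, t)


def _first_pass_ends(profile: LinearProfile, codes: np.ndarray) -> np.ndarray:
    """Best glocal alignment score ending at each position (free start)."""
    L = len(codes)
    S = np.zeros(L + 1)
    S = _insert_transform(S, profile.ins_c0[0], profile.ins_a[0],
                          profile.ins_b[0])
    for c in range(profile.ncols):
        em = profile.em[c][codes]
        Mv = np.full(L + 1, NEG)
        Mv[1:] = profile.tm[c] + em + S[:-1]
        S = np.maximum(Mv, profile.td[c] + S)
        S = _insert_transform(S, profile.ins_c0[c + 1], profile.ins_a[c + 1],
                              profile.ins_b[c + 1])
    return S


def _strand_candidates(profile: LinearProfile, codes: np.ndarray,
                       cfg: ScanConfig, chunk: int = 1 << 18) -> list:
    """(first_end, last_end, bits) segments of qualifying end positions."""
    L = len(codes)
    overlap = profile.ncols + 4 * cfg.candidate_flank
    hits = {}
    start = 0
    while start < L or (start == 0 and L == 0):
        stop = min(L, start + chunk)
        E = _first_pass_ends(profile, codes[start:stop])
        for p in np.nonzero(E >= cfg.first_pass_cutoff)[0]:
            g = start + int(p)
            if g not in hits or E[p] > hits[g]:
                hits[g] = float(E[p])
        if stop == L:
            break
        start = stop - overlap
    if not hits:
        return []
    merge_gap = profile.ncols + 30
    segs = []
    for p in sorted(hits):
        if segs and p - segs[-1][1] <= merge_gap:
            segs[-1][1] = p
            segs[-1][2] = max(segs[-1][2], hits[p])
        else:
            segs.append([p, p, hits[p]])
    return [(a, b, s) for a, b, s in segs]


def first_pass_scan(profile: LinearProfile, seq: NucSequence,
                    cfg: ScanConfig = None) -> list:
    """Gather candidate windows on both strands at the first-pass cutoff."""
    cfg = cfg or ScanConfig()
    L = len(seq)
    fwd = seq_to_codes(seq.residues)
    rev = seq_to_codes(revcomp(seq.residues))
    span = profile.ncols + 2 * cfg.candidate_flank
    cands = []
    for strand, codes in (("+", fwd), ("-", rev)):
        for first_p, last_p, bits in _strand_candidates(profile, codes, cfg):
            wb = max(0, first_p - span)
            we = min(L, last_p + cfg.candidate_flank)
            if strand == "-":
                wb, we = L - we, L - wb
            cands.append(Candidate(seq.id, strand, wb, we, bits))
    return merge_candidates(cands)


def merge_candidates(cands: list) -> list:
    """Merge overlapping candidate windows on the same strand."""
    out = []
    for strand in "+-":
        group = sorted((c for c in cands if c.strand == strand),
                       key=lambda c: (c.seq_id, c.begin))
        for c in group:
            if (out and out[-1].strand == strand
                    and out[-1].seq_id == c.seq_id
                    and c.begin <= out[-1].end):
                out[-1] = Candidate(c.seq_id, strand, out[-1].begin,
                                    max(out[-1].end, c.end),
                                    max(out[-1].first_pass_bits,
                                        c.first_pass_bits))
            else:
                out.append(c)
    return sorted(out, key=lambda c: (c.seq_id, c.begin, c.strand))


# ---------------------------------------------------------------------------
# Second pass: structural confirmation

def _window_hits(model: ProfileSCFG, seq: NucSequence, strand: str,
                 wb: int, we: int, cutoff: float,
                 trunc5_ok: bool, trunc3_ok: bool, out: list) -> None:
    """Best structural hit in a window; recurse on the flanks around it."""
    if we - wb < 15:
        return
    sub = seq.residues[wb:we]
    if strand == "-":
        sub = revcomp(sub)
    allow = trunc5_ok or trunc3_ok
    parse = score_sequence(model, sub, mode="local", allow_trunc=allow)
    # a truncated parse is only honoured when anchored at a true sequence end
    if (parse.trunc5 and not trunc5_ok) or (parse.trunc3 and not trunc3_ok):
        parse = score_sequence(model, sub, mode="local", allow_trunc=False)
    if parse.score < cutoff or parse.end <= parse.begin:
        return
    if strand == "+":
        begin, end = wb + parse.begin, wb + parse.end
    else:
        begin, end = we - parse.end, we - parse.begin
    out.append(Hit(seq.id, strand, begin, end, parse, model.name, wb, we))
    # additional genes may share a merged window: rescan both remainders
    if strand == "+":
        left = (wb, begin, trunc5_ok, False)
        right = (end, we, False, trunc3_ok)
    else:
        left = (wb, begin, False, trunc3_ok)
        right = (end, we, trunc5_ok, False)
    for b2, e2, t5, t3 in (left, right):
        _window_hits(model, seq, strand, b2, e2, cutoff, t5, t3, out)


def second_pass(model: ProfileSCFG, candidates: list, seqs: dict,
                cfg: ScanConfig = None) -> list:
    """Structurally re-score candidate windows; keep hits >= report cutoff."""
    cfg = cfg or ScanConfig()
    hits = []
    for cand in candidates:
        seq = seqs[cand.seq_id]
        L = len(seq)
        if cand.strand == "+":
            t5_ok, t3_ok = cand.begin == 0, cand.end == L
        else:
            t5_ok, t3_ok = cand.end == L, cand.begin == 0
        _window_hits(model, seq, cand.strand, cand.begin, cand.end,
                     cfg.report_cutoff, t5_ok, t3_ok, hits)
    return resolve_overlaps(hits)


def scan_sequences(model: ProfileSCFG, seqs: list,
                   cfg: ScanConfig = None, profile: LinearProfile = None) -> list:
    """Default two-pass pipeline over a collection of sequences.

    Besides the first-pass candidates, the first and last window of every
    sequence are always rescored structurally: genes truncated by a contig
    end can fall below the structure-free first-pass cutoff yet still
    exceed the reporting threshold once boundary truncation is allowed.
    """
    cfg = cfg or ScanConfig()
    profile = profile or marginalize(model)
    by_id = {s.id: s for s in seqs}
    cands = []
    span = profile.ncols + 2 * cfg.candidate_flank
    for s in seqs:
        cands.extend(first_pass_scan(profile, s, cfg))
        L = len(s)
        for strand in "+-":
            cands.append(Candidate(s.id, strand, 0, min(L, span), 0.0))
            cands.append(Candidate(s.id, strand, max(0, L - span), L, 0.0))
    return second_pass(model, merge_candidates(cands), by_id, cfg)


def scan_max(model: ProfileSCFG, seq: NucSequence,
             cfg: ScanConfig = None) -> list:
    """Exhaustive single-pass structural scan over sliding windows."""
    cfg = cfg or ScanConfig()
    if cfg.max_mode_window < model.ncols:
        raise ValueError("max-mode window smaller than the model span")
    L = len(seq)
    step = cfg.max_mode_window - cfg.max_mode_overlap
    hits = []
    wb = 0
    while True:
        we = min(L, wb + cfg.max_mode_window)
        for strand in "+-":
            if strand == "+":
                t5_ok, t3_ok = wb == 0, we == L
            else:
                t5_ok, t3_ok = we == L, wb == 0
            _window_hits(model, seq, strand, wb, we, cfg.report_cutoff,
                         t5_ok, t3_ok, hits)
        if we >= L:
            break
        wb += step
    # duplicate hits arise from overlapping windows: dedupe by coordinates
    seen = {}
    for h in hits:
        key = (h.seq_id, h.strand, h.begin, h.end)
        if key not in seen or h.score > seen[key].score:
            seen[key] = h
    return resolve_overlaps(list(seen.values()))


def resolve_overlaps(hits: list) -> list:
    """Keep the top-scoring hit at each same-strand overlapping locus.

    Ties break to the lexicographically first model name, then leftmost.
    """
    order = sorted(hits, key=lambda h: (-h.score, h.model, h.begin))
    kept = []
    for h in order:
        clash = any(
            k.seq_id == h.seq_id and k.strand == h.strand
            and h.begin < k.end and k.begin < h.end
            for k in kept
        )
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.seq_id, h.begin, h.strand))
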