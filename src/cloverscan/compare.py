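"""Categorised agreement between two tRNA annotation sets.

Nuclear comparisons use four categories at a 10-nt boundary tolerance:
consistent, isotype mismatch, novel (prediction only), not detected
(reference only).  Mitochondrial comparisons add a position-mismatch
category at a 15-nt tolerance: same isotype but opposite strand, or
boundaries beyond the tolerance while still overlapping.

Matching is one-to-one greedy by overlap length (ties to the larger
overlap, then leftmost); "same genomic locus" for an isotype mismatch
means at least 50% reciprocal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import CompareConfig

NUCLEAR_CATEGORIES = ("consistent", "isotype_mismatch", "novel",
                      "not_detected")
MITO_CATEGORIES = ("consistent", "isotype_mismatch", "position_mismatch",
                   "novel", "not_detected")


@dataclass
class ComparisonResult:
    counts: dict = field(default_factory=dict)
    pred_labels: list = field(default_factory=list)   # (record, category)
    ref_labels: list = field(default_factory=list)

    def table(self) -> str:
        lines = ["category\tcount"]
        lines += [f"{k}\t{v}" for k, v in self.counts.items()]
        return "\n".join(lines) + "\n"


def _overlap(a, b) -> int:
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.begin, b.begin))


def _reciprocal50(a, b) -> bool:
    ov = _overlap(a, b)
    return ov >= 0.5 * (a.end - a.begin) and ov >= 0.5 * (b.end - b.begin)


def _greedy_match(preds, refs, same_strand_only: bool) -> list:
    """One-to-one pairs by descending overlap; ties larger overlap, leftmost."""
    cand = []
    for pi, p in enumerate(preds):
        for ri, r in enumerate(refs):
            if same_strand_only and p.strand != r.strand:
                continue
            ov = _overlap(p, r)
            if ov > 0:
                cand.append((-ov, p.begin, r.begin, pi, ri))
    cand.sort()
    used_p, used_r, pairs = set(), set(), []
    for _, _, _, pi, ri in cand:
        if pi in used_p or ri in used_r:
            continue
        used_p.add(pi)
        used_r.add(ri)
        pairs.append((pi, ri))
    return pairs


def _boundaries_within(p, r, tol: int) -> bool:
    return abs(p.begin - r.begin) <= tol and abs(p.end - r.end) <= tol


def compare_nuclear(preds, refs, cfg: CompareConfig = None) -> ComparisonResult:
    """Four-category comparison with a 10-nt boundary tolerance."""
    cfg = cfg or CompareConfig()
    tol = cfg.nuclear_tolerance
    res = ComparisonResult(counts={k: 0 for k in NUCLEAR_CATEGORIES})
    pairs = _greedy_match(preds, refs, same_strand_only=True)
    lab_p, lab_r = {}, {}
    for pi, ri in pairs:
        p, r = preds[pi], refs[ri]
        same_identity = (p.isotype == r.isotype and p.anticodon == r.anticodon)
        if same_identity and _boundaries_within(p, r, tol):
            lab_p[pi] = lab_r[ri] = "consistent"
        elif p.isotype != r.isotype and _reciprocal50(p, r):
            lab_p[pi] = lab_r[ri] = "isotype_mismatch"
        # otherwise the pair is dissolved: novel + not detected
    for pi, p in enumerate(preds):
        cat = lab_p.get(pi, "novel")
        res.pred_labels.append((p, cat))
        res.counts[cat] += 1          # matched pairs counted on this side
    for ri, r in enumerate(refs):
        cat = lab_r.get(ri, "not_detected")
        res.ref_labels.append((r, cat))
        if cat == "not_detected":
            res.counts[cat] += 1
    return res


def compare_mito(preds, refs, cfg: CompareConfig = None) -> ComparisonResult:
    """Five-category comparison with a 15-nt tolerance and strand rule."""
    cfg = cfg or CompareConfig()
    tol = cfg.mito_tolerance
    res = ComparisonResult(counts={k: 0 for k in MITO_CATEGORIES})
    pairs = _greedy_match(preds, refs, same_strand_only=False)
    lab_p, lab_r = {}, {}
    for pi, ri in pairs:
        p, r = preds[pi], refs[ri]
        if p.isotype == r.isotype:
            if p.strand == r.strand and _boundaries_within(p, r, tol):
                lab_p[pi] = lab_r[ri] = "consistent"
            else:
                lab_p[pi] = lab_r[ri] = "position_mismatch"
        elif _reciprocal50(p, r):
            lab_p[pi] = lab_r[ri] = "isotype_mismatch"
    for pi, p in enumerate(preds):
        cat = lab_p.get(pi, "novel")
        res.pred_labels.append((p, cat))
        res.counts[cat] += 1          # matched pairs counted on this side
    for ri, r in enumerate(refs):
        cat = lab_r.get(ri, "not_detected")
        res.ref_labels.append((r, cat))
        if cat == "not_detected":
            res.counts[cat] += 1
    return res
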