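"""Intron detection: canonical (37/38) and noncanonical bulge-helix-bulge.

Canonical tRNA introns sit one nucleotide downstream of the anticodon and
appear in a parse as an insert run attached between that consensus column
and its successor.  Noncanonical introns are found by scanning the
candidate (extended with flanking sequence) with bulge-helix-bulge
structural models and accepting a splice only when the re-scored mature
tRNA improves on the unspliced form; the search iterates because closely
spaced introns can hide one another's motifs, and stops when the score no
longer improves, the iteration cap is reached, or the mature tRNA would
drop below the minimum plausible length.
"""

from __future__ import annotations

from .config import IntronConfig
from .dp import ParseResult, score_sequence
from .model import ProfileSCFG
from .records import IntronAnnotation


def splice(residues: str, begin: int, end: int) -> str:
    """Remove ``[begin, end)`` from a sequence."""
    if begin > end or begin < 0 or end > len(residues):
        raise ValueError(f"invalid intron bounds [{begin}, {end})")
    return residues[:begin] + residues[end:]


def detect_canonical(parse: ParseResult, model: ProfileSCFG,
                     cfg: IntronConfig = None) -> list:
    """Canonical introns: long insert runs just 3' of the anticodon.

    Bounds are positions within the scored sequence; the caller maps them
    to genomic coordinates.
    """
    cfg = cfg or IntronConfig()
    if model.anticodon_cols is None:
        return []
    # the canonical point is between the column one 3' of the anticodon and
    # its successor; splice-boundary bases can mimic a neighbouring
    # consensus column, so runs attached one region to either side count
    target = model.anticodon_cols[2] + 1
    best = None
    for region in (target - 1, target, target + 1):
        if region < 0 or region >= model.ncols:
            continue
        positions = sorted(p for p, r in parse.inserts if r == region)
        if len(positions) < cfg.min_intron_len:
            continue
        if positions[-1] - positions[0] + 1 != len(positions):
            continue
        if best is None or len(positions) > len(best):
            best = positions
    if best is None:
        return []
    return [IntronAnnotation(kind="canonical", begin=best[0],
                             end=best[-1] + 1)]


def search_noncanonical(precursor: str, trna_model: ProfileSCFG,
                        bhb_models: dict, cfg: IntronConfig = None):
    """Iterative splice-and-rescore over BHB model hits.

    ``precursor`` is the candidate sequence already extended with flanks
    (model orientation).  Returns ``(mature_parse, introns, mature_seq,
    index_map)`` where intron bounds refer to the *precursor* and
    ``index_map[i]`` gives the precursor position of mature position i.
    """
    cfg = cfg or IntronConfig()
    cur = precursor
    index_map = list(range(len(precursor)))
    best_parse = score_sequence(trna_model, cur, mode="local")
    best_score = best_parse.score
    introns: list = []

    for iteration in range(1, cfg.max_iterations + 1):
        chosen = None
        for name in sorted(bhb_models):
            bp = score_sequence(bhb_models[name], cur, mode="local")
            if bp.score < cfg.bhb_accept_bits:
                continue
            b, e = bp.begin, bp.end
            if e - b < cfg.min_intron_len:
                continue
            # a motif interrupted by a long insertion has not formed yet
            if e - b > bhb_models[name].ncols + cfg.bhb_span_slack:
                continue
            trial = splice(cur, b, e)
            tp = score_sequence(trna_model, trial, mode="local")
            if tp.end - tp.begin < cfg.min_mature_len:
                continue
            # accept only a strict improvement of the mature-tRNA score
            if tp.score > best_score and (
                    chosen is None or tp.score > chosen[0]):
                chosen = (tp.score, b, e, bp.score, trial, tp)
        if chosen is None:
            break
        score, b, e, bhb_bits, trial, tp = chosen
        introns.append(IntronAnnotation(
            kind="noncanonical", begin=index_map[b],
            end=index_map[e - 1] + 1, bhb_bits=bhb_bits,
            iteration=iteration))
        del index_map[b:e]
        cur = trial
        best_parse, best_score = tp, score
        if len(cur) < cfg.min_mature_len:
            break

    return best_parse, introns, cur, index_map
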