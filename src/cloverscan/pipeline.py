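"""End-to-end prediction: scan, intron search, classification.

Turns raw structural hits into :class:`TRNAPrediction` records: maps parse
coordinates to genomic coordinates on either strand, annotates canonical
(37/38) introns from insert runs, optionally runs the bulge-helix-bulge
noncanonical intron search (archaeal mode), extracts the anticodon, and
runs the comparative isotype classification.
"""

from __future__ import annotations

from .classifier import DecodingTable, classify, score_isotypes
from .config import IntronConfig, ScanConfig
from .dp import extract_anticodon, score_sequence
from .introns import detect_canonical, search_noncanonical, splice
from .model import ProfileSCFG, marginalize
from .records import IntronAnnotation, TRNAPrediction, revcomp
from .scanner import Hit, scan_sequences


def _to_genomic(hit: Hit, b: int, e: int) -> tuple:
    """Map an interval in window-oriented coordinates to forward genomic."""
    if hit.strand == "+":
        return hit.window_begin + b, hit.window_begin + e
    return hit.window_end - e, hit.window_end - b


def hit_to_prediction(hit: Hit, seq, model: ProfileSCFG,
                      table: DecodingTable, registry: dict = None,
                      bhb_models: dict = None,
                      intron_cfg: IntronConfig = None) -> TRNAPrediction:
    intron_cfg = intron_cfg or IntronConfig()
    sub = seq.residues[hit.window_begin:hit.window_end]
    if hit.strand == "-":
        sub = revcomp(sub)
    parse = hit.parse
    residues = sub
    introns = []
    # map a position in the current parse frame to window coordinates
    to_window = lambda p: p  # noqa: E731

    if bhb_models:
        # extend the hit span with flanks and run the iterative BHB search
        pre_b = max(0, parse.begin - intron_cfg.flank)
        pre_e = min(len(sub), parse.end + intron_cfg.flank)
        precursor = sub[pre_b:pre_e]
        mparse, bhb_introns, mature_seq, index_map = search_noncanonical(
            precursor, model, bhb_models, intron_cfg)
        if bhb_introns:
            for it in bhb_introns:
                gb, ge = _to_genomic(hit, pre_b + it.begin, pre_b + it.end)
                introns.append(IntronAnnotation(
                    kind="noncanonical", begin=gb, end=ge,
                    bhb_bits=it.bhb_bits, iteration=it.iteration))
            parse = mparse
            residues = mature_seq
            to_window = lambda p: pre_b + (  # noqa: E731
                index_map[p] if p < len(index_map)
                else (index_map[-1] + 1 if index_map else 0))
            gb, ge = _to_genomic(hit, to_window(mparse.begin),
                                 pre_b + index_map[mparse.end - 1] + 1)
            hit = Hit(hit.seq_id, hit.strand, min(gb, ge), max(gb, ge),
                      mparse, hit.model, hit.window_begin, hit.window_end)

    # canonical introns from insert runs one position 3' of the anticodon
    mature = residues[parse.begin:parse.end]
    for it in detect_canonical(parse, model, intron_cfg):
        gb, ge = _to_genomic(hit, to_window(it.begin),
                             to_window(it.end - 1) + 1)
        introns.append(IntronAnnotation(kind="canonical", begin=min(gb, ge),
                                        end=max(gb, ge)))
        rel_b, rel_e = it.begin - parse.begin, it.end - parse.begin
        mature = splice(mature, rel_b, rel_e)

    # final reported scores and anticodon come from the mature tRNA
    mparse = score_sequence(model, mature, mode="global",
                            allow_trunc=parse.trunc5 or parse.trunc3)
    anticodon = extract_anticodon(mparse, model, mature)
    # the scan model's anticodon columns are masked to NNN, so its parses
    # carry no anchor there; when isotype models are available, read the
    # anticodon off the best-scoring one instead (its loop is anchored)
    iso_scores = {}
    if registry:
        iso_scores = score_isotypes(mature, registry)
        top = sorted(iso_scores, key=lambda k: (-iso_scores[k], k))[0]
        top_model = registry[top]
        if top_model.anticodon_cols is not None:
            tparse = score_sequence(top_model, mature, mode="global",
                                    allow_trunc=parse.trunc5 or parse.trunc3)
            refined = extract_anticodon(tparse, top_model, mature)
            if refined != "NNN":
                anticodon = refined
    pred = TRNAPrediction(
        seq_id=hit.seq_id, begin=hit.begin, end=hit.end, strand=hit.strand,
        overall_bits=mparse.score, primary_bits=mparse.primary_bits,
        secondary_bits=mparse.secondary_bits, anticodon=anticodon,
        isotype_scores=iso_scores, model=hit.model,
    )
    if parse.trunc5:
        pred.flags.add("trunc5")
    if parse.trunc3:
        pred.flags.add("trunc3")
    pred.introns = sorted(introns, key=lambda x: x.begin)
    classify(pred, table, registry or {}, residues=mature)
    return pred


def predict(seqs: list, model: ProfileSCFG, table: DecodingTable,
            registry: dict = None, bhb_models: dict = None,
            scan_cfg: ScanConfig = None,
            intron_cfg: IntronConfig = None) -> list:
    """Run the default two-pass pipeline and classify every hit.

    With BHB models (archaeal mode), candidates are gathered down to the
    first-pass cutoff so that genes whose unspliced form scores poorly can
    still be rescued by intron removal; the reporting threshold is then
    applied to the mature-sequence score.
    """
    scan_cfg = scan_cfg or ScanConfig()
    by_id = {s.id: s for s in seqs}
    if bhb_models:
        provisional = ScanConfig(
            first_pass_cutoff=scan_cfg.first_pass_cutoff,
            report_cutoff=scan_cfg.first_pass_cutoff,
            candidate_flank=scan_cfg.candidate_flank,
            max_mode_window=scan_cfg.max_mode_window,
            max_mode_overlap=scan_cfg.max_mode_overlap,
        )
        hits = scan_sequences(model, seqs, provisional)
    else:
        hits = scan_sequences(model, seqs, scan_cfg)
    preds = [
        hit_to_prediction(h, by_id[h.seq_id], model, table, registry,
                          bhb_models, intron_cfg)
        for h in hits
    ]
    preds = [p for p in preds if p.overall_bits >= scan_cfg.report_cutoff]
    return sorted(preds, key=lambda p: (p.seq_id, p.begin))
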