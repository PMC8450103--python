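"""Vertebrate mitochondrial search mode.

Mitochondrial tRNAs are divergent enough to need their own models: one per
isotype/anticodon class, 22 in vertebrates (one per amino acid, with two
leucine and two serine classes), including a D-armless architecture for
Ser(GCU).  Scanning runs every model over both strands, merges overlapping
hits keeping the top-scoring model, reports the winning model's identity
as the isotype, and flags loci whose extracted anticodon implies a
different isotype under the vertebrate mitochondrial genetic code.
"""

from __future__ import annotations

from .classifier import DecodingTable, anticodon_to_isotype
from .config import IntronConfig, ScanConfig
from .model import ProfileSCFG, train_model
from .pipeline import hit_to_prediction
from .records import NucSequence
from .scanner import resolve_overlaps, scan_sequences
from .training import align_to_model

# the 22 vertebrate mt-tRNA classes: 20 amino acids, Leu x2, Ser x2
VERT_MITO_CLASSES = (
    ("Ala", "TGC", "standard"), ("Arg", "TCG", "standard"),
    ("Asn", "GTT", "standard"), ("Asp", "GTC", "standard"),
    ("Cys", "GCA", "standard"), ("Gln", "TTG", "standard"),
    ("Glu", "TTC", "standard"), ("Gly", "TCC", "standard"),
    ("His", "GTG", "standard"), ("Ile", "GAT", "standard"),
    ("Leu", "TAA", "standard"), ("Leu", "TAG", "standard"),
    ("Lys", "TTT", "standard"), ("Met", "CAT", "standard"),
    ("Phe", "GAA", "standard"), ("Pro", "TGG", "standard"),
    ("Ser", "GCT", "d_armless"), ("Ser", "TGA", "standard"),
    ("Thr", "TGT", "standard"), ("Trp", "TCA", "standard"),
    ("Tyr", "GTA", "standard"), ("Val", "TAC", "standard"),
)


class RegistryError(ValueError):
    pass


def class_name(isotype: str, anticodon: str) -> str:
    return f"{isotype}-{anticodon}"


def build_mito_registry(alignments: list, pseudocount: float = 1.0,
                        two_round: bool = True) -> dict:
    """Train the 22-model vertebrate registry from per-class alignments.

    Each alignment must carry isotype metadata and an anticodon marker;
    training is two-round: a first model from the seed alignment, then a
    realignment of its own members to that model and a final retrain.
    """
    expected = {class_name(i, a) for i, a, _ in VERT_MITO_CLASSES}
    seen = {}
    for aln in alignments:
        seen[aln.name] = aln
    missing = sorted(expected - set(seen))
    if missing or len(seen) != len(VERT_MITO_CLASSES):
        raise RegistryError(
            f"expected exactly the 22 vertebrate classes; missing: {missing}; "
            f"got {len(seen)}")
    registry = {}
    for name in sorted(seen):
        aln = seen[name]
        m1 = train_model(aln, pseudocount=pseudocount, name=name)
        if two_round:
            seqs = [
                NucSequence(sid, text.replace("-", "").replace(".", ""))
                for sid, text in aln.rows
            ]
            realigned = align_to_model(m1, seqs, name=name,
                                       isotype=aln.isotype)
            registry[name] = train_model(realigned, pseudocount=pseudocount,
                                         name=name)
        else:
            registry[name] = m1
    return registry


def mito_scan(seqs: list, registry: dict, report_cutoff: float = 20.0,
              table: DecodingTable = None,
              scan_cfg: ScanConfig = None) -> list:
    """Scan with all registry models, merge, keep the top model per locus."""
    table = table or DecodingTable.load("mito_vert")
    base = scan_cfg or ScanConfig()
    cfg = ScanConfig(
        first_pass_cutoff=min(base.first_pass_cutoff, report_cutoff),
        report_cutoff=report_cutoff,
        candidate_flank=base.candidate_flank,
        max_mode_window=base.max_mode_window,
        max_mode_overlap=base.max_mode_overlap,
    )
    by_id = {s.id: s for s in seqs}
    models = {m.name: m for m in registry.values()}
    hits = []
    for name in sorted(registry):
        hits.extend(scan_sequences(registry[name], seqs, cfg))
    merged = resolve_overlaps(hits)
    preds = []
    for h in merged:
        model = models[h.model]
        pred = hit_to_prediction(h, by_id[h.seq_id], model, table,
                                 registry={}, intron_cfg=IntronConfig())
        pred.isotype_override = model.isotype
        pred.isotype_by_model = model.isotype
        implied = anticodon_to_isotype(pred.anticodon, table)
        if implied != model.isotype:
            pred.flags.add("isotype_mismatch")
        preds.append(pred)
    return sorted(preds, key=lambda p: (p.seq_id, p.begin))
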