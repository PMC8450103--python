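"""Model-guided alignment and two-round isotype-specific training.

Isotype-specific models are built iteratively: sequences are first grouped
by their anticodon-derived label, aligned to the domain model and trained
into intermediate models; every sequence is then *re*-grouped by its
highest-scoring intermediate model regardless of its anticodon, aligned to
that model, and the groups are retrained into the final models.  The
second round lets a gene whose anticodon has mutated (or been misread)
join the family its body actually resembles.
"""

from __future__ import annotations

import warnings

from .dp import score_sequence
from .formats import SeedAlignment
from .model import ProfileSCFG, train_model
from .records import NucSequence


def align_to_model(model: ProfileSCFG, seqs: list, name: str = None,
                   isotype: str = None) -> SeedAlignment:
    """Build a seed alignment from the global parses of sequences.

    Columns are the model's consensus columns; inserted residues open
    all-gap insert columns (annotated '.' in the structure line).
    """
    parses = [score_sequence(model, s, mode="global") for s in seqs]
    nregions = model.ncols + 1
    ins_width = [0] * nregions
    per_seq_ins = []
    for p in parses:
        runs = {r: [] for r in range(-1, model.ncols)}
        for pos, region in p.inserts:
            runs[region].append(pos)
        per_seq_ins.append(runs)
        for r, positions in runs.items():
            ins_width[r + 1] = max(ins_width[r + 1], len(positions))

    ss_chars = []
    ac_marker_cols = []
    col_pos_in_aln = {}
    width = 0
    for c in range(model.ncols + 1):
        ss_chars.extend("." * ins_width[c])
        width += ins_width[c]
        if c < model.ncols:
            ss_chars.append(model.ss_cons[c])
            col_pos_in_aln[c] = width
            width += 1
    if model.anticodon_cols:
        ac_marker_cols = [col_pos_in_aln[c] for c in model.anticodon_cols]

    rows = []
    for seq, p, runs in zip(seqs, parses, per_seq_ins):
        res = seq.residues if hasattr(seq, "residues") else str(seq)
        chars = []
        for c in range(model.ncols + 1):
            positions = sorted(runs[c - 1])
            pad = ins_width[c] - len(positions)
            chars.extend(res[q] for q in positions)
            chars.extend("." * pad)
            if c < model.ncols:
                a = p.col_assign[c]
                chars.append(res[a[1]] if a[0] == "M" else "-")
        sid = seq.id if hasattr(seq, "id") else f"seq{len(rows)}"
        rows.append((sid, "".join(chars)))

    return SeedAlignment(
        rows=rows, ss_cons="".join(ss_chars),
        anticodon_cols=tuple(ac_marker_cols) if ac_marker_cols else None,
        name=name or model.name, domain=model.domain,
        isotype=isotype if isotype is not None else model.isotype,
        fold=model.fold,
    )


def two_round_isotype_training(labeled_seqs: list, domain_model: ProfileSCFG,
                               pseudocount: float = 1.0) -> dict:
    """Train per-isotype models in two rounds.

    ``labeled_seqs`` is a list of ``(NucSequence, isotype_label)`` pairs,
    the label normally derived from the anticodon.  Returns a mapping
    isotype -> trained :class:`ProfileSCFG`.
    """
    groups = {}
    for seq, label in labeled_seqs:
        groups.setdefault(label, []).append(seq)

    intermediate = {}
    for label in sorted(groups):
        aln = align_to_model(domain_model, groups[label], name=label,
                             isotype=label)
        intermediate[label] = train_model(aln, pseudocount=pseudocount,
                                          name=label)

    # round 2: regroup every sequence by its best-scoring intermediate
    # model, regardless of the anticodon-derived label
    regrouped = {label: [] for label in intermediate}
    for seq, _ in labeled_seqs:
        scores = {
            label: score_sequence(m, seq, mode="global").score
            for label, m in intermediate.items()
        }
        best = max(scores.values())
        winner = sorted(l for l, s in scores.items() if s == best)[0]
        regrouped[winner].append(seq)

    final = {}
    for label in sorted(regrouped):
        members = regrouped[label]
        if not members:
            warnings.warn(f"isotype {label}: no members after round 2; "
                          "model omitted")
            continue
        aln = align_to_model(intermediate[label], members, name=label,
                             isotype=label)
        final[label] = train_model(aln, pseudocount=pseudocount, name=label)
    return final
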