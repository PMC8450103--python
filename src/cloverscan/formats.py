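"""External file formats: FASTA, Stockholm seed alignments, prediction tables.

The Stockholm dialect used for seed alignments carries the consensus
secondary structure on ``#=GC SS_cons`` and marks the three anticodon
columns with ``*`` on a ``#=GC AC`` line (all other columns ``.``).
Family metadata travels on ``#=GF`` tags (ID/DOMAIN/ISOTYPE/FOLD).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO

from .records import (
    IUPAC,
    AnnotationRecord,
    FormatError,
    NucSequence,
    StructureError,
    TRNAPrediction,
)

OPEN_BRACKETS = "<([{"
CLOSE_BRACKETS = ">)]}"
UNPAIRED_CHARS = ".,-_:~"
GAP_CHARS = ".-_~"

VALID_FOLDS = ("standard", "sec_9_4", "sec_8_5", "d_armless")


def read_fasta(path) -> list:
    """Read a multi-record FASTA file into :class:`NucSequence` records.

    Records come back in file order, uppercased, with U normalised to T.
    An invalid residue raises :class:`FormatError` naming the record.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        out.append(NucSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def parse_pairs(ss_cons: str) -> dict:
    """Map each paired column to its partner; validate balanced nesting.

    All WUSS bracket variants are accepted; closers must match the type of
    the innermost open bracket, which also rejects crossing annotations.
    """
    stack = []
    pairs = {}
    for i, ch in enumerate(ss_cons):
        if ch in OPEN_BRACKETS:
            stack.append((ch, i))
        elif ch in CLOSE_BRACKETS:
            if not stack:
                raise StructureError(f"unbalanced bracket at column {i}")
            open_ch, j = stack.pop()
            if OPEN_BRACKETS.index(open_ch) != CLOSE_BRACKETS.index(ch):
                raise StructureError(
                    f"mismatched bracket types at columns {j},{i}"
                )
            pairs[j] = i
            pairs[i] = j
        elif ch not in UNPAIRED_CHARS:
            raise StructureError(f"unknown structure character {ch!r}")
    if stack:
        raise StructureError(f"unbalanced bracket at column {stack[-1][1]}")
    return pairs


@dataclass
class SeedAlignment:
    """A structure-annotated alignment: the model-training substrate."""

    rows: list                       # [(seq_id, aligned_text), ...]
    ss_cons: str
    anticodon_cols: tuple = None     # 3 consecutive column indices, or None
    name: str = "seed"
    domain: str = "eukaryote"        # eukaryote | bacteria | archaea | mito
    isotype: str = ""
    fold: str = "standard"
    pairs: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        width = len(self.ss_cons)
        for sid, text in self.rows:
            if len(text) != width:
                raise FormatError(f"ragged row {sid!r}")
            bad = set(text.upper()) - set(IUPAC) - set(GAP_CHARS)
            if bad:
                raise FormatError(f"row {sid!r}: invalid residues {sorted(bad)}")
        self.rows = [(sid, t.upper().replace("U", "T")) for sid, t in self.rows]
        self.pairs = parse_pairs(self.ss_cons)
        if self.fold not in VALID_FOLDS:
            raise FormatError(f"unknown fold tag {self.fold!r}")
        if self.anticodon_cols is not None:
            cols = tuple(self.anticodon_cols)
            if len(cols) != 3 or list(cols) != list(range(cols[0], cols[0] + 3)):
                raise FormatError("anticodon marker must span 3 consecutive columns")
            if any(c in self.pairs for c in cols):
                raise StructureError("anticodon columns must be unpaired")
            self.anticodon_cols = cols

    @property
    def width(self) -> int:
        return len(self.ss_cons)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SeedAlignment)
            and self.rows == other.rows
            and self.ss_cons == other.ss_cons
            and self.anticodon_cols == other.anticodon_cols
            and (self.name, self.domain, self.isotype, self.fold)
            == (other.name, other.domain, other.isotype, other.fold)
        )


def read_stockholm(path) -> SeedAlignment:
    with open(path) as fh:
        text = fh.read()
    return parse_stockholm(text)


def parse_stockholm(text: str) -> SeedAlignment:
    rows: dict = {}
    order: list = []
    gc: dict = {}
    gf: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip()
        if not line or line == "//" or line.startswith("# STOCKHOLM"):
            continue
        if line.startswith("#=GF"):
            try:
                _, tag, value = line.split(None, 2)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed #=GF line") from exc
            gf[tag] = value
        elif line.startswith("#=GC"):
            try:
                _, tag, value = line.split(None, 2)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed #=GC line") from exc
            gc[tag] = gc.get(tag, "") + value
        elif line.startswith("#"):
            continue
        else:
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: malformed alignment row")
            sid, chunk = parts
            if sid not in rows:
                order.append(sid)
                rows[sid] = ""
            rows[sid] += chunk
    if "SS_cons" not in gc:
        raise FormatError("missing #=GC SS_cons line")
    anticodon_cols = None
    if "AC" in gc:
        stars = [i for i, ch in enumerate(gc["AC"]) if ch == "*"]
        if stars:
            anticodon_cols = tuple(stars)
    return SeedAlignment(
        rows=[(sid, rows[sid]) for sid in order],
        ss_cons=gc["SS_cons"],
        anticodon_cols=anticodon_cols,
        name=gf.get("ID", "seed"),
        domain=gf.get("DOMAIN", "eukaryote"),
        isotype=gf.get("ISOTYPE", ""),
        fold=gf.get("FOLD", "standard"),
    )


def write_stockholm(aln: SeedAlignment, path=None) -> str:
    buf = io.StringIO()
    buf.write("# STOCKHOLM 1.0\n")
    buf.write(f"#=GF ID {aln.name}\n")
    buf.write(f"#=GF DOMAIN {aln.domain}\n")
    if aln.isotype:
        buf.write(f"#=GF ISOTYPE {aln.isotype}\n")
    buf.write(f"#=GF FOLD {aln.fold}\n")
    pad = max(len(sid) for sid, _ in aln.rows)
    pad = max(pad, len("#=GC SS_cons"))
    for sid, text in aln.rows:
        buf.write(f"{sid:<{pad}}  {text}\n")
    buf.write(f"{'#=GC SS_cons':<{pad}}  {aln.ss_cons}\n")
    if aln.anticodon_cols is not None:
        marker = "".join(
            "*" if i in aln.anticodon_cols else "." for i in range(aln.width)
        )
        buf.write(f"{'#=GC AC':<{pad}}  {marker}\n")
    buf.write("//\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Prediction tables

TABULAR_COLUMNS = [
    "SeqName", "tRNA#", "Begin", "End", "Isotype", "Anticodon",
    "IntronBegins", "IntronEnds", "Score", "Note",
]
DETAIL_COLUMNS = ["IsotypeModel", "IsotypeScore", "PrimaryScore",
                  "SecondaryScore"]

_FLAG_ORDER = ["pseudo", "trunc_start", "trunc_end", "IPD", "unexpected_anticodon"]


def _note(pred: TRNAPrediction) -> str:
    names = []
    flags = set(pred.flags)
    if "trunc5" in flags:
        flags.discard("trunc5")
        flags.add("trunc_start" if pred.strand == "+" else "trunc_end")
    if "trunc3" in flags:
        flags.discard("trunc3")
        flags.add("trunc_end" if pred.strand == "+" else "trunc_start")
    for f in _FLAG_ORDER:
        if f in flags:
            names.append(f)
    names.extend(sorted(flags - set(_FLAG_ORDER)))
    return ",".join(names) if names else "-"


def _tabular_coords(pred: TRNAPrediction) -> tuple:
    # 1-based inclusive; begin > end on the minus strand.
    if pred.strand == "+":
        return pred.begin + 1, pred.end
    return pred.end, pred.begin + 1


def write_predictions(preds, path=None, style: str = "tabular",
                      detail: bool = False) -> str:
    """Serialise predictions as a tabular table, GFF3 or BED6."""
    if style not in ("tabular", "gff3", "bed"):
        raise ValueError(f"unknown output style {style!r}")
    lines = []
    if style == "tabular":
        cols = TABULAR_COLUMNS + (DETAIL_COLUMNS if detail else [])
        lines.append("#" + "\t".join(cols))
        for n, p in enumerate(preds, 1):
            b, e = _tabular_coords(p)
            ib = ",".join(str(i.begin + 1) for i in p.introns) or "0"
            ie = ",".join(str(i.end) for i in p.introns) or "0"
            row = [p.seq_id, str(n), str(b), str(e), p.isotype, p.anticodon,
                   ib, ie, f"{p.overall_bits:.1f}", _note(p)]
            if detail:
                best = p.isotype_by_model or "-"
                score = max(p.isotype_scores.values()) if p.isotype_scores \
                    else float("nan")
                row += [best, f"{score:.1f}", f"{p.primary_bits:.1f}",
                        f"{p.secondary_bits:.1f}"]
            lines.append("\t".join(row))
    elif style == "gff3":
        lines.append("##gff-version 3")
        for n, p in enumerate(preds, 1):
            attrs = (
                f"ID=tRNA{n};isotype={p.isotype};anticodon={p.anticodon};"
                f"note={_note(p)}"
            )
            if detail and p.isotype_by_model:
                attrs += (
                    f";isotype_model={p.isotype_by_model};isotype_score="
                    f"{p.isotype_scores.get(p.isotype_by_model, float('nan')):.1f}"
                )
            lines.append("\t".join([
                p.seq_id, "cloverscan", "tRNA", str(p.begin + 1), str(p.end),
                f"{p.overall_bits:.1f}", p.strand, ".", attrs,
            ]))
    else:  # bed
        for p in preds:
            name = f"{p.isotype}-{p.anticodon}"
            lines.append("\t".join([
                p.seq_id, str(p.begin), str(p.end), name,
                str(int(round(p.overall_bits))), p.strand,
            ]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_predictions(path) -> list:
    """Parse a tabular prediction file back into :class:`AnnotationRecord`."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}:{lineno}: expected >=10 columns")
            seq_id, _, b, e, isotype, anticodon = parts[:6]
            score = float(parts[8])
            note = parts[9]
            b, e = int(b), int(e)
            if b <= e:
                begin, end, strand = b - 1, e, "+"
            else:
                begin, end, strand = e - 1, b, "-"
            flags = frozenset() if note in ("-", "") else frozenset(note.split(","))
            out.append(AnnotationRecord(
                seq_id=seq_id, begin=begin, end=end, strand=strand,
                isotype=isotype, anticodon=anticodon, score=score, note=flags,
            ))
    return out


def read_predictions_detail(path) -> list:
    """Parse a detail-style table into :class:`TRNAPrediction` records.

    Requires the detail columns (isotype model and score, primary and
    secondary scores) so post-scan filtering can be applied offline.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 14:
                raise FormatError(
                    f"{path}:{lineno}: detail columns required for filtering")
            seq_id, _, b, e, isotype, anticodon = parts[:6]
            b, e = int(b), int(e)
            if b <= e:
                begin, end, strand = b - 1, e, "+"
            else:
                begin, end, strand = e - 1, b, "-"
            note = parts[9]
            flags = set() if note in ("-", "") else set(note.split(","))
            pred = TRNAPrediction(
                seq_id=seq_id, begin=begin, end=end, strand=strand,
                overall_bits=float(parts[8]), anticodon=anticodon,
                isotype_by_anticodon=isotype,
                isotype_by_model=parts[10] if parts[10] != "-" else "",
                primary_bits=float(parts[12]), secondary_bits=float(parts[13]),
                flags=flags,
            )
            if parts[10] != "-":
                pred.isotype_scores = {parts[10]: float(parts[11])}
            out.append(pred)
    return out
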