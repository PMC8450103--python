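"""Compact profile-SCFG (mini covariance model) training and utilities.

A model is trained from a structure-annotated seed alignment.  Consensus
columns (gap fraction < 0.5) are arranged on a guide tree; each emitting
node carries bit-score log-odds emissions (single 4-vectors, pair 4x4
tables) and trained transition scores for match/delete (and the pair
left-only/right-only variants), plus geometric insert slots.  Scores are
log2 likelihood ratios against a background base composition (uniform by
default), so inserted residues score zero bits and N scores as the
background expectation (zero bits) everywhere.

Laplace pseudocounts (alpha = 1 per cell / per transition option) keep
every probability finite and make tiny hand-checkable examples exact:
one training row with an A at a column gives match bits
log2(((1+1)/(1+4)) / 0.25) ~ +0.678.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import guide as G
from .formats import SeedAlignment, GAP_CHARS
from .records import IUPAC, NucSequence

NEG = -1.0e30  # effective -infinity for bit scores

# insert-run geometry prior: expected run length ~10 nt when no inserts
# were observed in training (cf. the permissive insert states of covariance
# models); observed runs still dominate the estimate
EXT_PRIOR = 9.0
STOP_PRIOR = 1.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def seq_to_codes(residues: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A,C,G,T -> 0..3; ambiguity -> 4)."""
    out = np.full(len(residues), 4, dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = _CODE.get(ch, 4)
    return out


def _residue_weights(ch: str) -> np.ndarray:
    """Fractional base counts for one residue (uniform over its IUPAC set)."""
    bases = IUPAC[ch]
    w = np.zeros(4)
    for b in bases:
        w[_CODE[b]] += 1.0 / len(bases)
    return w


class TrainingError(ValueError):
    pass


@dataclass
class ProfileSCFG:
    """A trained structural profile over a fixed guide tree."""

    name: str
    domain: str
    isotype: str
    anticodon: str
    fold: str
    ncols: int
    ss_cons: str                      # consensus-column structure
    anticodon_cols: tuple             # consensus column indices or None
    background: np.ndarray            # (4,) probabilities
    # flat guide-tree arrays (pre-order; parents before children)
    ntype: np.ndarray                 # int8 (n,)
    child: np.ndarray                 # int32 (n,)
    child2: np.ndarray                # int32 (n,)
    colL: np.ndarray                  # int32 (n,)
    colR: np.ndarray                  # int32 (n,)
    trans: np.ndarray                 # float64 (n, 4)
    insc0: np.ndarray                 # float64 (n, 2)  zero-insert cost
    insa: np.ndarray                  # float64 (n, 2)  first-insert cost
    insb: np.ndarray                  # float64 (n, 2)  per-extension cost
    esl: np.ndarray                   # float64 (n, 5)  single emissions
    ep: np.ndarray                    # float64 (n, 5, 5) pair emissions
    eml: np.ndarray                   # float64 (n, 5)  pair left marginals
    emr: np.ndarray                   # float64 (n, 5)  pair right marginals
    slot_region: np.ndarray           # int32 (n, 2) preceding consensus col
    col_node: np.ndarray = field(default=None)  # int32 (ncols,)
    col_side: np.ndarray = field(default=None)  # int8 (ncols,) 0=L 1=R

    @property
    def nnodes(self) -> int:
        return len(self.ntype)

    def region_slot(self) -> dict:
        """Map region index (preceding consensus column; -1 leading) -> slot."""
        out = {}
        for v in range(self.nnodes):
            for s in range(2):
                r = int(self.slot_region[v, s])
                if r >= -1:
                    out[r] = (v, s)
        return out

    def consensus_length(self) -> int:
        return self.ncols


def _extend_single(bits4: np.ndarray) -> np.ndarray:
    out = np.zeros(5)
    out[:4] = bits4
    return out


def _pair_tables(bits16: np.ndarray, bg: np.ndarray):
    """Extend a 4x4 pair bit table with marginal and N rules."""
    ml = np.log2(np.sum(np.exp2(bits16) * bg[None, :], axis=1))
    mr = np.log2(np.sum(np.exp2(bits16) * bg[:, None], axis=0))
    ep = np.zeros((5, 5))
    ep[:4, :4] = bits16
    ep[:4, 4] = ml
    ep[4, :4] = mr
    ep[4, 4] = 0.0
    eml = np.zeros(5)
    eml[:4] = ml
    emr = np.zeros(5)
    emr[:4] = mr
    return ep, eml, emr


def consensus_columns(aln: SeedAlignment) -> list:
    """Columns with gap fraction < 0.5 become consensus (match) columns."""
    n = len(aln.rows)
    cols = []
    for c in range(aln.width):
        gaps = sum(1 for _, t in aln.rows if t[c] in GAP_CHARS)
        if gaps / n < 0.5:
            cols.append(c)
    return cols


def train_model(aln: SeedAlignment, pseudocount: float = 1.0,
                background: np.ndarray = None, name: str = None,
                ext_prior: float = EXT_PRIOR,
                stop_prior: float = STOP_PRIOR) -> ProfileSCFG:
    """Train a profile SCFG from a seed alignment.

    Ambiguity residues contribute fractionally (uniform over their IUPAC
    set), so anticodon columns masked to NNN train to near-flat emissions.
    ``ext_prior``/``stop_prior`` set the insert-run length prior: the
    permissive default suits gene models that must absorb introns; compact
    motif models (such as splice-site models) should pass ``ext_prior=1``.
    """
    a = float(pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    nrows = len(aln.rows)
    cols = consensus_columns(aln)
    if not cols:
        raise TrainingError("alignment has no consensus columns")
    cidx = {c: k for k, c in enumerate(cols)}
    ncols = len(cols)

    # project pairing onto consensus columns
    proj_pairs = {}
    for c in cols:
        p = aln.pairs.get(c)
        if p is not None and p in cidx:
            proj_pairs[cidx[c]] = cidx[p]
    ss = []
    for c in cols:
        k = cidx[c]
        if k in proj_pairs:
            ss.append("<" if proj_pairs[k] > k else ">")
        else:
            ss.append(".")
    ss_proj = "".join(ss)

    tree = G.build_guide_tree(ss_proj)
    owners = G.region_owners(tree)
    n = len(tree.nodes)

    ntype = np.zeros(n, np.int8)
    child = np.full(n, -1, np.int32)
    child2 = np.full(n, -1, np.int32)
    colL = np.full(n, -1, np.int32)
    colR = np.full(n, -1, np.int32)
    trans = np.zeros((n, 4))
    insc0 = np.zeros((n, 2))
    insa = np.full((n, 2), NEG)
    insb = np.full((n, 2), NEG)
    esl = np.zeros((n, 5))
    ep = np.zeros((n, 5, 5))
    eml = np.zeros((n, 5))
    emr = np.zeros((n, 5))
    slot_region = np.full((n, 2), -2, np.int32)
    col_node = np.full(ncols, -1, np.int32)
    col_side = np.zeros(ncols, np.int8)

    for node in tree.nodes:
        v = node.index
        ntype[v] = node.kind
        if node.children:
            child[v] = node.children[0].index
            if len(node.children) > 1:
                child2[v] = node.children[1].index
        colL[v] = node.colL
        colR[v] = node.colR
        if node.colL >= 0:
            col_node[node.colL] = v
            col_side[node.colL] = 0
        if node.colR >= 0:
            col_node[node.colR] = v
            col_side[node.colR] = 1

    # region (between consecutive consensus columns) -> alignment columns
    region_cols = {r: [] for r in range(-1, ncols)}
    boundaries = [-1] + cols
    for c in range(aln.width):
        if c in cidx:
            continue
        r = -1
        for k, b in enumerate(boundaries):
            if c > b:
                r = k - 1
            else:
                break
        region_cols[r].append(c)

    rows = [t for _, t in aln.rows]
    # per-cell fractional base weights (gap rows weight 0); vectorised
    chars = sorted({ch for t in rows for ch in t})
    charmat = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    charmat = charmat.reshape(nrows, aln.width)
    wmat = np.zeros((nrows, aln.width, 4))
    presmat = np.zeros((nrows, aln.width), bool)
    for ch in chars:
        mask = charmat == ord(ch)
        if ch in GAP_CHARS:
            continue
        wmat[mask] = _residue_weights(ch)
        presmat |= mask
    P = presmat[:, cols]  # (nrows, ncols) presence at consensus columns

    # ---- transition counts -------------------------------------------------
    for node in tree.nodes:
        v = node.index
        if node.kind == G.MATL or node.kind == G.MATR:
            c = node.colL if node.kind == G.MATL else node.colR
            nm = int(P[:, c].sum())
            pm = (nm + a) / (nrows + 2 * a)
            pd = (nrows - nm + a) / (nrows + 2 * a)
            trans[v, 0] = np.log2(pm)
            trans[v, 1] = np.log2(pd)
        elif node.kind == G.PAIR:
            l, r = P[:, node.colL], P[:, node.colR]
            counts = np.array([
                (l & r).sum(), (l & ~r).sum(), (~l & r).sum(), (~l & ~r).sum()
            ], float)  # MP, ML, MR, D
            probs = (counts + a) / (nrows + 4 * a)
            trans[v] = np.log2(probs)

    # ---- insert slots ------------------------------------------------------
    for r, (vi, side) in owners.items():
        s = 0 if side == "L" else 1
        slot_region[vi, s] = r
    # every slot that structurally exists (owner of some region, or generic
    # by node type) gets geometric parameters; unobserved slots train from
    # pseudocounts alone.
    slot_types = {G.ROOT: (0, 1), G.MATL: (0,), G.MATR: (1,),
                  G.PAIR: (0, 1), G.BIF: (0,), G.END: ()}
    region_of = {(vi, s): r for r, (vi, sd) in owners.items()
                 for s in [0 if sd == "L" else 1]}
    for node in tree.nodes:
        v = node.index
        for s in slot_types[node.kind]:
            r = region_of.get((v, s))
            if r is None or not region_cols[r]:
                ks = np.zeros(nrows, int)
            else:
                ks = presmat[:, region_cols[r]].sum(axis=1)
            n1 = int((ks >= 1).sum())
            n0 = nrows - n1
            ext = int(ks.sum()) - n1
            p_open = (n1 + a) / (nrows + 2 * a)
            p_c0 = (n0 + a) / (nrows + 2 * a)
            # length-calibrated extension prior (mean unobserved run ~10 nt
            # by default): a pure Laplace prior would make every inserted
            # residue cost log2(1/3) bits and long introns undetectable
            p_ext = (ext + ext_prior) / (ext + n1 + ext_prior + stop_prior)
            p_stop = (n1 + stop_prior) / (ext + n1 + ext_prior + stop_prior)
            insc0[v, s] = np.log2(p_c0)
            insa[v, s] = np.log2(p_open) + np.log2(p_stop)
            insb[v, s] = np.log2(p_ext)

    # ---- emissions ---------------------------------------------------------
    for node in tree.nodes:
        v = node.index
        if node.kind in (G.MATL, G.MATR):
            c = node.colL if node.kind == G.MATL else node.colR
            cnt = wmat[:, cols[c], :].sum(axis=0)
            probs = (cnt + a) / (cnt.sum() + 4 * a)
            esl[v] = _extend_single(np.log2(probs / bg))
        elif node.kind == G.PAIR:
            acl, acr = cols[node.colL], cols[node.colR]
            sel = presmat[:, acl] & presmat[:, acr]
            cnt = np.einsum("ri,rj->ij", wmat[sel, acl], wmat[sel, acr])
            probs = (cnt + a) / (cnt.sum() + 16 * a)
            bits16 = np.log2(probs / np.outer(bg, bg))
            ep[v], eml[v], emr[v] = _pair_tables(bits16, bg)

    # ---- meta --------------------------------------------------------------
    ac_cols = None
    anticodon = ""
    if aln.anticodon_cols is not None:
        if all(c in cidx for c in aln.anticodon_cols):
            ac_cols = tuple(cidx[c] for c in aln.anticodon_cols)
            letters = []
            for c in aln.anticodon_cols:
                cnt = wmat[:, c, :].sum(axis=0)
                letters.append(
                    "ACGT"[int(np.argmax(cnt))]
                    if cnt.sum() > 0 and cnt.max() > 1.5 * cnt.mean() else "N"
                )
            anticodon = "".join(letters)
        else:
            warnings.warn("anticodon columns fall outside the consensus")

    return ProfileSCFG(
        name=name or aln.name, domain=aln.domain, isotype=aln.isotype,
        anticodon=anticodon, fold=aln.fold, ncols=ncols, ss_cons=ss_proj,
        anticodon_cols=ac_cols, background=bg,
        ntype=ntype, child=child, child2=child2, colL=colL, colR=colR,
        trans=trans, insc0=insc0, insa=insa, insb=insb,
        esl=esl, ep=ep, eml=eml, emr=emr, slot_region=slot_region,
        col_node=col_node, col_side=col_side,
    )


def mask_anticodons(aln: SeedAlignment) -> SeedAlignment:
    """Replace the three marked anticodon columns with N in every row.

    Gaps in marked columns are retained; an alignment without a marker is
    returned unchanged with a warning.
    """
    if aln.anticodon_cols is None:
        warnings.warn("alignment has no anticodon marker; mask is a no-op")
        return aln
    marked = set(aln.anticodon_cols)
    rows = []
    for sid, text in aln.rows:
        chars = list(text)
        for c in marked:
            if chars[c] not in GAP_CHARS:
                chars[c] = "N"
        rows.append((sid, "".join(chars)))
    return SeedAlignment(
        rows=rows, ss_cons=aln.ss_cons, anticodon_cols=aln.anticodon_cols,
        name=aln.name, domain=aln.domain, isotype=aln.isotype, fold=aln.fold,
    )


# ---------------------------------------------------------------------------
# Structure-free linear profile (first-pass scanning)

@dataclass
class LinearProfile:
    """Column-wise single-residue profile: pair columns released to marginals."""

    name: str
    ncols: int
    em: np.ndarray        # (ncols, 5) emission bits
    tm: np.ndarray        # (ncols,) match transition bits
    td: np.ndarray        # (ncols,) delete transition bits
    ins_c0: np.ndarray    # (ncols + 1,) indexed by gap position
    ins_a: np.ndarray
    ins_b: np.ndarray


def marginalize(model: ProfileSCFG) -> LinearProfile:
    """Release every pair into its two marginal single columns."""
    nc = model.ncols
    em = np.zeros((nc, 5))
    tm = np.zeros(nc)
    td = np.zeros(nc)
    for c in range(nc):
        v = int(model.col_node[c])
        side = int(model.col_side[c])
        t = model.ntype[v]
        if t in (G.MATL, G.MATR):
            em[c] = model.esl[v]
            tm[c] = model.trans[v, 0]
            td[c] = model.trans[v, 1]
        else:  # PAIR
            p = np.exp2(model.trans[v])  # MP, ML, MR, D
            if side == 0:
                em[c] = model.eml[v]
                tm[c] = np.log2(p[0] + p[1])
                td[c] = np.log2(p[2] + p[3])
            else:
                em[c] = model.emr[v]
                tm[c] = np.log2(p[0] + p[2])
                td[c] = np.log2(p[1] + p[3])
    ins_c0 = np.zeros(nc + 1)
    ins_a = np.full(nc + 1, NEG)
    ins_b = np.full(nc + 1, NEG)
    rslot = model.region_slot()
    for r, (v, s) in rslot.items():
        g = r + 1  # region -1 -> gap position 0
        ins_c0[g] = model.insc0[v, s]
        ins_a[g] = model.insa[v, s]
        ins_b[g] = model.insb[v, s]
    return LinearProfile(name=model.name, ncols=nc, em=em, tm=tm, td=td,
                         ins_c0=ins_c0, ins_a=ins_a, ins_b=ins_b)


# ---------------------------------------------------------------------------
# Sampling

@dataclass
class SampledSeq:
    residues: str
    col_residues: list        # per consensus column: base or None (deleted)
    col_positions: dict       # consensus column -> position in residues

    def anticodon(self, model: ProfileSCFG) -> str:
        if model.anticodon_cols is None:
            return "NNN"
        bases = [self.col_residues[c] for c in model.anticodon_cols]
        if any(b is None for b in bases):
            return "NNN"
        return "".join(bases)


def _sample_emission(rng, bits: np.ndarray, bg: np.ndarray) -> int:
    p = np.exp2(bits[:4]) * bg
    p = p / p.sum()
    return int(rng.choice(4, p=p))


def _sample_pair(rng, bits: np.ndarray, bg: np.ndarray) -> tuple:
    p = np.exp2(bits[:4, :4]) * np.outer(bg, bg)
    p = (p / p.sum()).ravel()
    k = int(rng.choice(16, p=p))
    return k // 4, k % 4


def _sample_insert_run(rng, model: ProfileSCFG, v: int, s: int) -> list:
    p_open = 1.0 - min(1.0, float(np.exp2(model.insc0[v, s])))
    if model.insa[v, s] <= NEG / 2 or rng.random() >= p_open:
        return []
    p_ext = float(np.exp2(model.insb[v, s]))
    out = [(None, "ACGT"[_sample_bg(rng, model.background)])]
    while rng.random() < p_ext:
        out.append((None, "ACGT"[_sample_bg(rng, model.background)]))
    return out


def _sample_bg(rng, bg: np.ndarray) -> int:
    return int(rng.choice(4, p=bg / bg.sum()))


def sample(model: ProfileSCFG, rng) -> SampledSeq:
    """Draw one sequence from the probabilistic model implied by the scores.

    Returns the residues plus, for each consensus column, the emitted base
    (or None when the column was deleted) and its sequence position.
    """
    bg = model.background

    def gen(v: int) -> list:   # list of (column | None, base)
        t = model.ntype[v]
        if t == G.END:
            return []
        if t == G.ROOT:
            return (_sample_insert_run(rng, model, v, 0) + gen(model.child[v])
                    + _sample_insert_run(rng, model, v, 1))
        if t == G.BIF:
            return (gen(model.child[v]) + _sample_insert_run(rng, model, v, 0)
                    + gen(model.child2[v]))
        if t == G.MATL:
            p = np.exp2(model.trans[v, :2])
            left = []
            if rng.random() < p[0] / p.sum():
                x = _sample_emission(rng, model.esl[v], bg)
                left = [(int(model.colL[v]), "ACGT"[x])]
            return left + _sample_insert_run(rng, model, v, 0) + gen(model.child[v])
        if t == G.MATR:
            p = np.exp2(model.trans[v, :2])
            right = []
            if rng.random() < p[0] / p.sum():
                x = _sample_emission(rng, model.esl[v], bg)
                right = [(int(model.colR[v]), "ACGT"[x])]
            return (gen(model.child[v]) + _sample_insert_run(rng, model, v, 1)
                    + right)
        # PAIR
        p = np.exp2(model.trans[v])
        opt = int(rng.choice(4, p=p / p.sum()))
        left = right = []
        if opt == 0:
            x, y = _sample_pair(rng, model.ep[v], bg)
            left = [(int(model.colL[v]), "ACGT"[x])]
            right = [(int(model.colR[v]), "ACGT"[y])]
        elif opt == 1:
            x = _sample_emission(rng, model.eml[v], bg)
            left = [(int(model.colL[v]), "ACGT"[x])]
        elif opt == 2:
            y = _sample_emission(rng, model.emr[v], bg)
            right = [(int(model.colR[v]), "ACGT"[y])]
        return (left + _sample_insert_run(rng, model, v, 0)
                + gen(model.child[v])
                + _sample_insert_run(rng, model, v, 1) + right)

    tokens = gen(0)
    col_res = [None] * model.ncols
    col_pos = {}
    for pos, (col, base) in enumerate(tokens):
        if col is not None:
            col_res[col] = base
            col_pos[col] = pos
    return SampledSeq(residues="".join(b for _, b in tokens),
                      col_residues=col_res, col_positions=col_pos)


def sample_sequence(model: ProfileSCFG, rng_seed: int,
                    seq_id: str = "sample") -> NucSequence:
    rng = np.random.default_rng(rng_seed)
    return NucSequence(seq_id, sample(model, rng).residues)
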