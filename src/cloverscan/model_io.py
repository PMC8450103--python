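"""Plain-text model serialisation.

A model file carries the metadata header, the consensus structure (from
which the guide tree is rebuilt deterministically), and per-node
transition/insert/emission bit scores to three decimals.  Reading a file
written by :func:`write_model` and writing it again reproduces the file
byte for byte.
"""

from __future__ import annotations

import numpy as np

from . import guide as G
from .model import NEG, ProfileSCFG, _pair_tables
from .records import FormatError

MAGIC = "CLOVERSCAN-MODEL 1"


def _fmt(x: float) -> str:
    return "*" if x <= NEG / 2 else f"{x:.3f}"


def _parse(tok: str) -> float:
    return NEG if tok == "*" else float(tok)


def write_model(model: ProfileSCFG, path=None) -> str:
    lines = [MAGIC]
    lines.append(f"name {model.name}")
    lines.append(f"domain {model.domain}")
    lines.append(f"isotype {model.isotype or '-'}")
    lines.append(f"anticodon {model.anticodon or '-'}")
    lines.append(f"fold {model.fold}")
    lines.append(f"ncols {model.ncols}")
    lines.append(f"ss_cons {model.ss_cons}")
    ac = (" ".join(str(c) for c in model.anticodon_cols)
          if model.anticodon_cols else "none")
    lines.append(f"anticodon_cols {ac}")
    lines.append("background " + " ".join(f"{b:.6f}" for b in model.background))
    lines.append(f"nodes {model.nnodes}")
    for v in range(model.nnodes):
        lines.append(f"node {v} {G.KIND_NAMES[model.ntype[v]]}")
        lines.append("  trans " + " ".join(_fmt(x) for x in model.trans[v]))
        lines.append("  insL " + " ".join(
            _fmt(x) for x in (model.insc0[v, 0], model.insa[v, 0],
                              model.insb[v, 0])))
        lines.append("  insR " + " ".join(
            _fmt(x) for x in (model.insc0[v, 1], model.insa[v, 1],
                              model.insb[v, 1])))
        if model.ntype[v] in (G.MATL, G.MATR):
            lines.append("  esingle " + " ".join(
                _fmt(x) for x in model.esl[v, :4]))
        elif model.ntype[v] == G.PAIR:
            for i in range(4):
                lines.append("  epair " + " ".join(
                    _fmt(x) for x in model.ep[v, i, :4]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_model(path=None, text: str = None) -> ProfileSCFG:
    if text is None:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or lines[0] != MAGIC:
        raise FormatError("not a cloverscan model file")
    meta = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("node "):
        key, _, value = lines[i].partition(" ")
        meta[key] = value
        i += 1
    ncols = int(meta["ncols"])
    ss = meta["ss_cons"]
    ac = (None if meta["anticodon_cols"] == "none"
          else tuple(int(x) for x in meta["anticodon_cols"].split()))
    bg = np.array([float(x) for x in meta["background"].split()])

    # rebuild the guide tree; node order is deterministic
    from .model import train_model  # noqa: F401 (avoid cycle at import time)
    tree = G.build_guide_tree(ss)
    n = len(tree.nodes)
    if int(meta["nodes"]) != n:
        raise FormatError("node count mismatch with consensus structure")

    ntype = np.zeros(n, np.int8)
    child = np.full(n, -1, np.int32)
    child2 = np.full(n, -1, np.int32)
    colL = np.full(n, -1, np.int32)
    colR = np.full(n, -1, np.int32)
    col_node = np.full(ncols, -1, np.int32)
    col_side = np.zeros(ncols, np.int8)
    slot_region = np.full((n, 2), -2, np.int32)
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
            col_node[node.colL], col_side[node.colL] = v, 0
        if node.colR >= 0:
            col_node[node.colR], col_side[node.colR] = v, 1
    for r, (vi, side) in G.region_owners(tree).items():
        slot_region[vi, 0 if side == "L" else 1] = r

    trans = np.zeros((n, 4))
    insc0 = np.zeros((n, 2))
    insa = np.full((n, 2), NEG)
    insb = np.full((n, 2), NEG)
    esl = np.zeros((n, 5))
    ep = np.zeros((n, 5, 5))
    eml = np.zeros((n, 5))
    emr = np.zeros((n, 5))
    v = -1
    pair_rows = []
    for line in lines[i:]:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "node":
            if pair_rows:
                _finish_pair(ep, eml, emr, v, pair_rows, bg)
                pair_rows = []
            v = int(parts[1])
        elif parts[0] == "trans":
            trans[v] = [_parse(x) for x in parts[1:]]
        elif parts[0] == "insL":
            insc0[v, 0], insa[v, 0], insb[v, 0] = (_parse(x) for x in parts[1:])
        elif parts[0] == "insR":
            insc0[v, 1], insa[v, 1], insb[v, 1] = (_parse(x) for x in parts[1:])
        elif parts[0] == "esingle":
            esl[v, :4] = [_parse(x) for x in parts[1:]]
        elif parts[0] == "epair":
            pair_rows.append([_parse(x) for x in parts[1:]])
        else:
            raise FormatError(f"unexpected model line: {line!r}")
    if pair_rows:
        _finish_pair(ep, eml, emr, v, pair_rows, bg)

    return ProfileSCFG(
        name=meta["name"], domain=meta["domain"],
        isotype="" if meta["isotype"] == "-" else meta["isotype"],
        anticodon="" if meta["anticodon"] == "-" else meta["anticodon"],
        fold=meta["fold"], ncols=ncols, ss_cons=ss, anticodon_cols=ac,
        background=bg, ntype=ntype, child=child, child2=child2,
        colL=colL, colR=colR, trans=trans, insc0=insc0, insa=insa, insb=insb,
        esl=esl, ep=ep, eml=eml, emr=emr, slot_region=slot_region,
        col_node=col_node, col_side=col_side,
    )


def _finish_pair(ep, eml, emr, v, pair_rows, bg):
    bits16 = np.array(pair_rows)
    ep[v], eml[v], emr[v] = _pair_tables(bits16, bg)
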