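"""Maximum-bit-score parsing of sequences against profile SCFGs.

The scorer is a CYK-style dynamic program over the model's guide tree:
``M[v, i, j]`` is the best bit score of node *v*'s subtree generating the
subsequence ``s[i:j]``.  Bifurcations maximise over split points; insert
runs carry trained geometric costs (residues themselves score zero bits
against the background); N and other ambiguity codes score zero bits.

Truncation support: three companion tables allow a *prefix* (``T5``),
*suffix* (``T3``) or both (``T53``) of the consensus columns, in emission
order, to be deleted at zero penalty without consuming sequence.  They are
only consulted for parses anchored at a sequence boundary, modelling tRNA
genes running off a contig end.

Tie-breaking in traceback is deterministic: fewest inserted residues
first, then a fixed option order (emitting options before deletions,
non-truncated before truncated continuations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import guide as G
from .model import NEG, ProfileSCFG, seq_to_codes

_EPS = 1e-6


@njit(cache=True)
def _li(C, c0, a, b, out, L):
    # out[i,j] = max over k>=0 of insert_cost(k) + C[i+k, j]
    for j in range(L + 1):
        g = NEG
        for i in range(L, -1, -1):
            best = c0 + C[i, j]
            cand = a + g
            if cand > best:
                best = cand
            out[i, j] = best
            g2 = C[i, j]
            if b + g > g2:
                g2 = b + g
            g = g2


@njit(cache=True)
def _ri(C, c0, a, b, out, L):
    # out[i,j] = max over k>=0 of insert_cost(k) + C[i, j-k]
    for i in range(L + 1):
        for j in range(i):
            out[i, j] = NEG
        h = NEG
        for j in range(i, L + 1):
            best = c0 + C[i, j]
            cand = a + h
            if cand > best:
                best = cand
            out[i, j] = best
            h2 = C[i, j]
            if b + h > h2:
                h2 = b + h
            h = h2


@njit(cache=True)
def _cyk_kernel(ntype, child, child2, trans, insc0, insa, insb,
                esl, ep, eml, emr, seq, want_trunc):
    n = ntype.shape[0]
    L = seq.shape[0]
    M = np.full((n, L + 1, L + 1), NEG)
    nt = n if want_trunc else 1
    T5 = np.full((nt, L + 1, L + 1), NEG)
    T3 = np.full((nt, L + 1, L + 1), NEG)
    T53 = np.full((nt, L + 1, L + 1), NEG)
    W = np.empty((L + 1, L + 1))
    W2 = np.empty((L + 1, L + 1))

    for v in range(n - 1, -1, -1):
        t = ntype[v]
        if t == 5:  # END
            for i in range(L + 1):
                M[v, i, i] = 0.0
                if want_trunc:
                    T5[v, i, i] = 0.0
                    T3[v, i, i] = 0.0
                    T53[v, i, i] = 0.0
        elif t == 1:  # MATL
            u = child[v]
            _li(M[u], insc0[v, 0], insa[v, 0], insb[v, 0], W, L)
            for i in range(L + 1):
                for j in range(i, L + 1):
                    best = trans[v, 1] + W[i, j]
                    if j > i:
                        c = trans[v, 0] + esl[v, seq[i]] + W[i + 1, j]
                        if c > best:
                            best = c
                    M[v, i, j] = best
            if want_trunc:
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b5 = M[v, i, j]
                        if T5[u, i, j] > b5:
                            b5 = T5[u, i, j]
                        T5[v, i, j] = b5
                _li(T3[u], insc0[v, 0], insa[v, 0], insb[v, 0], W, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        best = trans[v, 1] + W[i, j]
                        if j > i:
                            c = trans[v, 0] + esl[v, seq[i]] + W[i + 1, j]
                            if c > best:
                                best = c
                        if i == j and 0.0 > best:
                            best = 0.0
                        T3[v, i, j] = best
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b53 = T3[v, i, j]
                        if T53[u, i, j] > b53:
                            b53 = T53[u, i, j]
                        T53[v, i, j] = b53
        elif t == 2:  # MATR
            u = child[v]
            _ri(M[u], insc0[v, 1], insa[v, 1], insb[v, 1], W, L)
            for i in range(L + 1):
                for j in range(i, L + 1):
                    best = trans[v, 1] + W[i, j]
                    if j > i:
                        c = trans[v, 0] + esl[v, seq[j - 1]] + W[i, j - 1]
                        if c > best:
                            best = c
                    M[v, i, j] = best
            if want_trunc:
                _ri(T5[u], insc0[v, 1], insa[v, 1], insb[v, 1], W, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        best = trans[v, 1] + W[i, j]
                        if j > i:
                            c = trans[v, 0] + esl[v, seq[j - 1]] + W[i, j - 1]
                            if c > best:
                                best = c
                        if i == j and 0.0 > best:
                            best = 0.0
                        T5[v, i, j] = best
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b3 = M[v, i, j]
                        if T3[u, i, j] > b3:
                            b3 = T3[u, i, j]
                        T3[v, i, j] = b3
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b53 = T5[v, i, j]
                        if T53[u, i, j] > b53:
                            b53 = T53[u, i, j]
                        T53[v, i, j] = b53
        elif t == 3:  # PAIR
            u = child[v]
            _ri(M[u], insc0[v, 1], insa[v, 1], insb[v, 1], W2, L)
            _li(W2, insc0[v, 0], insa[v, 0], insb[v, 0], W, L)
            for i in range(L + 1):
                for j in range(i, L + 1):
                    best = trans[v, 3] + W[i, j]
                    if j > i:
                        c = trans[v, 1] + eml[v, seq[i]] + W[i + 1, j]
                        if c > best:
                            best = c
                        c = trans[v, 2] + emr[v, seq[j - 1]] + W[i, j - 1]
                        if c > best:
                            best = c
                    if j >= i + 2:
                        c = (trans[v, 0] + ep[v, seq[i], seq[j - 1]]
                             + W[i + 1, j - 1])
                        if c > best:
                            best = c
                    M[v, i, j] = best
            if want_trunc:
                # orphaned pair mates carry no transition cost: the freed
                # half is zero-penalty and the survivor emits its marginal
                _ri(T5[u], insc0[v, 1], insa[v, 1], insb[v, 1], W2, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        best = M[v, i, j]
                        if W2[i, j] > best:
                            best = W2[i, j]
                        if j > i:
                            c = emr[v, seq[j - 1]] + W2[i, j - 1]
                            if c > best:
                                best = c
                        if i == j and 0.0 > best:
                            best = 0.0
                        T5[v, i, j] = best
                _li(T3[u], insc0[v, 0], insa[v, 0], insb[v, 0], W2, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        best = M[v, i, j]
                        if W2[i, j] > best:
                            best = W2[i, j]
                        if j > i:
                            c = eml[v, seq[i]] + W2[i + 1, j]
                            if c > best:
                                best = c
                        if i == j and 0.0 > best:
                            best = 0.0
                        T3[v, i, j] = best
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b53 = T5[v, i, j]
                        if T3[v, i, j] > b53:
                            b53 = T3[v, i, j]
                        if T53[u, i, j] > b53:
                            b53 = T53[u, i, j]
                        T53[v, i, j] = b53
        elif t == 4:  # BIF
            l = child[v]
            r = child2[v]
            _li(M[r], insc0[v, 0], insa[v, 0], insb[v, 0], W, L)
            for i in range(L + 1):
                for j in range(i, L + 1):
                    best = NEG
                    for k in range(i, j + 1):
                        c = M[l, i, k] + W[k, j]
                        if c > best:
                            best = c
                    M[v, i, j] = best
            if want_trunc:
                _li(T3[r], insc0[v, 0], insa[v, 0], insb[v, 0], W2, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b5 = T5[r, i, j]
                        b3 = T3[l, i, j]
                        b53 = T53[l, i, j]
                        if T53[r, i, j] > b53:
                            b53 = T53[r, i, j]
                        for k in range(i, j + 1):
                            c = T5[l, i, k] + W[k, j]
                            if c > b5:
                                b5 = c
                            c = M[l, i, k] + W2[k, j]
                            if c > b3:
                                b3 = c
                            c = T5[l, i, k] + W2[k, j]
                            if c > b53:
                                b53 = c
                        T5[v, i, j] = b5
                        T3[v, i, j] = b3
                        T53[v, i, j] = b53
        else:  # ROOT
            u = child[v]
            _ri(M[u], insc0[v, 1], insa[v, 1], insb[v, 1], W2, L)
            _li(W2, insc0[v, 0], insa[v, 0], insb[v, 0], W, L)
            for i in range(L + 1):
                for j in range(i, L + 1):
                    M[v, i, j] = W[i, j]
            if want_trunc:
                _ri(T5[u], insc0[v, 1], insa[v, 1], insb[v, 1], W2, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b5 = M[v, i, j]
                        if W2[i, j] > b5:
                            b5 = W2[i, j]
                        T5[v, i, j] = b5
                _li(T3[u], insc0[v, 0], insa[v, 0], insb[v, 0], W2, L)
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b3 = M[v, i, j]
                        if W2[i, j] > b3:
                            b3 = W2[i, j]
                        T3[v, i, j] = b3
                for i in range(L + 1):
                    for j in range(i, L + 1):
                        b53 = T5[v, i, j]
                        if T3[v, i, j] > b53:
                            b53 = T3[v, i, j]
                        if T53[u, i, j] > b53:
                            b53 = T53[u, i, j]
                        T53[v, i, j] = b53
    return M, T5, T3, T53


def cyk_tables(model: ProfileSCFG, codes: np.ndarray, want_trunc: bool = False):
    """Run the DP; returns the (M, T5, T3, T53) score tables."""
    return _cyk_kernel(
        model.ntype, model.child, model.child2, model.trans,
        model.insc0, model.insa, model.insb,
        model.esl, model.ep, model.eml, model.emr,
        codes.astype(np.int8), want_trunc,
    )


# ---------------------------------------------------------------------------
# Parse results and traceback

@dataclass
class ParseResult:
    """One maximum-score parse of a (sub)sequence against a model."""

    score: float
    primary_bits: float
    secondary_bits: float
    col_assign: list                  # per consensus column: ('M', pos) | ('D',) | ('T',)
    inserts: list                     # (position, region) region = preceding col, -1 leading
    begin: int                        # span within the scored sequence
    end: int
    trunc5: bool = False
    trunc3: bool = False
    mode: str = "global"

    def emitted_positions(self) -> list:
        return sorted([p for a in self.col_assign if a[0] == "M" for p in [a[1]]]
                      + [p for p, _ in self.inserts])


_M, _T5, _T3, _T53 = 0, 1, 2, 3


class _Tracer:
    def __init__(self, model, codes, tables):
        self.m = model
        self.s = codes
        self.M, self.T5, self.T3, self.T53 = tables
        self.col_assign = [("D",)] * model.ncols
        self.inserts = []
        self.secondary = 0.0
        self.trunc5 = False
        self.trunc3 = False

    def _tab(self, var):
        return (self.M, self.T5, self.T3, self.T53)[var]

    def _ins_cost(self, v, s, k):
        if k == 0:
            return float(self.m.insc0[v, s])
        return float(self.m.insa[v, s]) + (k - 1) * float(self.m.insb[v, s])

    def _record_run(self, v, s, i, k):
        """Record k inserted residues starting at position i for slot (v,s)."""
        region = int(self.m.slot_region[v, s])
        if region == -2:
            region = -1
        for p in range(i, i + k):
            self.inserts.append((p, region))

    def _free_subtree(self, v, side5: bool):
        for c in _subtree_cols(self.m, v):
            self.col_assign[c] = ("T",)
        if side5:
            self.trunc5 = True
        else:
            self.trunc3 = True

    def trace(self, v, i, j, var):
        m, s = self.m, self.s
        t = int(m.ntype[v])
        target = self._tab(var)[v, i, j]
        if target <= NEG / 2:
            raise RuntimeError("traceback reached an unreachable cell")
        if t == G.END:
            return
        if t == G.BIF:
            self._trace_bif(v, i, j, var, target)
            return
        if t == G.MATL:
            self._trace_matl(v, i, j, var, target)
            return
        if t == G.MATR:
            self._trace_matr(v, i, j, var, target)
            return
        if t == G.PAIR:
            self._trace_pair(v, i, j, var, target)
            return
        self._trace_root(v, i, j, var, target)

    # -- helpers per node type ---------------------------------------------

    def _trace_matl(self, v, i, j, var, target):
        m, s = self.m, self.s
        u = int(m.child[v])
        col = int(m.colL[v])
        if var in (_T5, _T53):
            # prefer the non-truncated continuation
            base = self.M if var == _T5 else self.T3
            if abs(base[v, i, j] - target) < _EPS:
                self.trace(v, i, j, _M if var == _T5 else _T3)
                return
            nxt = self.T5 if var == _T5 else self.T53
            if abs(nxt[u, i, j] - target) < _EPS:
                self.col_assign[col] = ("T",)
                self.trunc5 = True
                self.trace(u, i, j, var)
                return
            raise RuntimeError("MATL truncated traceback failed")
        child_tab = self.M if var == _M else self.T3
        cvar = _M if var == _M else _T3
        if var == _T3 and i == j and abs(target) < _EPS:
            maybe = self._try_matl_options(v, u, i, j, child_tab, cvar, target,
                                           commit=False)
            if not maybe:
                self._free_subtree(v, side5=False)
                return
        if not self._try_matl_options(v, u, i, j, child_tab, cvar, target,
                                      commit=True):
            raise RuntimeError("MATL traceback failed")

    def _try_matl_options(self, v, u, i, j, child_tab, cvar, target, commit):
        m, s = self.m, self.s
        col = int(m.colL[v])
        for k in range(0, j - i + 1):
            # match
            if j > i and i + 1 + k <= j:
                val = (m.trans[v, 0] + m.esl[v, s[i]] + self._ins_cost(v, 0, k)
                       + child_tab[u, i + 1, j] if k == 0 else
                       m.trans[v, 0] + m.esl[v, s[i]] + self._ins_cost(v, 0, k)
                       + child_tab[u, i + 1 + k, j])
                if abs(val - target) < _EPS:
                    if not commit:
                        return True
                    self.col_assign[col] = ("M", i)
                    self._record_run(v, 0, i + 1, k)
                    self.trace(u, i + 1 + k, j, cvar)
                    return True
            # delete
            if i + k <= j:
                val = (m.trans[v, 1] + self._ins_cost(v, 0, k)
                       + child_tab[u, i + k, j])
                if abs(val - target) < _EPS:
                    if not commit:
                        return True
                    self.col_assign[col] = ("D",)
                    self._record_run(v, 0, i, k)
                    self.trace(u, i + k, j, cvar)
                    return True
        return False

    def _trace_matr(self, v, i, j, var, target):
        m, s = self.m, self.s
        u = int(m.child[v])
        col = int(m.colR[v])
        if var in (_T3, _T53):
            base = self.M if var == _T3 else self.T5
            if abs(base[v, i, j] - target) < _EPS:
                self.trace(v, i, j, _M if var == _T3 else _T5)
                return
            nxt = self.T3 if var == _T3 else self.T53
            if abs(nxt[u, i, j] - target) < _EPS:
                self.col_assign[col] = ("T",)
                self.trunc3 = True
                self.trace(u, i, j, var)
                return
            raise RuntimeError("MATR truncated traceback failed")
        child_tab = self.M if var == _M else self.T5
        cvar = _M if var == _M else _T5
        if var == _T5 and i == j and abs(target) < _EPS:
            if not self._try_matr_options(v, u, i, j, child_tab, cvar, target,
                                          commit=False):
                self._free_subtree(v, side5=True)
                return
        if not self._try_matr_options(v, u, i, j, child_tab, cvar, target,
                                      commit=True):
            raise RuntimeError("MATR traceback failed")

    def _try_matr_options(self, v, u, i, j, child_tab, cvar, target, commit):
        m, s = self.m, self.s
        col = int(m.colR[v])
        for k in range(0, j - i + 1):
            if j > i and j - 1 - k >= i:
                val = (m.trans[v, 0] + m.esl[v, s[j - 1]]
                       + self._ins_cost(v, 1, k) + child_tab[u, i, j - 1 - k])
                if abs(val - target) < _EPS:
                    if not commit:
                        return True
                    self.col_assign[col] = ("M", j - 1)
                    self._record_run(v, 1, j - 1 - k, k)
                    self.trace(u, i, j - 1 - k, cvar)
                    return True
            if j - k >= i:
                val = (m.trans[v, 1] + self._ins_cost(v, 1, k)
                       + child_tab[u, i, j - k])
                if abs(val - target) < _EPS:
                    if not commit:
                        return True
                    self.col_assign[col] = ("D",)
                    self._record_run(v, 1, j - k, k)
                    self.trace(u, i, j - k, cvar)
                    return True
        return False

    def _trace_pair(self, v, i, j, var, target):
        m, s = self.m, self.s
        u = int(m.child[v])
        cl, cr = int(m.colL[v]), int(m.colR[v])
        if var == _M:
            if self._try_pair_full(v, u, i, j, target):
                return
            raise RuntimeError("PAIR traceback failed")
        if var == _T5:
            if abs(self.M[v, i, j] - target) < _EPS:
                self.trace(v, i, j, _M)
                return
            # left column truncated; right normal over T5 child
            for k in range(0, j - i + 1):
                if j > i and j - 1 - k >= i:
                    val = (m.emr[v, s[j - 1]]
                           + self._ins_cost(v, 1, k) + self.T5[u, i, j - 1 - k])
                    if abs(val - target) < _EPS:
                        self.col_assign[cl] = ("T",)
                        self.trunc5 = True
                        self.col_assign[cr] = ("M", j - 1)
                        self._record_run(v, 1, j - 1 - k, k)
                        self.trace(u, i, j - 1 - k, _T5)
                        return
                if j - k >= i:
                    val = (self._ins_cost(v, 1, k) + self.T5[u, i, j - k])
                    if abs(val - target) < _EPS:
                        self.col_assign[cl] = ("T",)
                        self.trunc5 = True
                        self.col_assign[cr] = ("D",)
                        self._record_run(v, 1, j - k, k)
                        self.trace(u, i, j - k, _T5)
                        return
            if i == j and abs(target) < _EPS:
                self._free_subtree(v, side5=True)
                return
            raise RuntimeError("PAIR T5 traceback failed")
        if var == _T3:
            if abs(self.M[v, i, j] - target) < _EPS:
                self.trace(v, i, j, _M)
                return
            for k in range(0, j - i + 1):
                if j > i and i + 1 + k <= j:
                    val = (m.eml[v, s[i]]
                           + self._ins_cost(v, 0, k) + self.T3[u, i + 1 + k, j])
                    if abs(val - target) < _EPS:
                        self.col_assign[cr] = ("T",)
                        self.trunc3 = True
                        self.col_assign[cl] = ("M", i)
                        self._record_run(v, 0, i + 1, k)
                        self.trace(u, i + 1 + k, j, _T3)
                        return
                if i + k <= j:
                    val = (self._ins_cost(v, 0, k) + self.T3[u, i + k, j])
                    if abs(val - target) < _EPS:
                        self.col_assign[cr] = ("T",)
                        self.trunc3 = True
                        self.col_assign[cl] = ("D",)
                        self._record_run(v, 0, i + k, k)
                        self.trace(u, i + k, j, _T3)
                        return
            if i == j and abs(target) < _EPS:
                self._free_subtree(v, side5=False)
                return
            raise RuntimeError("PAIR T3 traceback failed")
        # T53
        if abs(self.T5[v, i, j] - target) < _EPS:
            self.trace(v, i, j, _T5)
            return
        if abs(self.T3[v, i, j] - target) < _EPS:
            self.trace(v, i, j, _T3)
            return
        if abs(self.T53[u, i, j] - target) < _EPS:
            self.col_assign[cl] = ("T",)
            self.col_assign[cr] = ("T",)
            self.trunc5 = True
            self.trunc3 = True
            self.trace(u, i, j, _T53)
            return
        raise RuntimeError("PAIR T53 traceback failed")

    def _try_pair_full(self, v, u, i, j, target) -> bool:
        m, s = self.m, self.s
        cl, cr = int(m.colL[v]), int(m.colR[v])
        for ktot in range(0, j - i + 1):
            for kl in range(0, ktot + 1):
                kr = ktot - kl
                icost = self._ins_cost(v, 0, kl) + self._ins_cost(v, 1, kr)
                # MP
                if j >= i + 2 and i + 1 + kl <= j - 1 - kr:
                    val = (m.trans[v, 0] + m.ep[v, s[i], s[j - 1]] + icost
                           + self.M[u, i + 1 + kl, j - 1 - kr])
                    if abs(val - target) < _EPS:
                        self.col_assign[cl] = ("M", i)
                        self.col_assign[cr] = ("M", j - 1)
                        self.secondary += float(
                            m.ep[v, s[i], s[j - 1]] - m.eml[v, s[i]]
                            - m.emr[v, s[j - 1]])
                        self._record_run(v, 0, i + 1, kl)
                        self._record_run(v, 1, j - 1 - kr, kr)
                        self.trace(u, i + 1 + kl, j - 1 - kr, _M)
                        return True
                # ML
                if j > i and i + 1 + kl <= j - kr:
                    val = (m.trans[v, 1] + m.eml[v, s[i]] + icost
                           + self.M[u, i + 1 + kl, j - kr])
                    if abs(val - target) < _EPS:
                        self.col_assign[cl] = ("M", i)
                        self.col_assign[cr] = ("D",)
                        self._record_run(v, 0, i + 1, kl)
                        self._record_run(v, 1, j - kr, kr)
                        self.trace(u, i + 1 + kl, j - kr, _M)
                        return True
                # MR
                if j > i and i + kl <= j - 1 - kr:
                    val = (m.trans[v, 2] + m.emr[v, s[j - 1]] + icost
                           + self.M[u, i + kl, j - 1 - kr])
                    if abs(val - target) < _EPS:
                        self.col_assign[cl] = ("D",)
                        self.col_assign[cr] = ("M", j - 1)
                        self._record_run(v, 0, i, kl)
                        self._record_run(v, 1, j - 1 - kr, kr)
                        self.trace(u, i + kl, j - 1 - kr, _M)
                        return True
                # D
                if i + kl <= j - kr:
                    val = (m.trans[v, 3] + icost + self.M[u, i + kl, j - kr])
                    if abs(val - target) < _EPS:
                        self.col_assign[cl] = ("D",)
                        self.col_assign[cr] = ("D",)
                        self._record_run(v, 0, i, kl)
                        self._record_run(v, 1, j - kr, kr)
                        self.trace(u, i + kl, j - kr, _M)
                        return True
        return False

    def _trace_bif(self, v, i, j, var, target):
        m = self.m
        l, r = int(m.child[v]), int(m.child2[v])
        if var == _M:
            lv, rv = _M, _M
        elif var == _T5:
            if abs(self.T5[r, i, j] - target) < _EPS:
                self._free_left_subtree(l)
                self.trace(r, i, j, _T5)
                return
            lv, rv = _T5, _M
        elif var == _T3:
            if abs(self.T3[l, i, j] - target) < _EPS:
                self._free_right_subtree(r)
                self.trace(l, i, j, _T3)
                return
            lv, rv = _M, _T3
        else:
            if abs(self.T53[l, i, j] - target) < _EPS:
                self._free_right_subtree(r)
                self.trace(l, i, j, _T53)
                return
            if abs(self.T53[r, i, j] - target) < _EPS:
                self._free_left_subtree(l)
                self.trace(r, i, j, _T53)
                return
            lv, rv = _T5, _T3
        ltab = self._tab(lv)
        rtab = self._tab(rv)
        for k in range(i, j + 1):
            for kin in range(0, j - k + 1):
                val = (ltab[l, i, k] + self._ins_cost(v, 0, kin)
                       + rtab[r, k + kin, j])
                if abs(val - target) < _EPS:
                    self.trace(l, i, k, lv)
                    self._record_run(v, 0, k, kin)
                    self.trace(r, k + kin, j, rv)
                    return
        raise RuntimeError("BIF traceback failed")

    def _free_left_subtree(self, l):
        for c in _subtree_cols(self.m, l):
            self.col_assign[c] = ("T",)
        self.trunc5 = True

    def _free_right_subtree(self, r):
        for c in _subtree_cols(self.m, r):
            self.col_assign[c] = ("T",)
        self.trunc3 = True

    def _trace_root(self, v, i, j, var, target):
        m = self.m
        u = int(m.child[v])
        if var != _M:
            if abs(self.M[v, i, j] - target) < _EPS:
                self.trace(v, i, j, _M)
                return
            if var == _T53:
                if abs(self.T5[v, i, j] - target) < _EPS:
                    self.trace(v, i, j, _T5)
                    return
                if abs(self.T3[v, i, j] - target) < _EPS:
                    self.trace(v, i, j, _T3)
                    return
                if abs(self.T53[u, i, j] - target) < _EPS:
                    self.trunc5 = True
                    self.trunc3 = True
                    self.trace(u, i, j, _T53)
                    return
                raise RuntimeError("ROOT T53 traceback failed")
        if var == _T5:
            # right root inserts over truncated child
            for k in range(0, j - i + 1):
                val = self._ins_cost(v, 1, k) + self.T5[u, i, j - k]
                if abs(val - target) < _EPS:
                    self.trunc5 = True
                    self._record_run(v, 1, j - k, k)
                    self.trace(u, i, j - k, _T5)
                    return
            raise RuntimeError("ROOT T5 traceback failed")
        if var == _T3:
            for k in range(0, j - i + 1):
                val = self._ins_cost(v, 0, k) + self.T3[u, i + k, j]
                if abs(val - target) < _EPS:
                    self.trunc3 = True
                    self._record_run(v, 0, i, k)
                    self.trace(u, i + k, j, _T3)
                    return
            raise RuntimeError("ROOT T3 traceback failed")
        # plain: left and right insert runs around the child
        for ktot in range(0, j - i + 1):
            for kl in range(0, ktot + 1):
                kr = ktot - kl
                val = (self._ins_cost(v, 0, kl) + self._ins_cost(v, 1, kr)
                       + self.M[u, i + kl, j - kr])
                if abs(val - target) < _EPS:
                    self._record_run(v, 0, i, kl)
                    self._record_run(v, 1, j - kr, kr)
                    self.trace(u, i + kl, j - kr, _M)
                    return
        raise RuntimeError("ROOT traceback failed")


def _subtree_cols(model: ProfileSCFG, v: int) -> list:
    out = []
    stack = [v]
    while stack:
        w = stack.pop()
        if model.colL[w] >= 0:
            out.append(int(model.colL[w]))
        if model.colR[w] >= 0:
            out.append(int(model.colR[w]))
        if model.child[w] >= 0:
            stack.append(int(model.child[w]))
        if model.child2[w] >= 0:
            stack.append(int(model.child2[w]))
    return out


# ---------------------------------------------------------------------------
# Public scoring interface

def score_sequence(model: ProfileSCFG, seq, mode: str = "global",
                   allow_trunc: bool = False,
                   tables=None, codes=None) -> ParseResult:
    """Score a sequence against a model and return the best parse.

    ``global`` parses the whole sequence; ``local`` allows unpenalised
    flanking residues outside the chosen span.  With ``allow_trunc``,
    consensus columns may be deleted at zero penalty, but only in parses
    anchored at a sequence boundary (5' prefix at position 0, 3' suffix at
    the final position).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    if codes is None:
        residues = seq.residues if hasattr(seq, "residues") else str(seq)
        codes = seq_to_codes(residues)
    L = len(codes)
    if tables is None:
        tables = cyk_tables(model, codes, want_trunc=allow_trunc)
    M, T5, T3, T53 = tables

    candidates = []  # (score, preference_rank, i, j, var)
    if mode == "global":
        candidates.append((M[0, 0, L], 0, 0, L, _M))
        if allow_trunc:
            candidates.append((T5[0, 0, L], 1, 0, L, _T5))
            candidates.append((T3[0, 0, L], 2, 0, L, _T3))
            candidates.append((T53[0, 0, L], 3, 0, L, _T53))
        best = max(candidates, key=lambda c: (c[0], -c[1]))
    else:
        root = M[0]
        i0, j0 = divmod(int(np.argmax(root)), L + 1)
        best = (float(root[i0, j0]), 0, i0, j0, _M)
        if allow_trunc:
            j5 = int(np.argmax(T5[0, 0, :]))
            if T5[0, 0, j5] > best[0] + _EPS:
                best = (float(T5[0, 0, j5]), 1, 0, j5, _T5)
            i3 = int(np.argmax(T3[0, :, L]))
            if T3[0, i3, L] > best[0] + _EPS:
                best = (float(T3[0, i3, L]), 2, i3, L, _T3)
            if T53[0, 0, L] > best[0] + _EPS:
                best = (float(T53[0, 0, L]), 3, 0, L, _T53)

    score, _, i, j, var = best
    tracer = _Tracer(model, codes, (M, T5, T3, T53))
    tracer.trace(0, i, j, var)
    secondary = tracer.secondary
    primary = float(score) - secondary
    return ParseResult(
        score=float(score), primary_bits=primary, secondary_bits=secondary,
        col_assign=tracer.col_assign, inserts=sorted(tracer.inserts),
        begin=i, end=j, trunc5=tracer.trunc5, trunc3=tracer.trunc3, mode=mode,
    )


def decompose_score(parse: ParseResult, model: ProfileSCFG = None) -> tuple:
    """(primary, secondary): the parse re-scored with pairs marginalised."""
    return parse.primary_bits, parse.secondary_bits


def extract_anticodon(parse: ParseResult, model: ProfileSCFG,
                      residues: str) -> str:
    """Residues emitted at the three anticodon columns; NNN if any deleted."""
    if model.anticodon_cols is None:
        return "NNN"
    bases = []
    for c in model.anticodon_cols:
        a = parse.col_assign[c]
        if a[0] != "M":
            return "NNN"
        bases.append(residues[a[1]])
    return "".join(bases)
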