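"""Independent reference scorer: direct recursion over the parse grammar.

This transliterates the generative grammar definition node by node with
explicit loops over insert-run lengths and bifurcation splits, instead of
the production kernel's transformed tables, and serves as the ground truth
for maximum-parse-score equivalence on tiny models and sequences.
"""

import numpy as np

from cloverscan import guide as G
from cloverscan.model import NEG

M, T5, T3, T53 = 0, 1, 2, 3


def _ins(m, v, s, k):
    if k == 0:
        return float(m.insc0[v, s])
    return float(m.insa[v, s]) + (k - 1) * float(m.insb[v, s])


def oracle_table(model, codes):
    """Memoised recursive max-score over all legal parses."""
    memo = {}
    s = codes

    def rec(v, i, j, var):
        key = (v, i, j, var)
        if key in memo:
            return memo[key]
        t = int(model.ntype[v])
        best = NEG
        if t == G.END:
            best = 0.0 if i == j else NEG
        elif t == G.MATL:
            u = int(model.child[v])
            if var in (M, T3):
                cv = var
                for k in range(j - i + 1):
                    if j > i and i + 1 + k <= j:
                        best = max(best, model.trans[v, 0]
                                   + model.esl[v, s[i]] + _ins(model, v, 0, k)
                                   + rec(u, i + 1 + k, j, cv))
                    if i + k <= j:
                        best = max(best, model.trans[v, 1]
                                   + _ins(model, v, 0, k) + rec(u, i + k, j, cv))
                if var == T3 and i == j:
                    best = max(best, 0.0)
            elif var == T5:
                best = max(rec(v, i, j, M), rec(u, i, j, T5))
            else:
                best = max(rec(v, i, j, T3), rec(u, i, j, T53))
        elif t == G.MATR:
            u = int(model.child[v])
            if var in (M, T5):
                cv = var
                for k in range(j - i + 1):
                    if j > i and j - 1 - k >= i:
                        best = max(best, model.trans[v, 0]
                                   + model.esl[v, s[j - 1]]
                                   + _ins(model, v, 1, k)
                                   + rec(u, i, j - 1 - k, cv))
                    if j - k >= i:
                        best = max(best, model.trans[v, 1]
                                   + _ins(model, v, 1, k) + rec(u, i, j - k, cv))
                if var == T5 and i == j:
                    best = max(best, 0.0)
            elif var == T3:
                best = max(rec(v, i, j, M), rec(u, i, j, T3))
            else:
                best = max(rec(v, i, j, T5), rec(u, i, j, T53))
        elif t == G.PAIR:
            u = int(model.child[v])
            if var == M:
                for kl in range(j - i + 1):
                    for kr in range(j - i + 1 - kl):
                        ic = _ins(model, v, 0, kl) + _ins(model, v, 1, kr)
                        if j >= i + 2 and i + 1 + kl <= j - 1 - kr:
                            best = max(best, model.trans[v, 0]
                                       + model.ep[v, s[i], s[j - 1]] + ic
                                       + rec(u, i + 1 + kl, j - 1 - kr, M))
                        if j > i and i + 1 + kl <= j - kr:
                            best = max(best, model.trans[v, 1]
                                       + model.eml[v, s[i]] + ic
                                       + rec(u, i + 1 + kl, j - kr, M))
                        if j > i and i + kl <= j - 1 - kr:
                            best = max(best, model.trans[v, 2]
                                       + model.emr[v, s[j - 1]] + ic
                                       + rec(u, i + kl, j - 1 - kr, M))
                        if i + kl <= j - kr:
                            best = max(best, model.trans[v, 3] + ic
                                       + rec(u, i + kl, j - kr, M))
            elif var == T5:
                # an orphaned right mate emits its marginal, transition-free
                best = rec(v, i, j, M)
                for k in range(j - i + 1):
                    if j > i and j - 1 - k >= i:
                        best = max(best, model.emr[v, s[j - 1]]
                                   + _ins(model, v, 1, k)
                                   + rec(u, i, j - 1 - k, T5))
                    if j - k >= i:
                        best = max(best, _ins(model, v, 1, k)
                                   + rec(u, i, j - k, T5))
                if i == j:
                    best = max(best, 0.0)
            elif var == T3:
                best = rec(v, i, j, M)
                for k in range(j - i + 1):
                    if j > i and i + 1 + k <= j:
                        best = max(best, model.eml[v, s[i]]
                                   + _ins(model, v, 0, k)
                                   + rec(u, i + 1 + k, j, T3))
                    if i + k <= j:
                        best = max(best, _ins(model, v, 0, k)
                                   + rec(u, i + k, j, T3))
                if i == j:
                    best = max(best, 0.0)
            else:
                best = max(rec(v, i, j, T5), rec(v, i, j, T3),
                           rec(u, i, j, T53))
        elif t == G.BIF:
            l, r = int(model.child[v]), int(model.child2[v])
            if var == M:
                lv, rv = M, M
            elif var == T5:
                best = rec(r, i, j, T5)
                lv, rv = T5, M
            elif var == T3:
                best = rec(l, i, j, T3)
                lv, rv = M, T3
            else:
                best = max(rec(l, i, j, T53), rec(r, i, j, T53))
                lv, rv = T5, T3
            for k in range(i, j + 1):
                for kin in range(j - k + 1):
                    best = max(best, rec(l, i, k, lv)
                               + _ins(model, v, 0, kin)
                               + rec(r, k + kin, j, rv))
        else:  # ROOT
            u = int(model.child[v])
            if var == M:
                for kl in range(j - i + 1):
                    for kr in range(j - i + 1 - kl):
                        best = max(best, _ins(model, v, 0, kl)
                                   + _ins(model, v, 1, kr)
                                   + rec(u, i + kl, j - kr, M))
            elif var == T5:
                best = rec(v, i, j, M)
                for k in range(j - i + 1):
                    best = max(best, _ins(model, v, 1, k)
                               + rec(u, i, j - k, T5))
            elif var == T3:
                best = rec(v, i, j, M)
                for k in range(j - i + 1):
                    best = max(best, _ins(model, v, 0, k)
                               + rec(u, i + k, j, T3))
            else:
                best = max(rec(v, i, j, T5), rec(v, i, j, T3),
                           rec(u, i, j, T53))
        memo[key] = best
        return best

    return rec


def oracle_global(model, codes, allow_trunc=False):
    rec = oracle_table(model, codes)
    L = len(codes)
    best = rec(0, 0, L, M)
    if allow_trunc:
        best = max(best, rec(0, 0, L, T5), rec(0, 0, L, T3),
                   rec(0, 0, L, T53))
    return best


def oracle_local(model, codes, allow_trunc=False):
    rec = oracle_table(model, codes)
    L = len(codes)
    best = NEG
    for i in range(L + 1):
        for j in range(i, L + 1):
            best = max(best, rec(0, i, j, M))
    if allow_trunc:
        for j in range(L + 1):
            best = max(best, rec(0, 0, j, T5))
        for i in range(L + 1):
            best = max(best, rec(0, i, L, T3))
        best = max(best, rec(0, 0, L, T53))
    return best
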