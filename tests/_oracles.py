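"""Independent brute-force oracles used to cross-check the package.

Everything here recomputes measures naively from edge lists or by
exhaustive enumeration, deliberately sharing no code with the package
internals it checks.
"""

from itertools import combinations, product

import numpy as np


def naive_degrees(edges, women, men):
    """{'in': {id: k}, 'out': {id: k}} by direct edge counting."""
    indeg = {n: 0 for n in (*women, *men)}
    outdeg = {n: 0 for n in (*women, *men)}
    for s, r in edges:
        outdeg[s] += 1
        indeg[r] += 1
    return {"in": indeg, "out": outdeg}


def naive_density(edges, n_women, n_men):
    return len(set(edges)) / (2 * n_women * n_men)


def naive_reciprocity(edges):
    e = set(edges)
    mutual = sum(1 for s, r in e if (r, s) in e)
    return mutual / len(e)


def naive_centralization(edges, mode_ids, opposite_ids):
    indeg = {n: 0 for n in mode_ids}
    for _, r in set(edges):
        if r in indeg:
            indeg[r] += 1
    vals = list(indeg.values())
    num = sum(max(vals) - v for v in vals)
    return num / ((len(mode_ids) - 1) * len(opposite_ids))


def naive_tie_gap(edges, women, men, direction, weighted=False):
    """Mean sender-minus-receiver standardized indegree, edge by edge."""
    e = set(edges)
    deg = naive_degrees(e, women, men)["in"]
    wset, mset = set(women), set(men)
    std = {
        n: deg[n] / (len(men) if n in wset else len(women)) for n in (*women, *men)
    }
    sel = [
        (s, r)
        for s, r in e
        if (s in mset) == (direction == "men_to_women")
    ]
    if weighted:
        outdeg = naive_degrees(e, women, men)["out"]
        w = [1 / outdeg[s] for s, _ in sel]
        return sum(wi * (std[s] - std[r]) for wi, (s, r) in zip(w, sel)) / sum(w)
    return np.mean([std[s] - std[r] for s, r in sel])


def naive_reciprocal_gap(edges, women, men):
    e = set(edges)
    deg = naive_degrees(e, women, men)["in"]
    wset = set(women)
    std = {n: deg[n] / (len(men) if n in wset else len(women)) for n in (*women, *men)}
    pairs = {(s, r) for s, r in e if s in wset and (r, s) in e}  # (woman, man)
    return np.mean([std[m] - std[w] for w, m in pairs])


def _row_options(row):
    n, k = row.size, int(row.sum())
    out = []
    for pos in combinations(range(n), k):
        r = np.zeros(n, dtype=np.int8)
        r[list(pos)] = 1
        out.append(r)
    return out


def enumerate_row_permutations(M_F, M_M, stat):
    """Evaluate ``stat(PF, PM)`` on every joint within-row rearrangement.

    All outcomes are equally likely under the row-permutation null, so
    the returned list *is* the exact null distribution.  Only feasible
    for matrices whose rows have few cells.
    """
    opts_f = [_row_options(r) for r in np.asarray(M_F, dtype=np.int8)]
    opts_m = [_row_options(r) for r in np.asarray(M_M, dtype=np.int8)]
    vals = []
    for rows_f in product(*opts_f):
        PF = np.array(rows_f, dtype=np.int8).reshape(M_F.shape)
        for rows_m in product(*opts_m):
            PM = np.array(rows_m, dtype=np.int8).reshape(M_M.shape)
            vals.append(stat(PF, PM))
    return vals
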