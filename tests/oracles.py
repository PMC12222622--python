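"""Brute-force reference implementations, independent of the package.

Everything here is written with plain Python loops and direct count
ratios: entropy by enumerating individuals one at a time, and the
partition terms by evaluating the staggered delta-form cell by cell.  No
factored shortcuts, no numpy vectorisation — deliberately a second route
to the same numbers.
"""

import math


def _totals(counts, habs):
    S = len(counts)
    C = len(counts[0])
    J = max(habs) + 1
    grand = float(sum(sum(row) for row in counts))
    sp = [float(sum(row)) for row in counts]
    nij = [
        [float(sum(counts[i][k] for k in range(C) if habs[k] == j)) for j in range(J)]
        for i in range(S)
    ]
    comm = [float(sum(counts[i][k] for i in range(S))) for k in range(C)]
    return {"n": counts, "grand": grand, "sp": sp, "nij": nij, "comm": comm}


def _a(st, i):
    return st["sp"][i] / st["grand"]


def _b(st, i, k, habs):
    return st["nij"][i][habs[k]] / st["sp"][i] if st["sp"][i] > 0 else None


def _c(st, i, k, habs):
    d = st["nij"][i][habs[k]]
    return st["n"][i][k] / d if d > 0 else None


def _z(st, i, k, habs, component):
    if component == "gamma":
        p = _a(st, i)
        return -math.log(p) if p > 0 else None
    if component == "alpha":
        ct = st["comm"][k]
        if ct <= 0:
            return None
        w = st["n"][i][k] / ct
        return -math.log(w) if w > 0 else None
    zg = _z(st, i, k, habs, "gamma")
    za = _z(st, i, k, habs, "alpha")
    if zg is None or za is None:
        return None
    return zg - za


def brute_entropy(counts, habs, component):
    """Entropy by enumerating individuals: each contributes z / n_total."""
    st = _totals(counts, habs)
    total = 0.0
    for i in range(len(counts)):
        for k in range(len(counts[0])):
            for _ in range(int(counts[i][k])):
                total += _z(st, i, k, habs, component) / st["grand"]
    return total


def brute_partition(prev, fut, habs, component):
    """Five partition terms plus the total, evaluated cell by cell.

    Pooled future rarity scores; the default cell-level immigrant
    classifier.  Returns a dict keyed by term name and ``"total"``.
    """
    S = len(prev)
    C = len(prev[0])
    imm = [[fut[i][k] if prev[i][k] == 0 else 0 for k in range(C)] for i in range(S)]
    res = [[fut[i][k] - imm[i][k] for k in range(C)] for i in range(S)]
    n_fut = float(sum(sum(row) for row in fut))
    n_imm = float(sum(sum(row) for row in imm))
    n_res = float(sum(sum(row) for row in res))
    phi = n_imm / n_fut

    P = _totals(prev, habs)
    F = _totals(fut, habs)

    h_now = 0.0
    for i in range(S):
        for k in range(C):
            if prev[i][k] > 0:
                h_now += (prev[i][k] / P["grand"]) * _z(P, i, k, habs, component)
    h_fut = 0.0
    for i in range(S):
        for k in range(C):
            if fut[i][k] > 0:
                h_fut += (fut[i][k] / F["grand"]) * _z(F, i, k, habs, component)
    total = h_fut - h_now

    t1 = t2 = t3 = t4 = 0.0
    if n_res > 0:
        R = _totals(res, habs)
        for i in range(S):
            for k in range(C):
                b0 = _b(P, i, k, habs)
                c0 = _c(P, i, k, habs)
                z0 = _z(P, i, k, habs, component)
                # species term: delta a, everything else at present
                if b0 not in (None, 0.0) and c0 not in (None, 0.0):
                    t1 += (_a(R, i) - _a(P, i)) * b0 * c0 * z0
                a2 = _a(R, i)
                if a2 == 0.0:
                    continue
                b2 = _b(R, i, k, habs)
                # habitat term: future a, delta b, present c and z
                if c0 not in (None, 0.0):
                    t2 += a2 * (b2 - b0) * c0 * z0
                if b2 == 0.0:
                    continue
                # community term: future a and b, delta c, present z
                c2 = _c(R, i, k, habs) or 0.0
                c0v = c0 or 0.0
                if c2 > 0.0 or c0v > 0.0:
                    t3 += a2 * b2 * (c2 - c0v) * z0
                # transmission: all future probabilities, delta z
                if res[i][k] > 0:
                    t4 += (res[i][k] / n_res) * (
                        _z(F, i, k, habs, component) - z0
                    )
        scale = 1.0 - phi
        t1 *= scale
        t2 *= scale
        t3 *= scale
        t4 *= scale

    t_imm = 0.0
    if n_imm > 0:
        h_i = 0.0
        for i in range(S):
            for k in range(C):
                if imm[i][k] > 0:
                    h_i += (imm[i][k] / n_imm) * _z(F, i, k, habs, component)
        t_imm = phi * (h_i - h_now)

    return {
        "species_selection": t1,
        "habitat_selection": t2,
        "community_selection": t3,
        "transmission": t4,
        "immigration": t_imm,
        "total": total,
    }
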