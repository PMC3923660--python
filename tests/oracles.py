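"""Independent reference implementations used as test oracles.

Everything here is written as plain loops / direct sums, deliberately
separate from the package's vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np

CUTOFF = 8.0
SWITCH_START = 7.0
ELEC_MIN = 5.0
COULOMB = 332.0637
REP_FRAC = 0.6
HB_STRENGTH = 2.0
HB_R0 = 1.9
HB_SIGMA = 0.3
HB_MAX = 3.5


def switch(r: float) -> float:
    if r <= SWITCH_START:
        return 1.0
    if r >= CUTOFF:
        return 0.0
    t = (CUTOFF - r) / (CUTOFF - SWITCH_START)
    return t * t * (3.0 - 2.0 * t)


def lj_pair(r: float, rmin: float, eps: float) -> tuple[float, float]:
    r0 = REP_FRAC * rmin
    rs = max(r, r0)
    x = rmin / rs
    e = eps * (x ** 12 - 2.0 * x ** 6)
    if r >= rmin:
        attr, rep = e, 0.0
    else:
        attr, rep = -eps, e + eps
    if r < r0:
        slope = eps * 12.0 * (x ** 12 - x ** 6) / rs
        rep += slope * (r0 - r)
    return attr, rep


def _pairs(group_a, group_b):
    for res_a, a in group_a:
        for res_b, b in group_b:
            yield res_a, a, res_b, b, float(np.linalg.norm(a.position - b.position))


def _donors(group):
    """[(H entry index, donor heavy entry index)] by geometric detection."""
    out = []
    for i, (res, a) in enumerate(group):
        if not a.is_hydrogen:
            continue
        best = None
        for j, (res2, b) in enumerate(group):
            if res2 is not res or b.is_hydrogen or b.element not in "NOS":
                continue
            d = float(np.linalg.norm(a.position - b.position))
            if d < 1.3 and (best is None or d < best[1]):
                best = (j, d)
        if best:
            out.append((i, best[0]))
    return out


def _acceptors(group):
    out = []
    for i, (res, a) in enumerate(group):
        if a.is_hydrogen:
            continue
        if a.element == "O":
            out.append(i)
        elif a.element == "N":
            has_h = heavy_deg = 0
            for res2, b in group:
                if b is a:
                    continue
                d = float(np.linalg.norm(a.position - b.position))
                if b.is_hydrogen and d < 1.15:
                    has_h += 1
                if not b.is_hydrogen and d < 1.85 and res2 is res:
                    heavy_deg += 1
            if not has_h and heavy_deg <= 2:
                out.append(i)
    return out


def cross_terms_oracle(group_a, group_b) -> dict[str, float]:
    """Direct-sum cross-interface terms over (residue, atom) pair lists."""
    attr = rep = solv = elec = 0.0
    for _, a, _, b, r in _pairs(group_a, group_b):
        if r >= CUTOFF:
            continue
        sw = switch(r)
        at, rp = lj_pair(r, a.lj_radius + b.lj_radius,
                         math.sqrt(a.lj_well_depth * b.lj_well_depth))
        attr += at * sw
        rep += rp * sw
        if not a.is_hydrogen and not b.is_hydrogen:
            fa = a.dg_free / a.lam * math.exp(-((r - a.lj_radius) / a.lam) ** 2)
            fb = b.dg_free / b.lam * math.exp(-((r - b.lj_radius) / b.lam) ** 2)
            pref = 1.0 / (2.0 * math.pi ** 1.5 * r ** 2)
            solv -= (fa * b.volume + fb * a.volume) * pref * sw
        if r >= ELEC_MIN and abs(a.charge * b.charge) > 1e-12:
            elec += COULOMB * a.charge * b.charge / (4.0 * r ** 2) * sw

    hb = 0.0
    for gdon, gacc in ((group_a, group_b), (group_b, group_a)):
        donors = _donors(gdon)
        accs = _acceptors(gacc)
        for hi, di in donors:
            hpos = gdon[hi][1].position
            dpos = gdon[di][1].position
            u1 = hpos - dpos
            u1 = u1 / np.linalg.norm(u1)
            for ai in accs:
                apos = gacc[ai][1].position
                dha = float(np.linalg.norm(apos - hpos))
                if dha > HB_MAX:
                    continue
                u2 = apos - hpos
                u2 = u2 / np.linalg.norm(u2)
                cosang = float(u1 @ u2)
                if cosang <= 0:
                    continue
                hb -= HB_STRENGTH * math.exp(
                    -((dha - HB_R0) ** 2) / (2 * HB_SIGMA ** 2)) * cosang ** 2
    return {"vdw_attr": attr, "vdw_rep": rep, "solvation": solv,
            "hbond": hb, "electrostatics": elec}


def intra_rep_oracle(res) -> float:
    atoms = res.atoms
    n = len(atoms)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            lim = 1.85 if not (atoms[i].is_hydrogen or atoms[j].is_hydrogen) else 1.25
            if np.linalg.norm(atoms[i].position - atoms[j].position) < lim:
                adj[i].add(j)
                adj[j].add(i)
    total = 0.0
    for i in range(n):
        # graph distance by BFS
        dist = {i: 0}
        front = [i]
        while front:
            nxt = []
            for u in front:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            front = nxt
        for j in range(i + 1, n):
            if dist.get(j, 99) < 3:
                continue
            if not (atoms[i].parameterized and atoms[j].parameterized):
                continue
            r = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            if r >= CUTOFF:
                continue
            _, rp = lj_pair(r, atoms[i].lj_radius + atoms[j].lj_radius,
                            math.sqrt(atoms[i].lj_well_depth * atoms[j].lj_well_depth))
            total += rp * switch(r)
    return total


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def kendall_oracle(x, y) -> float:
    """Tau-b by exhaustive pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U: P(pos ranked better than neg),
    lower score = better, ties get half credit."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    u = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def rmsd_align_oracle(p: np.ndarray, q: np.ndarray) -> float:
    """Superposition RMSD via scipy's independent align_vectors solver."""
    from scipy.spatial.transform import Rotation
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    _, rssd = Rotation.align_vectors(pc, qc)
    return rssd / math.sqrt(len(p))
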