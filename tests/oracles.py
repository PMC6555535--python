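"""Brute-force reference implementations used only to check the package.

Everything here works on genotype strings with plain Python loops and
itertools — deliberately independent of the vectorized integer-coded
scans in the package.
"""

from __future__ import annotations

import itertools
import math


def all_genotypes(L):
    return ["".join(b) for b in itertools.product("01", repeat=L)]


def flip(g, p):
    return g[:p] + ("1" if g[p] == "0" else "0") + g[p + 1 :]


def string_neighbors(g):
    return [flip(g, p) for p in range(len(g))]


def string_hamming(g, h):
    return sum(a != b for a, b in zip(g, h))


def oracle_peaks(fit: dict, deltas: dict | None = None, margin: float = 1.0):
    """Strict (or error-aware) peaks by direct neighbor comparison."""
    deltas = deltas or {}
    peaks = []
    for g, w in fit.items():
        lo = w - margin * deltas.get(g, 0.0)
        if all(lo > fit[h] + margin * deltas.get(h, 0.0) for h in string_neighbors(g)):
            peaks.append(g)
    return sorted(peaks)


def oracle_ruggedness(fit: dict, L: int, k: int = 4):
    """Average within-subgraph peak count over every k-position subgraph,
    enumerated genotype-set by genotype-set."""
    total = 0
    n_sub = 0
    for positions in itertools.combinations(range(L), k):
        free = set(positions)
        fixed = [p for p in range(L) if p not in free]
        for bits in itertools.product("01", repeat=L - k):
            members = []
            for sub_bits in itertools.product("01", repeat=k):
                g = [""] * L
                for p, b in zip(fixed, bits):
                    g[p] = b
                for p, b in zip(positions, sub_bits):
                    g[p] = b
                members.append("".join(g))
            mset = set(members)
            n_sub += 1
            for g in members:
                nb = [h for h in string_neighbors(g) if h in mset]
                if all(fit[g] > fit[h] for h in nb):
                    total += 1
    return total / n_sub


def oracle_epistasis_magnitudes(fit: dict, L: int):
    """|log10(W_AB*W_0/(W_A*W_B))| over every 2-position subgraph,
    skipping any subgraph with a non-positive corner."""
    mags, skipped = [], 0
    for i, j in itertools.combinations(range(L), 2):
        fixed = [p for p in range(L) if p not in (i, j)]
        for bits in itertools.product("01", repeat=L - 2):
            g = [""] * L
            for p, b in zip(fixed, bits):
                g[p] = b
            g[i], g[j] = "0", "0"
            w0 = fit["".join(g)]
            g[i] = "1"
            wa = fit["".join(g)]
            g[i], g[j] = "0", "1"
            wb = fit["".join(g)]
            g[i] = "1"
            wab = fit["".join(g)]
            if min(w0, wa, wb, wab) <= 0:
                skipped += 1
            else:
                mags.append(abs(math.log10(wab * w0 / (wa * wb))))
    return sorted(mags), skipped


def oracle_escape(fit: dict, g: str, k: int):
    """Ordered k-mutation trajectories from g with a fitter endpoint,
    by explicit permutation enumeration."""
    L = len(g)
    n_higher = 0
    n_possible = 0
    for perm in itertools.permutations(range(L), k):
        n_possible += 1
        h = g
        for p in perm:
            h = flip(h, p)
        if fit[h] > fit[g]:
            n_higher += 1
    return n_higher, n_possible


def oracle_nearest_distance(source_fit, target_fit, cutoff, mode="cutoff"):
    """All-pairs nearest cross-network distance by direct scan."""
    out = {}
    for g, w in source_fit.items():
        if w < cutoff:
            continue
        thr = cutoff if mode == "cutoff" else w
        best = None
        for h, v in target_fit.items():
            if v >= thr:
                d = string_hamming(g, h)
                best = d if best is None else min(best, d)
        out[g] = -1 if best is None else best
    return out
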