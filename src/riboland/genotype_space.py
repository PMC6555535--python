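"""Combinatorics of the biallelic genotype hypercube.

The genotype space studied here is the set of all combinations of two
alleles at L variable positions — the vertices of an L-dimensional
hypercube.  Genotypes are represented externally as strings over {0,1}
(allele index at each position, position 0 leftmost) and internally,
where speed matters, as integers whose bit p encodes the allele at
position p.  Two genotypes are mutational neighbors when they differ at
exactly one position (Hamming distance 1).

The default dimension is L = 14, the size of the ribozyme library the
package was written to analyze: two reference sequences (a self-cleaving
HDV ribozyme and a ligase ribozyme) differ at 14 sites, and the space
contains every intermediate, 2^14 = 16,384 genotypes in all.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

DEFAULT_L = 14

#: Largest dimension for which full-space enumeration is permitted.
MAX_L = 24

__all__ = [
    "DEFAULT_L",
    "MAX_L",
    "Genotype",
    "Subgraph",
    "genotype_to_index",
    "index_to_genotype",
    "validate_genotype",
    "enumerate_space",
    "neighbors",
    "neighbor_indices",
    "hamming",
    "genotypes_at_distance",
    "count_trajectories",
    "enumerate_subgraphs",
]

Genotype = str  # L-character string over {0,1}


def validate_genotype(g: Genotype, L: int | None = None) -> str:
    """Validate a genotype string; return it unchanged.

    Raises ``ValueError`` if it contains characters outside {0,1} or, when
    *L* is given, has the wrong length.
    """
    if not isinstance(g, str):
        raise TypeError(f"genotype must be a str, got {type(g).__name__}")
    if L is not None and len(g) != L:
        raise ValueError(f"genotype {g!r} has length {len(g)}, expected {L}")
    if set(g) - {"0", "1"}:
        bad = sorted(set(g) - {"0", "1"})
        raise ValueError(f"genotype {g!r} contains invalid characters {bad}")
    if len(g) == 0:
        raise ValueError("genotype must be non-empty")
    return g


def genotype_to_index(g: Genotype) -> int:
    """Integer code of a genotype: bit p holds the allele at position p."""
    validate_genotype(g)
    idx = 0
    for p, c in enumerate(g):
        if c == "1":
            idx |= 1 << p
    return idx


def index_to_genotype(idx: int, L: int) -> Genotype:
    """Inverse of :func:`genotype_to_index`."""
    if not 0 <= idx < (1 << L):
        raise ValueError(f"index {idx} out of range for L={L}")
    return "".join("1" if idx >> p & 1 else "0" for p in range(L))


@dataclass(frozen=True)
class AlleleMap:
    """Optional display sidecar mapping each position to a nucleotide pair.

    ``pairs[p] = (ref_nt, alt_nt)``: allele '0' at position p displays as
    ``ref_nt``, allele '1' as ``alt_nt``.
    """

    pairs: tuple[tuple[str, str], ...]

    def to_nucleotides(self, g: Genotype) -> str:
        validate_genotype(g, L=len(self.pairs))
        return "".join(self.pairs[p][int(c)] for p, c in enumerate(g))

    def from_nucleotides(self, seq: str) -> Genotype:
        if len(seq) != len(self.pairs):
            raise ValueError("sequence length does not match allele map")
        out = []
        for p, nt in enumerate(seq):
            ref, alt = self.pairs[p]
            if nt == ref:
                out.append("0")
            elif nt == alt:
                out.append("1")
            else:
                raise ValueError(f"nucleotide {nt!r} at position {p} not in {ref, alt}")
        return "".join(out)


@dataclass(frozen=True)
class Subgraph:
    """An induced sub-hypercube: k free positions on a fixed background.

    ``positions`` are the 0-based indices that vary; ``background`` fixes
    the remaining L−k positions (its alleles at the free positions are
    ignored and canonicalized to '0').
    """

    positions: tuple[int, ...]
    background: Genotype

    def __post_init__(self) -> None:
        L = len(self.background)
        validate_genotype(self.background)
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("subgraph positions must be distinct")
        for p in self.positions:
            if not 0 <= p < L:
                raise ValueError(f"position {p} out of range for L={L}")
        # canonical background: zero at the free positions
        bg = list(self.background)
        for p in self.positions:
            bg[p] = "0"
        object.__setattr__(self, "background", "".join(bg))

    @property
    def k(self) -> int:
        return len(self.positions)

    def members(self) -> list[Genotype]:
        """The 2^k genotypes varying only at the free positions."""
        out = []
        bg = list(self.background)
        for bits in itertools.product("01", repeat=self.k):
            g = bg[:]
            for p, b in zip(self.positions, bits):
                g[p] = b
            out.append("".join(g))
        return out

    def member_indices(self) -> list[int]:
        base = genotype_to_index(self.background)
        masks = [1 << p for p in self.positions]
        out = []
        for bits in itertools.product((0, 1), repeat=self.k):
            idx = base
            for m, b in zip(masks, bits):
                if b:
                    idx |= m
            out.append(idx)
        return out


def enumerate_space(L: int) -> list[Genotype]:
    """All 2^L genotypes in lexicographic (canonical) order.

    Lexicographic order over the strings corresponds to counting with
    position 0 as the most significant digit.
    """
    if not 1 <= L <= MAX_L:
        raise ValueError(f"L={L} out of supported range [1, {MAX_L}]")
    return ["".join(bits) for bits in itertools.product("01", repeat=L)]


def neighbors(g: Genotype) -> list[Genotype]:
    """The L single-mutation neighbors of *g*, in position order."""
    validate_genotype(g)
    out = []
    for p, c in enumerate(g):
        out.append(g[:p] + ("1" if c == "0" else "0") + g[p + 1 :])
    return out


def neighbor_indices(idx: int, L: int) -> list[int]:
    """Integer codes of the L neighbors of integer-coded genotype *idx*."""
    return [idx ^ (1 << p) for p in range(L)]


def hamming(g: Genotype, h: Genotype) -> int:
    """Number of positions at which two equal-length genotypes differ."""
    if len(g) != len(h):
        raise ValueError(f"length mismatch: {len(g)} vs {len(h)}")
    return sum(a != b for a, b in zip(g, h))


def genotypes_at_distance(ref: Genotype, d: int) -> list[Genotype]:
    """All C(L, d) genotypes at exact Hamming distance *d* from *ref*."""
    validate_genotype(ref)
    L = len(ref)
    if not 0 <= d <= L:
        raise ValueError(f"distance {d} out of range [0, {L}]")
    out = []
    for positions in itertools.combinations(range(L), d):
        g = list(ref)
        for p in positions:
            g[p] = "1" if g[p] == "0" else "0"
        out.append("".join(g))
    return out


def count_trajectories(L: int, k: int) -> int:
    """Number of ordered mutation trajectories touching k distinct positions.

    A trajectory is an ordered choice of k distinct positions to mutate,
    so the count is the falling factorial L·(L−1)·…·(L−k+1).  At L=14
    there are 182 two-mutation and 2,184 three-mutation trajectories.
    """
    if k < 0 or k > L:
        raise ValueError(f"k={k} out of range [0, {L}]")
    return math.perm(L, k)


def enumerate_subgraphs(
    L: int, k: int, mode: str = "all-backgrounds"
) -> Iterator[Subgraph]:
    """Stream the induced k-dimensional sub-hypercubes of the L-cube.

    mode="all-backgrounds" (default): every choice of k free positions
    with every one of the 2^(L−k) backgrounds — C(L,k)·2^(L−k) subgraphs,
    each genotype subset produced exactly once.

    mode="per-position-set": identical subgraphs, grouped so that each of
    the C(L,k) position choices streams its full partition of the space
    into 2^(L−k) backgrounds before moving on.  The two modes differ only
    in iteration order.
    """
    if not 1 <= k <= L:
        raise ValueError(f"k={k} out of range [1, {L}]")
    if mode not in ("all-backgrounds", "per-position-set"):
        raise ValueError(f"unknown mode {mode!r}")
    # Both modes enumerate position sets outermost; order within a position
    # set is by background.  They coincide; the distinction is kept for API
    # compatibility with grouped/streamed consumption.
    for positions in itertools.combinations(range(L), k):
        fixed = [p for p in range(L) if p not in positions]
        for bits in itertools.product("01", repeat=L - k):
            bg = ["0"] * L
            for p, b in zip(fixed, bits):
                bg[p] = b
            yield Subgraph(positions=positions, background="".join(bg))
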