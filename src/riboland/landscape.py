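"""The Landscape container: a total fitness map on the L-cube.

Fitness is stored as a dense numpy vector indexed by the integer genotype
code (bit p = allele at position p), which makes neighbor comparisons,
subgraph scans and Wright-Fisher lookups vectorizable: the neighbor of
index ``i`` at position ``p`` is simply ``i ^ (1 << p)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .genotype_space import (
    Genotype,
    genotype_to_index,
    index_to_genotype,
    validate_genotype,
)

__all__ = ["Landscape"]


@dataclass
class Landscape:
    """Total fitness map on the 2^L genotype space.

    Parameters
    ----------
    L : int
        Number of variable positions.
    fitness : ndarray, shape (2**L,)
        Relative fitness per genotype, indexed by integer code; all
        values must be finite and >= 0.
    delta : ndarray or None
        Per-genotype replicate standard error, same shape; used by
        error-aware peak detection.
    reference : str or None
        The landscape's reference genotype (fitness-normalization
        anchor), if any.
    name : str
        Label used in reports.
    """

    L: int
    fitness: np.ndarray
    delta: np.ndarray | None = None
    reference: Genotype | None = None
    name: str = "landscape"

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.fitness.shape != (1 << self.L,):
            raise ValueError(
                f"fitness must have shape (2**{self.L},) = ({1 << self.L},), "
                f"got {self.fitness.shape}"
            )
        if not np.all(np.isfinite(self.fitness)):
            raise ValueError("fitness contains non-finite values")
        if np.any(self.fitness < 0):
            raise ValueError("fitness contains negative values")
        if self.delta is not None:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.shape != self.fitness.shape:
                raise ValueError("delta shape does not match fitness")
            if np.any(~np.isfinite(self.delta)) or np.any(self.delta < 0):
                raise ValueError("delta must be finite and >= 0")
        if self.reference is not None:
            validate_genotype(self.reference, L=self.L)

    # -- construction -------------------------------------------------

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[Genotype, float],
        L: int | None = None,
        delta: Mapping[Genotype, float] | None = None,
        **kwargs,
    ) -> "Landscape":
        """Build from a {genotype string: fitness} mapping.

        The mapping must cover all 2^L genotypes (the landscape is total).
        """
        if not mapping:
            raise ValueError("empty fitness mapping")
        if L is None:
            L = len(next(iter(mapping)))
        n = 1 << L
        if len(mapping) != n:
            raise ValueError(
                f"landscape must be total: got {len(mapping)} of {n} genotypes"
            )
        fit = np.empty(n, dtype=float)
        seen = np.zeros(n, dtype=bool)
        for g, w in mapping.items():
            i = genotype_to_index(validate_genotype(g, L=L))
            if seen[i]:
                raise ValueError(f"duplicate genotype {g!r}")
            seen[i] = True
            fit[i] = w
        if not seen.all():
            missing = index_to_genotype(int(np.flatnonzero(~seen)[0]), L)
            raise ValueError(f"missing genotype, e.g. {missing!r}")
        darr = None
        if delta is not None:
            darr = np.zeros(n, dtype=float)
            for g, d in delta.items():
                darr[genotype_to_index(validate_genotype(g, L=L))] = d
        return cls(L=L, fitness=fit, delta=darr, **kwargs)

    # -- access --------------------------------------------------------

    def __getitem__(self, g: Genotype) -> float:
        return float(self.fitness[genotype_to_index(validate_genotype(g, L=self.L))])

    def delta_of(self, g: Genotype) -> float:
        if self.delta is None:
            return 0.0
        return float(self.delta[genotype_to_index(validate_genotype(g, L=self.L))])

    @property
    def n_genotypes(self) -> int:
        return 1 << self.L

    @property
    def summit_index(self) -> int:
        """Integer code of the global fitness maximum (lowest index on ties)."""
        return int(np.argmax(self.fitness))

    @property
    def summit(self) -> Genotype:
        return index_to_genotype(self.summit_index, self.L)

    @property
    def summit_fitness(self) -> float:
        return float(self.fitness[self.summit_index])

    def genotypes(self) -> Iterable[Genotype]:
        for i in range(self.n_genotypes):
            yield index_to_genotype(i, self.L)

    def to_mapping(self) -> dict[Genotype, float]:
        return {index_to_genotype(i, self.L): float(w) for i, w in enumerate(self.fitness)}

    def normalized(self) -> "Landscape":
        """Copy with fitness divided by the landscape maximum (summit -> 1)."""
        m = self.summit_fitness
        if m <= 0:
            raise ValueError("cannot normalize: maximum fitness is 0")
        return Landscape(
            L=self.L,
            fitness=self.fitness / m,
            delta=None if self.delta is None else self.delta / m,
            reference=self.reference,
            name=self.name,
        )
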