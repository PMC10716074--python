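"""In-memory container for simulated diploid individuals.

A :class:`Population` stores the two haplotypes of every individual over all
sites of a genome map (chromosome-major site order), together with pool /
role / generation bookkeeping and optional pedigree links.  Alleles are
biallelic and coded 0/1; haplotypes are ``uint8`` arrays of shape
``(n, 2, n_sites)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import RRSimError

POOL_LABELS = ("A", "B", "none")
ROLE_LABELS = ("founder", "line", "tester", "hybrid", "parent")

_id_counter = itertools.count(1)


def fresh_ids(n: int) -> np.ndarray:
    """Return ``n`` process-unique int64 individual identifiers."""
    return np.fromiter(itertools.islice(_id_counter, n), dtype=np.int64, count=n)


@dataclass
class Population:
    ids: np.ndarray                 # (n,) int64, unique
    haplotypes: np.ndarray          # (n, 2, m) uint8 in {0, 1}
    pool: np.ndarray                # (n,) str in POOL_LABELS
    role: np.ndarray                # (n,) str in ROLE_LABELS
    generation: np.ndarray          # (n,) int32 cycle index
    mothers: np.ndarray = field(default=None, repr=False)  # (n,) int64 or None
    fathers: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise RRSimError(
                f"haplotypes must have shape (n, 2, n_sites); got {self.haplotypes.shape}"
            )
        n = self.haplotypes.shape[0]
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.shape != (n,):
            raise RRSimError("ids length does not match haplotypes")
        if len(np.unique(self.ids)) != n:
            raise RRSimError("individual ids must be unique within a population")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_haplotypes(
        cls,
        haplotypes: np.ndarray,
        pool: str = "none",
        role: str = "founder",
        generation: int = 0,
        ids: np.ndarray | None = None,
        mothers: np.ndarray | None = None,
        fathers: np.ndarray | None = None,
    ) -> "Population":
        n = haplotypes.shape[0]
        return cls(
            ids=fresh_ids(n) if ids is None else ids,
            haplotypes=haplotypes,
            pool=np.full(n, pool, dtype="<U4"),
            role=np.full(n, role, dtype="<U8"),
            generation=np.full(n, generation, dtype=np.int32),
            mothers=mothers,
            fathers=fathers,
        )

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[2]

    def dosage(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 count per individual and site, in {0, 1, 2}."""
        h = self.haplotypes if sites is None else self.haplotypes[:, :, sites]
        return h.sum(axis=1, dtype=np.int8)

    def centered_dosage(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Dosage coded {aa, Aa, AA} = {-1, 0, +1}."""
        return (self.dosage(sites) - 1).astype(np.int8)

    def het(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Heterozygosity indicator per individual and site, in {0, 1}."""
        h = self.haplotypes if sites is None else self.haplotypes[:, :, sites]
        return (h[:, 0, :] != h[:, 1, :]).astype(np.int8)

    def allele_freq(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Frequency of the 1-allele per site, over both haplotypes."""
        h = self.haplotypes if sites is None else self.haplotypes[:, :, sites]
        return h.mean(axis=(0, 1))

    def is_fully_inbred(self) -> np.ndarray:
        """Boolean per individual: identical haplotype pair at every site."""
        return (self.haplotypes[:, 0, :] == self.haplotypes[:, 1, :]).all(axis=1)

    def line_genotypes(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Per-line genotype in {-1, +1} for fully inbred individuals.

        Raises if any individual is heterozygous anywhere, since a single
        haplotype then no longer determines the genotype.
        """
        if not self.is_fully_inbred().all():
            raise RRSimError("line_genotypes requires fully inbred individuals")
        h = self.haplotypes[:, 0, :] if sites is None else self.haplotypes[:, 0, sites]
        return (2 * h.astype(np.int8) - 1)

    # -- manipulation ------------------------------------------------------

    def subset(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        return Population(
            ids=self.ids[idx],
            haplotypes=self.haplotypes[idx],
            pool=self.pool[idx],
            role=self.role[idx],
            generation=self.generation[idx],
            mothers=None if self.mothers is None else self.mothers[idx],
            fathers=None if self.fathers is None else self.fathers[idx],
        )

    def copy(self) -> "Population":
        return Population(
            ids=self.ids.copy(),
            haplotypes=self.haplotypes.copy(),
            pool=self.pool.copy(),
            role=self.role.copy(),
            generation=self.generation.copy(),
            mothers=None if self.mothers is None else self.mothers.copy(),
            fathers=None if self.fathers is None else self.fathers.copy(),
        )

    @staticmethod
    def concat(pops: list["Population"]) -> "Population":
        return Population(
            ids=np.concatenate([p.ids for p in pops]),
            haplotypes=np.concatenate([p.haplotypes for p in pops]),
            pool=np.concatenate([p.pool for p in pops]),
            role=np.concatenate([p.role for p in pops]),
            generation=np.concatenate([p.generation for p in pops]),
        )
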