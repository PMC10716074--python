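"""Meiosis, crossing, inbreeding and hybrid-genotype deduction.

Crossovers follow a Poisson process along the genetic map (expected count =
map length in Morgans), positions uniform, no interference and no obligate
chiasma; mutation is disabled.  :func:`make_gamete` implements that model
literally for a single meiosis.  :func:`gametes_batch` is the vectorised
engine used by the simulator: it samples, per interval between adjacent
mapped sites, an independent switch indicator with the Haldane
recombination fraction ``(1 - exp(-2d/100))/2`` — exactly the inheritance
law the Poisson process induces at the mapped sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import RRSimError
from .genome import GenomeMap
from .population import Population

CROSS_KINDS = ("intra_pool", "testcross", "inter_pool", "self")


@dataclass
class CrossPlan:
    mother_id: int
    father_id: int
    n_progeny: int = 1
    cross_kind: str = "intra_pool"

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise RRSimError("n_progeny must be >= 1")
        if self.cross_kind not in CROSS_KINDS:
            raise RRSimError(f"unknown cross kind {self.cross_kind!r}")


def make_gamete(
    parent: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
    return_crossovers: bool = False,
) -> np.ndarray | tuple[np.ndarray, int]:
    """One meiotic gamete from a (2, n_sites) parent haplotype pair."""
    parent = np.asarray(parent)
    if parent.shape != (2, gmap.n_sites):
        raise RRSimError("parent haplotypes do not conform to the genome map")
    gamete = np.empty(gmap.n_sites, dtype=np.uint8)
    total_xo = 0
    for c, sl in enumerate(gmap.chrom_slices):
        length_m = gmap.lengths_cM[c] / 100.0
        n_xo = rng.poisson(length_m)
        total_xo += n_xo
        start = int(rng.random() < 0.5)
        if n_xo == 0:
            gamete[sl] = parent[start, sl]
            continue
        xo_pos = np.sort(rng.uniform(0.0, gmap.lengths_cM[c], size=n_xo))
        source = (start + np.searchsorted(xo_pos, gmap.positions[c])) % 2
        h = parent[:, sl]
        gamete[sl] = np.where(source == 0, h[0], h[1])
    if return_crossovers:
        return gamete, total_xo
    return gamete


def gametes_batch(haplotypes: np.ndarray, gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent; ``haplotypes`` has shape (n, 2, n_sites)."""
    n = haplotypes.shape[0]
    out = np.empty((n, gmap.n_sites), dtype=np.uint8)
    for sl, r in zip(gmap.chrom_slices, gmap.interval_switch_probs()):
        k = sl.stop - sl.start
        u = rng.random((n, k), dtype=np.float32)
        switches = np.empty((n, k), dtype=bool)
        switches[:, 0] = u[:, 0] < 0.5          # random starting haplotype
        switches[:, 1:] = u[:, 1:] < r          # Haldane interval switches
        source = np.bitwise_xor.accumulate(switches, axis=1)  # crossover parity
        h = haplotypes[:, :, sl]
        out[:, sl] = np.where(source, h[:, 1, :], h[:, 0, :])
    return out


def cross(
    mother: np.ndarray,
    father: np.ndarray,
    n_progeny: int,
    gmap: GenomeMap,
    rng: np.random.Generator,
    pool: str = "none",
    generation: int = 0,
) -> Population:
    """F1 progeny of two individuals; one independent gamete from each."""
    haps = np.empty((n_progeny, 2, gmap.n_sites), dtype=np.uint8)
    for i in range(n_progeny):
        haps[i, 0] = make_gamete(mother, gmap, rng)
        haps[i, 1] = make_gamete(father, gmap, rng)
    return Population.from_haplotypes(haps, pool=pool, role="hybrid", generation=generation)


def make_inbred_line(
    f1: np.ndarray,
    gmap: GenomeMap,
    method: str = "doubled_gamete",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Derive a fully (or near-fully) inbred line from one individual.

    ``doubled_gamete`` draws a single gamete and duplicates it (instant full
    homozygosity, the package default standing in for rapid single-seed
    descent).  ``ssd_<k>`` performs k generations of selfing, keeping one
    random offspring each generation; residual heterozygosity halves per
    generation.
    """
    if rng is None:
        rng = np.random.default_rng()
    f1 = np.asarray(f1)
    if method == "doubled_gamete":
        g = make_gamete(f1, gmap, rng)
        return np.stack([g, g])
    if method.startswith("ssd_"):
        try:
            k = int(method[4:])
        except ValueError:
            raise RRSimError(f"unknown inbreeding method {method!r}") from None
        current = f1
        for _ in range(k):
            current = np.stack(
                [make_gamete(current, gmap, rng), make_gamete(current, gmap, rng)]
            )
        return current
    raise RRSimError(f"unknown inbreeding method {method!r}")


def doubled_gametes_batch(haplotypes: np.ndarray, gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """Vectorised doubled-gamete inbreeding; returns (n, 2, n_sites)."""
    gams = gametes_batch(haplotypes, gmap, rng)
    return np.repeat(gams[:, None, :], 2, axis=1)


def deduce_hybrid_genotype(mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    """Deterministic F1 genotype of two fully homozygous parents.

    Returns the maternal + paternal haplotype pair; raises if either parent
    is heterozygous anywhere, since the deduction is then invalid.
    """
    mother = np.asarray(mother)
    father = np.asarray(father)
    for name, h in (("mother", mother), ("father", father)):
        if not np.array_equal(h[0], h[1]):
            raise RRSimError(f"{name} is not fully homozygous; cannot deduce the F1")
    return np.stack([mother[0], father[0]]).astype(np.uint8)


def random_mate_within_pool(
    parents: Population,
    n_lines: int,
    rng: np.random.Generator,
) -> list[CrossPlan]:
    """Uniform random parent pairs (no selfing), one planned line per pair."""
    n = len(parents)
    if n < 2:
        raise RRSimError("random mating requires at least two parents in the pool")
    mothers = rng.integers(0, n, size=n_lines)
    fathers = (mothers + rng.integers(1, n, size=n_lines)) % n
    return [
        CrossPlan(int(parents.ids[i]), int(parents.ids[j]), 1, "intra_pool")
        for i, j in zip(mothers, fathers)
    ]


def derive_lines(
    parents: Population,
    n_lines: int,
    gmap: GenomeMap,
    rng: np.random.Generator,
    generation: int = 0,
) -> Population:
    """Random-mate a pool's parents and inbreed one line per pair.

    Vectorised equivalent of: random_mate_within_pool -> cross (one F1 per
    pair) -> doubled-gamete inbreeding of each F1.
    """
    plans = random_mate_within_pool(parents, n_lines, rng)
    id_to_row = {int(pid): r for r, pid in enumerate(parents.ids)}
    mi = np.array([id_to_row[p.mother_id] for p in plans])
    fi = np.array([id_to_row[p.father_id] for p in plans])
    f1 = np.stack(
        [gametes_batch(parents.haplotypes[mi], gmap, rng),
         gametes_batch(parents.haplotypes[fi], gmap, rng)],
        axis=1,
    )
    lines = doubled_gametes_batch(f1, gmap, rng)
    return Population.from_haplotypes(
        lines,
        pool=str(parents.pool[0]),
        role="line",
        generation=generation,
        mothers=parents.ids[mi],
        fathers=parents.ids[fi],
    )
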