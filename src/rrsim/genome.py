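"""Genome map construction and founder-panel simulation.

The genome map places segregating sites on a genetic map (positions in cM)
and labels disjoint subsets of them as causal loci (QTN) and as the
genotyping panel (SNP).  The founder panel emulates a diversity panel of
fully inbred lines: a Wright-Fisher population is random-mated with
recombination for many generations to build linkage disequilibrium, and
each founder is then derived by doubling a single gamete, which yields a
fully homozygous genome while preserving allele frequencies and LD.

Default dimensions describe a rice-like genome: 12 chromosomes of 130 cM,
30 QTN and 83 SNP per chromosome (360 QTN / 996 SNP genome-wide), and a
panel of 3,000 inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, GenerationError
from .population import Population

SITE_NEUTRAL, SITE_QTN, SITE_SNP = 0, 1, 2
_SITE_NAMES = {SITE_NEUTRAL: "neutral", SITE_QTN: "QTN", SITE_SNP: "SNP"}


@dataclass
class GenomeConfig:
    """Parameters of the genome map and founder generator."""

    chromosomes: int = 12
    length_cM: float = 130.0
    n_sites: int = 600          # segregating sites per chromosome
    n_qtn: int = 30             # causal loci per chromosome
    n_snp: int = 83             # genotyping-panel sites per chromosome
    n_founders: int = 3000
    seed: int | None = None
    # Wright-Fisher founder generator
    wf_size: int = 200          # diploid individuals
    wf_generations: int = 200   # generations of random mating
    freq_beta: tuple[float, float] = (0.5, 0.5)
    freq_clamp: tuple[float, float] = (0.05, 0.95)
    max_resample: int = 100     # attempts to fix a monomorphic site

    def __post_init__(self) -> None:
        self.freq_beta = tuple(self.freq_beta)
        self.freq_clamp = tuple(self.freq_clamp)


@dataclass
class GenomeMap:
    """Chromosome structure, site positions (cM) and site labels.

    Sites are stored in chromosome-major order; all per-site arrays across
    the package follow this flat ordering.
    """

    lengths_cM: np.ndarray          # (n_chrom,)
    positions: list[np.ndarray]     # per chromosome, strictly increasing, cM
    site_class: np.ndarray          # (n_sites_total,) uint8

    chrom_slices: list[slice] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lengths_cM = np.asarray(self.lengths_cM, dtype=float)
        self.site_class = np.asarray(self.site_class, dtype=np.uint8)
        offset = 0
        self.chrom_slices = []
        for c, pos in enumerate(self.positions):
            pos = np.asarray(pos, dtype=float)
            self.positions[c] = pos
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] > self.lengths_cM[c]):
                raise ConfigurationError(
                    f"chromosome {c + 1}: positions must be strictly increasing in [0, length]"
                )
            self.chrom_slices.append(slice(offset, offset + pos.size))
            offset += pos.size
        if self.site_class.size != offset:
            raise ConfigurationError("site_class length does not match total site count")

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_sites(self) -> int:
        return self.site_class.size

    @property
    def qtn_indices(self) -> np.ndarray:
        return np.flatnonzero(self.site_class == SITE_QTN)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.site_class == SITE_SNP)

    @property
    def chrom_of_site(self) -> np.ndarray:
        out = np.empty(self.n_sites, dtype=np.int32)
        for c, sl in enumerate(self.chrom_slices):
            out[sl] = c
        return out

    @property
    def flat_positions(self) -> np.ndarray:
        return np.concatenate(self.positions)

    def interval_switch_probs(self) -> list[np.ndarray]:
        """Per-chromosome recombination fraction between adjacent sites.

        Haldane mapping of the Poisson crossover process:
        ``r = (1 - exp(-2 d / 100)) / 2`` for an interval of ``d`` cM.
        Under no crossover interference the switch indicators of successive
        intervals are independent, so sampling them directly reproduces the
        Poisson-crossover inheritance law at the mapped sites.
        """
        if not hasattr(self, "_switch_probs"):
            self._switch_probs = [
                0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0)) for pos in self.positions
            ]
        return self._switch_probs


def build_genome_map(config: GenomeConfig, rng: np.random.Generator | None = None) -> GenomeMap:
    """Draw site positions and assign disjoint QTN / SNP labels.

    Positions are uniform on each chromosome; QTN and SNP sites are drawn
    jointly without replacement so the two sets can never overlap.
    """
    if config.chromosomes < 1:
        raise ConfigurationError("need at least one chromosome")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_labelled = config.n_qtn + config.n_snp
    positions, classes = [], []
    for c in range(config.chromosomes):
        if n_labelled > config.n_sites:
            raise ConfigurationError(
                f"chromosome {c + 1}: {config.n_qtn} QTN + {config.n_snp} SNP "
                f"exceed {config.n_sites} available sites"
            )
        pos = np.sort(rng.uniform(0.0, config.length_cM, size=config.n_sites))
        while np.any(np.diff(pos) <= 0):  # measure-zero guard against ties
            pos = np.sort(rng.uniform(0.0, config.length_cM, size=config.n_sites))
        chosen = rng.choice(config.n_sites, size=n_labelled, replace=False)
        cls = np.zeros(config.n_sites, dtype=np.uint8)
        cls[chosen[: config.n_qtn]] = SITE_QTN
        cls[chosen[config.n_qtn:]] = SITE_SNP
        positions.append(pos)
        classes.append(cls)
    return GenomeMap(
        lengths_cM=np.full(config.chromosomes, config.length_cM),
        positions=positions,
        site_class=np.concatenate(classes),
    )


def _initial_frequencies(config: GenomeConfig, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    a, b = config.freq_beta
    lo, hi = config.freq_clamp
    return np.clip(rng.beta(a, b, size=n_sites), lo, hi)


def simulate_founder_panel(
    gmap: GenomeMap,
    n_founders: int | None = None,
    seed: int | np.random.Generator | None = None,
    config: GenomeConfig | None = None,
) -> Population:
    """Simulate a panel of fully inbred founder lines.

    A Wright-Fisher population of ``wf_size`` diploids is initialised with
    per-site allele frequencies from a clamped Beta spectrum, random-mated
    with recombination for ``wf_generations`` generations (building LD that
    decays with map distance), and each founder is the doubled gamete of a
    random individual.  Any site monomorphic in the finished panel is
    re-drawn i.i.d. from the frequency spectrum (up to ``max_resample``
    attempts) so that every QTN and SNP segregates downstream.
    """
    from .mating import gametes_batch  # local import to avoid cycle

    config = config or GenomeConfig()
    if n_founders is None:
        n_founders = config.n_founders
    if n_founders < 2:
        raise ConfigurationError("n_founders must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m = gmap.n_sites
    n_wf = config.wf_size
    freqs = _initial_frequencies(config, m, rng)
    # initial WF haplotypes, re-drawing any site monomorphic at start
    haps = (rng.random((n_wf, 2, m)) < freqs).astype(np.uint8)
    for attempt in range(config.max_resample):
        mono = _monomorphic_sites(haps)
        if not mono.size:
            break
        freqs[mono] = _initial_frequencies(config, mono.size, rng)
        haps[:, :, mono] = (rng.random((n_wf, 2, mono.size)) < freqs[mono]).astype(np.uint8)
    else:
        raise GenerationError("could not initialise polymorphic Wright-Fisher population")

    for _ in range(config.wf_generations):
        mothers = rng.integers(0, n_wf, size=n_wf)
        fathers = rng.integers(0, n_wf, size=n_wf)
        parents = np.concatenate([mothers, fathers])
        gams = gametes_batch(haps[parents], gmap, rng)
        haps = np.stack([gams[:n_wf], gams[n_wf:]], axis=1)

    # founders: doubled gametes of random WF individuals
    picks = rng.integers(0, n_wf, size=n_founders)
    gams = gametes_batch(haps[picks], gmap, rng)
    founder_haps = np.repeat(gams[:, None, :], 2, axis=1)

    # guarantee segregation at every site (drift may have fixed some)
    mono = _monomorphic_sites(founder_haps)
    for site in mono:
        for attempt in range(config.max_resample):
            p = float(_initial_frequencies(config, 1, rng)[0])
            col = (rng.random(n_founders) < p).astype(np.uint8)
            if 0 < col.sum() < n_founders:
                founder_haps[:, 0, site] = col
                founder_haps[:, 1, site] = col
                break
        else:
            raise GenerationError(f"site {site} could not be made polymorphic "
                                  f"after {config.max_resample} attempts")

    return Population.from_haplotypes(founder_haps, pool="none", role="founder", generation=0)


def _monomorphic_sites(haps: np.ndarray) -> np.ndarray:
    counts = haps.sum(axis=(0, 1))
    total = haps.shape[0] * 2
    return np.flatnonzero((counts == 0) | (counts == total))
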