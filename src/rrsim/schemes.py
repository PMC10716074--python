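"""Reciprocal recurrent selection (RRS) breeding schemes for hybrid rice.

Five schemes are orchestrated over a shared base population and burn-in:

* ``TRAD_RRS``     — phenotypic testcross selection with three static
  testers per heterotic pool.
* ``DRIFT_RRS``    — identical mechanics, but the advanced hybrids are a
  uniform random sample (pure drift benchmark).
* ``TRAD_RRS_UP``  — phenotypic selection with the three testers of each
  pool replaced every cycle by the pool's three best testcross parents.
* ``GS_A_RRS``     — all L x L single crosses between the pools' inbred
  lines are predicted in silico with an additive RR-BLUP model; the top HO
  predictions are field-evaluated and drive selection.
* ``GS_AD_RRS``    — as GS_A_RRS with an additive + dominance model.

Breeding sizes I/II/III set the number of lines sampled per pool (L), the
hybrids predicted in silico (HI = L^2), the hybrids actually obtained and
phenotyped (HO = 2 pools x L lines x 3 testers), and the parents recycled
per pool (P).  Every cycle: P parents random-mate within each pool, one
fully inbred line is derived per pair, lines are evaluated (testcross or
prediction), the P best hybrids determine the next parents (their female
parents re-enter pool A, male parents pool B), and the best hybrid is
"released" as bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, RRSimError
from .genome import GenomeConfig, GenomeMap, build_genome_map, simulate_founder_panel
from .mating import derive_lines
from .metrics import (additive_variance_pool, fst_between_pools, hybrid_summary,
                      prediction_accuracy)
from .population import Population
from .prediction import (GramCache, TrainingSet, fit_rrblup, hybrid_codes_from_lines,
                         predict_hybrids, update_training_set_gpo)
from .trait import TraitArchitecture, calibrate_trait, genetic_values, phenotype, sample_effects

logger = logging.getLogger(__name__)

SCHEMES = ("TRAD_RRS", "DRIFT_RRS", "TRAD_RRS_UP", "GS_A_RRS", "GS_AD_RRS")
N_TESTERS = 3


@dataclass(frozen=True)
class BreedingSize:
    label: str
    lines: int                # L, sampled per heterotic pool
    hybrids_insilico: int     # HI = L^2 (genomic schemes only)
    hybrids_obtained: int     # HO = 2 pools x L x 3 testers
    parents: int              # P, recycled per pool


BREEDING_SIZES: dict[str, BreedingSize] = {
    "I": BreedingSize("I", 64, 4096, 384, 10),
    "II": BreedingSize("II", 128, 16384, 768, 20),
    "III": BreedingSize("III", 192, 36864, 1152, 30),
}


@dataclass
class PoolState:
    """One heterotic pool: its recycled parents, testers and current lines."""

    label: str
    parents: Population
    testers: Population
    lines: Population | None = None
    cycle: int = 0

    def copy(self) -> "PoolState":
        return PoolState(
            label=self.label,
            parents=self.parents.copy(),
            testers=self.testers.copy(),
            lines=None if self.lines is None else self.lines.copy(),
            cycle=self.cycle,
        )


@dataclass
class HybridRecord:
    """One realized single-cross hybrid (see CycleData for the batch form)."""

    mother_id: int
    father_id: int
    true_value: float
    phenotype: float
    predicted: float | None = None


@dataclass
class CycleData:
    """Per-cycle evaluation set and bookkeeping used by the metrics layer."""

    true_values: np.ndarray          # HO realized hybrids
    phenotypes: np.ndarray
    predicted: np.ndarray | None     # genomic schemes only
    aside_ids: np.ndarray            # pool-A-side (female) parent of each hybrid
    bside_ids: np.ndarray            # pool-B-side (male) parent
    lines_a: Population
    lines_b: Population
    released: HybridRecord | None = None
    marker_G: np.ndarray | None = None   # deduced SNP codes of the realized hybrids
    marker_T: np.ndarray | None = None
    grid_accuracy: float | None = None   # corr(true, predicted) over all L x L crosses


@dataclass
class SchemeConfig:
    """Full run configuration: scheme arm, sizes, genome, trait and seeds."""

    scheme: str = "TRAD_RRS"
    size: str = "I"
    n_cycles: int = 20
    n_replicates: int = 100
    master_seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    # trait
    mean_dd: float = 0.22          # mean dominance degree
    var_dd: float = 0.26           # variance of dominance degrees
    target_var_g: float = 1.0      # genetic variance in the founder panel
    target_H2: float = 0.53        # broad-sense heritability in the founder panel
    # base population and burn-in
    n_base_parents: int = 384
    n_pool_parents: int = 10
    n_testers: int = N_TESTERS
    burnin_cycles: int = 3
    burnin_size: str = "I"
    gpo_window: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        for s in (self.size, self.burnin_size):
            if s not in BREEDING_SIZES:
                raise ConfigurationError(f"unknown breeding size {s!r}")
        if isinstance(self.genome, dict):
            self.genome = GenomeConfig(**self.genome)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SchemeConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SchemeConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers


def _select_unique_parents(
    aside_ids: np.ndarray,
    bside_ids: np.ndarray,
    n_per_pool: int,
    strict: bool = True,
    disjoint: bool = False,
) -> tuple[list[int], list[int]]:
    """Walk a ranked hybrid list collecting unique parents for each pool.

    Unseen female-side parents fill pool A, unseen male-side parents pool
    B, until each pool holds ``n_per_pool``; later-ranked hybrids fill any
    remainder.  ``disjoint=True`` additionally forbids one individual from
    entering both pools (used when founding the pools, where the pair
    orientation is arbitrary).  With ``strict=False`` an exhausted list
    returns short selections instead of raising (the caller supplies a
    fallback).
    """
    sel_a: list[int] = []
    sel_b: list[int] = []
    seen_a: set[int] = set()
    seen_b: set[int] = set()
    for a, b in zip(aside_ids, bside_ids):
        a, b = int(a), int(b)
        if a >= 0 and len(sel_a) < n_per_pool and a not in seen_a \
                and not (disjoint and a in seen_b):
            sel_a.append(a)
            seen_a.add(a)
        if b >= 0 and len(sel_b) < n_per_pool and b not in seen_b \
                and not (disjoint and b in seen_a):
            sel_b.append(b)
            seen_b.add(b)
        if len(sel_a) == n_per_pool and len(sel_b) == n_per_pool:
            return sel_a, sel_b
    if strict:
        raise RRSimError(
            f"could not recover {n_per_pool} unique parents per pool from the ranked hybrids"
        )
    return sel_a, sel_b


def _fill_from_ranked(sel: list[int], ranked_ids: np.ndarray, n: int) -> list[int]:
    seen = set(sel)
    for i in ranked_ids:
        if len(sel) == n:
            break
        i = int(i)
        if i not in seen:
            sel.append(i)
            seen.add(i)
    if len(sel) < n:
        raise RRSimError(f"pool has fewer than {n} candidate parents")
    return sel


def _gather_by_id(ids: list[int], pops: list[Population]) -> np.ndarray:
    lookup: dict[int, tuple[Population, int]] = {}
    for pop in pops:
        for row, pid in enumerate(pop.ids):
            lookup[int(pid)] = (pop, row)
    haps = np.stack([lookup[i][0].haplotypes[lookup[i][1]] for i in ids])
    return haps


def _new_parent_pool(
    ids: list[int], sources: list[Population], label: str, cycle: int
) -> Population:
    haps = _gather_by_id(ids, sources)
    n = len(ids)
    return Population(
        ids=np.asarray(ids, dtype=np.int64),
        haplotypes=haps,
        pool=np.full(n, label, dtype="<U4"),
        role=np.full(n, "parent", dtype="<U8"),
        generation=np.full(n, cycle, dtype=np.int32),
    )


def _pair_values(
    arch: TraitArchitecture,
    gq_row: np.ndarray,   # (n, q) female-line QTN genotypes in {-1, +1}
    gq_col: np.ndarray,   # (m, q) male-line QTN genotypes
) -> np.ndarray:
    """True total genetic values of all deduced F1s, as an (n, m) matrix."""
    a, d = arch.additive_effects, arch.dominance_effects
    add_row = gq_row.astype(np.float64) @ a
    add_col = gq_col.astype(np.float64) @ a
    dom = 0.5 * (d.sum() - (gq_row.astype(np.float64) * d) @ gq_col.astype(np.float64).T)
    return 0.5 * (add_row[:, None] + add_col[None, :]) + dom + arch.intercept


# ---------------------------------------------------------------------------
# base population and burn-in


def initialize_base_population(
    founders: Population,
    arch: TraitArchitecture,
    gmap: GenomeMap,
    rng: np.random.Generator,
    n_parents: int = 384,
    pool_parents: int = 10,
    n_testers: int = N_TESTERS,
) -> tuple[PoolState, PoolState]:
    """Build cycle-zero heterotic pools from the founder panel.

    Founders are phenotyped once; the best ``n_parents`` are crossed in all
    pairwise combinations in silico, the single crosses are phenotyped, and
    the ranked list supplies the best-and-unique female parents (pool A),
    male parents (pool B) and, from the very best hybrids, each pool's
    testers.
    """
    if len(founders) < n_parents:
        raise ConfigurationError("founder panel smaller than the requested base selection")
    phen_f = phenotype(genetic_values(arch, founders, gmap), arch.env_variance, rng)
    top = np.argsort(-phen_f, kind="stable")[:n_parents]
    sel = founders.subset(top)

    gq = sel.line_genotypes(gmap.qtn_indices)
    totals = _pair_values(arch, gq, gq)
    iu, ju = np.triu_indices(n_parents, k=1)
    true = totals[iu, ju]
    phen = phenotype(true, arch.env_variance, rng)

    order = np.argsort(-phen, kind="stable")
    mothers = sel.ids[iu[order]]
    fathers = sel.ids[ju[order]]
    ids_a, ids_b = _select_unique_parents(mothers, fathers, pool_parents,
                                          disjoint=True)

    def build_pool(ids: list[int], label: str) -> PoolState:
        parents = _new_parent_pool(ids, [sel], label, cycle=0)
        testers = parents.subset(np.arange(n_testers))
        testers.role[:] = "tester"
        return PoolState(label=label, parents=parents, testers=testers, cycle=0)

    return build_pool(ids_a, "A"), build_pool(ids_b, "B")


def run_burnin(
    pool_a: PoolState,
    pool_b: PoolState,
    arch: TraitArchitecture,
    gmap: GenomeMap,
    rng: np.random.Generator,
    size: str = "I",
    n_cycles: int = 3,
) -> tuple[PoolState, PoolState, TrainingSet, CycleData]:
    """Traditional RRS burn-in; the final hybrid set seeds the GS training set."""
    data = None
    for c in range(1, n_cycles + 1):
        last = c == n_cycles
        pool_a, pool_b, data = cycle_trad(
            pool_a, pool_b, arch, gmap, BREEDING_SIZES[size], rng,
            generation=c, want_marker_codes=last,
        )
    ts0 = TrainingSet(
        G=data.marker_G,
        T=data.marker_T,
        y=data.phenotypes.copy(),
        cycle_tags=np.zeros(len(data.phenotypes), dtype=np.int32),
    )
    return pool_a, pool_b, ts0, data


# ---------------------------------------------------------------------------
# one breeding cycle, phenotypic (TRAD / DRIFT / TRAD_UP)


def cycle_trad(
    pool_a: PoolState,
    pool_b: PoolState,
    arch: TraitArchitecture,
    gmap: GenomeMap,
    size: BreedingSize,
    rng: np.random.Generator,
    update_testers: bool = False,
    select_random: bool = False,
    generation: int = 0,
    want_marker_codes: bool = False,
) -> tuple[PoolState, PoolState, CycleData]:
    """One phenotypic RRS cycle (testcrossing to three reciprocal testers)."""
    L, P = size.lines, size.parents
    lines_a = derive_lines(pool_a.parents, L, gmap, rng, generation)
    lines_b = derive_lines(pool_b.parents, L, gmap, rng, generation)
    testers_a, testers_b = pool_a.testers, pool_b.testers
    nt = len(testers_b)

    q = gmap.qtn_indices
    gq_la = lines_a.line_genotypes(q)
    gq_lb = lines_b.line_genotypes(q)
    gq_ta = testers_a.line_genotypes(q)
    gq_tb = testers_b.line_genotypes(q)

    # block 1: pool-A lines (females) x pool-B testers; block 2: pool-A
    # testers (females) x pool-B lines.  Pool A is the female (CMS) side.
    true1 = _pair_values(arch, gq_la, gq_tb)           # (L, nt)
    true2 = _pair_values(arch, gq_ta, gq_lb).T         # (L, nt) line-major
    true = np.concatenate([true1.ravel(), true2.ravel()])
    phen = phenotype(true, arch.env_variance, rng)

    aside = np.concatenate([np.repeat(lines_a.ids, nt), np.tile(testers_a.ids, L)])
    bside = np.concatenate([np.tile(testers_b.ids, L), np.repeat(lines_b.ids, nt)])
    # only the line parent of a testcross re-enters its pool's cycling
    # population; the tester is an evaluation aid and is not recycled
    sentinel = np.full(L * nt, -1, dtype=np.int64)
    aside_cand = np.concatenate([np.repeat(lines_a.ids, nt), sentinel])
    bside_cand = np.concatenate([sentinel, np.repeat(lines_b.ids, nt)])

    if select_random:
        order = rng.permutation(true.size)
    else:
        order = np.argsort(-phen, kind="stable")
    ids_a, ids_b = _select_unique_parents(aside_cand[order], bside_cand[order], P)
    new_parents_a = _new_parent_pool(ids_a, [lines_a], "A", generation)
    new_parents_b = _new_parent_pool(ids_b, [lines_b], "B", generation)

    best = int(order[0])
    released = HybridRecord(
        mother_id=int(aside[best]), father_id=int(bside[best]),
        true_value=float(true[best]), phenotype=float(phen[best]),
    )

    if update_testers:
        # each pool's new testers: its parents of the three best hybrids of
        # this cycle (the same rule that seeded the cycle-zero testers)
        new_testers_a = _new_parent_pool(ids_a[:N_TESTERS], [lines_a, testers_a],
                                         "A", generation)
        new_testers_b = _new_parent_pool(ids_b[:N_TESTERS], [lines_b, testers_b],
                                         "B", generation)
        new_testers_a.role[:] = "tester"
        new_testers_b.role[:] = "tester"
    else:
        new_testers_a, new_testers_b = testers_a, testers_b

    marker_G = marker_T = None
    if want_marker_codes:
        s = gmap.snp_indices
        gs_la, gs_lb = lines_a.line_genotypes(s), lines_b.line_genotypes(s)
        gs_ta, gs_tb = testers_a.line_genotypes(s), testers_b.line_genotypes(s)
        rows1 = np.repeat(np.arange(L), nt)
        cols1 = np.tile(np.arange(nt), L)
        G1, T1 = hybrid_codes_from_lines(gs_la[rows1], gs_tb[cols1])
        G2, T2 = hybrid_codes_from_lines(gs_ta[cols1], gs_lb[rows1])
        marker_G = np.concatenate([G1, G2])
        marker_T = np.concatenate([T1, T2])

    data = CycleData(
        true_values=true, phenotypes=phen, predicted=None,
        aside_ids=aside, bside_ids=bside,
        lines_a=lines_a, lines_b=lines_b, released=released,
        marker_G=marker_G, marker_T=marker_T,
    )
    new_a = PoolState("A", new_parents_a, new_testers_a, lines_a, generation)
    new_b = PoolState("B", new_parents_b, new_testers_b, lines_b, generation)
    return new_a, new_b, data


# ---------------------------------------------------------------------------
# one breeding cycle, genomic (GS_A / GS_AD)


def cycle_gs(
    pool_a: PoolState,
    pool_b: PoolState,
    arch: TraitArchitecture,
    gmap: GenomeMap,
    size: BreedingSize,
    ts: TrainingSet,
    kernel: str,
    rng: np.random.Generator,
    generation: int = 0,
    gram_cache: GramCache | None = None,
    gpo_window: int = 3,
) -> tuple[PoolState, PoolState, TrainingSet, CycleData]:
    """One genomic RRS cycle: predict all L x L crosses, realize the top HO."""
    L, P, HO = size.lines, size.parents, size.hybrids_obtained
    lines_a = derive_lines(pool_a.parents, L, gmap, rng, generation)
    lines_b = derive_lines(pool_b.parents, L, gmap, rng, generation)

    s = gmap.snp_indices
    gs_a = lines_a.line_genotypes(s)
    gs_b = lines_b.line_genotypes(s)

    model = fit_rrblup(ts, model=kernel, gram_cache=gram_cache)
    pred = predict_hybrids(model, gs_a, gs_b)          # (L, L)
    flat = pred.ravel()
    # rank descending with random tie order (ties become common once the
    # panel loses variance within the pools)
    perm = rng.permutation(flat.size)
    top_local = np.argpartition(-flat[perm], HO - 1)[:HO]
    top_local = top_local[np.argsort(-flat[perm][top_local], kind="stable")]
    top = perm[top_local]
    ii, jj = np.unravel_index(top, pred.shape)

    q = gmap.qtn_indices
    gq_a = lines_a.line_genotypes(q)
    gq_b = lines_b.line_genotypes(q)
    true_grid = _pair_values(arch, gq_a, gq_b)         # all L x L, for accuracy
    true = true_grid[ii, jj]
    phen = phenotype(true, arch.env_variance, rng)
    predicted = flat[top]
    if np.std(true_grid) > 0 and np.std(pred) > 0:
        grid_accuracy = float(np.corrcoef(true_grid.ravel(), flat)[0, 1])
    else:
        grid_accuracy = float("nan")

    aside = lines_a.ids[ii]
    bside = lines_b.ids[jj]
    # prediction-ranked walk; if the realized set does not expose P unique
    # parents per pool (degenerate late-cycle predictions), fill with the
    # pool's remaining lines ranked by marginal predicted value
    ids_a, ids_b = _select_unique_parents(aside, bside, P, strict=False)
    if len(ids_a) < P:
        ids_a = _fill_from_ranked(ids_a, lines_a.ids[np.argsort(-pred.mean(axis=1), kind="stable")], P)
    if len(ids_b) < P:
        ids_b = _fill_from_ranked(ids_b, lines_b.ids[np.argsort(-pred.mean(axis=0), kind="stable")], P)
    new_parents_a = _new_parent_pool(ids_a, [lines_a], "A", generation)
    new_parents_b = _new_parent_pool(ids_b, [lines_b], "B", generation)

    released = HybridRecord(
        mother_id=int(aside[0]), father_id=int(bside[0]),
        true_value=float(true[0]), phenotype=float(phen[0]),
        predicted=float(predicted[0]),
    )

    Gh, Th = hybrid_codes_from_lines(gs_a[ii], gs_b[jj])
    ts_new = update_training_set_gpo(ts, Gh, Th, phen, generation, window=gpo_window)

    data = CycleData(
        true_values=true, phenotypes=phen, predicted=predicted,
        aside_ids=aside, bside_ids=bside,
        lines_a=lines_a, lines_b=lines_b, released=released,
        marker_G=Gh, marker_T=Th, grid_accuracy=grid_accuracy,
    )
    new_a = PoolState("A", new_parents_a, pool_a.testers, lines_a, generation)
    new_b = PoolState("B", new_parents_b, pool_b.testers, lines_b, generation)
    return new_a, new_b, ts_new, data


# ---------------------------------------------------------------------------
# experiment driver


def _stage_rng(master_seed: int, replicate: int, stage: int) -> np.random.Generator:
    """Hierarchical stream: master seed -> replicate -> stage substream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate, stage))
    )


_STAGE_MAP, _STAGE_FOUNDERS, _STAGE_TRAIT, _STAGE_BASE, _STAGE_BURNIN = range(5)


def _arm_stage(scheme: str, size: str) -> int:
    return 100 + 10 * SCHEMES.index(scheme) + list(BREEDING_SIZES).index(size)


@dataclass
class ReplicateState:
    """Shared cycle-zero state of one replicate (all arms start from it)."""

    gmap: GenomeMap
    arch: TraitArchitecture
    pool_a: PoolState
    pool_b: PoolState
    ts0: TrainingSet
    cycle0: CycleData


def build_replicate_state(cfg: SchemeConfig, replicate: int) -> ReplicateState:
    gmap = build_genome_map(cfg.genome, _stage_rng(cfg.master_seed, replicate, _STAGE_MAP))
    founders = simulate_founder_panel(
        gmap, cfg.genome.n_founders,
        _stage_rng(cfg.master_seed, replicate, _STAGE_FOUNDERS), config=cfg.genome,
    )
    arch = sample_effects(
        gmap.qtn_indices.size, cfg.mean_dd, cfg.var_dd,
        _stage_rng(cfg.master_seed, replicate, _STAGE_TRAIT),
    )
    arch = calibrate_trait(arch, founders, gmap, cfg.target_var_g, cfg.target_H2)
    pool_a, pool_b = initialize_base_population(
        founders, arch, gmap, _stage_rng(cfg.master_seed, replicate, _STAGE_BASE),
        n_parents=cfg.n_base_parents, pool_parents=cfg.n_pool_parents,
        n_testers=cfg.n_testers,
    )
    pool_a, pool_b, ts0, cycle0 = run_burnin(
        pool_a, pool_b, arch, gmap,
        _stage_rng(cfg.master_seed, replicate, _STAGE_BURNIN),
        size=cfg.burnin_size, n_cycles=cfg.burnin_cycles,
    )
    return ReplicateState(gmap, arch, pool_a, pool_b, ts0, cycle0)


def _metric_row(
    data: CycleData,
    arch: TraitArchitecture,
    gmap: GenomeMap,
    scheme: str,
    size: str,
    replicate: int,
    cycle: int,
) -> dict:
    mean_gv, best_gv = hybrid_summary(data.true_values)
    if scheme == "DRIFT_RRS" and cycle > 0:
        acc = prediction_accuracy(data.true_values, mode="drift")
    elif data.predicted is not None:
        acc = prediction_accuracy(data.true_values, data.predicted, mode="genomic")
    else:
        acc = prediction_accuracy(data.true_values, data.phenotypes, mode="phenotypic")
    return {
        "replicate": replicate, "cycle": cycle, "scheme": scheme, "size": size,
        "mean_hybrid_gv": mean_gv, "best_hybrid_gv": best_gv,
        "va_pool_A": additive_variance_pool(data.lines_a, arch, gmap),
        "va_pool_B": additive_variance_pool(data.lines_b, arch, gmap),
        "accuracy": acc,
        "fst": fst_between_pools(data.lines_a, data.lines_b, gmap.snp_indices),
    }


def _run_arm(
    state: ReplicateState,
    cfg: SchemeConfig,
    scheme: str,
    size_label: str,
    replicate: int,
) -> list[dict]:
    rng = _stage_rng(cfg.master_seed, replicate, _arm_stage(scheme, size_label))
    size = BREEDING_SIZES[size_label]
    pool_a, pool_b = state.pool_a.copy(), state.pool_b.copy()
    rows = [_metric_row(state.cycle0, state.arch, state.gmap, scheme, size_label,
                        replicate, cycle=0)]
    if scheme.startswith("GS"):
        ts = state.ts0.copy()
        cache = GramCache()
        kernel = "AD" if scheme == "GS_AD_RRS" else "A"
        for cycle in range(1, cfg.n_cycles + 1):
            pool_a, pool_b, ts, data = cycle_gs(
                pool_a, pool_b, state.arch, state.gmap, size, ts, kernel, rng,
                generation=cycle, gram_cache=cache, gpo_window=cfg.gpo_window,
            )
            rows.append(_metric_row(data, state.arch, state.gmap, scheme, size_label,
                                    replicate, cycle))
    else:
        for cycle in range(1, cfg.n_cycles + 1):
            pool_a, pool_b, data = cycle_trad(
                pool_a, pool_b, state.arch, state.gmap, size, rng,
                update_testers=(scheme == "TRAD_RRS_UP"),
                select_random=(scheme == "DRIFT_RRS"),
                generation=cycle,
            )
            rows.append(_metric_row(data, state.arch, state.gmap, scheme, size_label,
                                    replicate, cycle))
    return rows


def run_comparison(
    cfg: SchemeConfig,
    arms: list[tuple[str, str]],
) -> pd.DataFrame:
    """Run several scheme arms over shared replicates.

    Every arm of a replicate starts from the same founder panel, trait,
    base population and burn-in state and diverges only afterwards.
    Returns one tidy row per (replicate, arm, cycle) with all metrics;
    cycle 0 is the shared post-burn-in state.
    """
    for scheme, size in arms:
        if scheme not in SCHEMES or size not in BREEDING_SIZES:
            raise ConfigurationError(f"unknown arm ({scheme}, {size})")
    rows: list[dict] = []
    for rep in range(cfg.n_replicates):
        try:
            state = build_replicate_state(cfg, rep)
            for scheme, size in arms:
                rows.extend(_run_arm(state, cfg, scheme, size, rep))
        except RRSimError:
            logger.exception("replicate %d aborted", rep)
    return pd.DataFrame(rows)


def run_experiment(cfg: SchemeConfig) -> pd.DataFrame:
    """Run the configured scheme x size arm for all replicates."""
    return run_comparison(cfg, [(cfg.scheme, cfg.size)])
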