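"""Per-cycle population-genetic and accuracy metrics, and replicate summaries.

The comparison surfaces follow the simulated-breeding literature: mean and
best true hybrid genetic value of the field-evaluated set, true additive
variance within each heterotic pool (variance of breeding values at the
pool's current allele frequencies), selection/prediction accuracy, and the
fixation index between the pools computed on the genotyping panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import RRSimError
from .genome import GenomeMap
from .population import Population
from .trait import TraitArchitecture, allele_substitution_effects, breeding_values

METRIC_COLUMNS = (
    "mean_hybrid_gv", "best_hybrid_gv", "va_pool_A", "va_pool_B", "accuracy", "fst",
)

ACCURACY_MODES = ("genomic", "phenotypic", "drift")


def hybrid_summary(true_values: np.ndarray) -> tuple[float, float]:
    """Mean and maximum true total genetic value of a hybrid set."""
    v = np.asarray(true_values, dtype=float)
    if v.size == 0:
        raise RRSimError("empty hybrid set")
    return float(v.mean()), float(v.max())


def additive_variance_pool(
    lines: Population,
    arch: TraitArchitecture,
    gmap: GenomeMap,
) -> float:
    """True additive variance within a pool.

    Variance (over pool members) of breeding values computed with
    allele-substitution effects alpha = a + (q - p) d at the pool's current
    allele frequencies.
    """
    if len(lines) < 2:
        raise RRSimError("additive variance requires at least two individuals")
    alpha = allele_substitution_effects(arch, lines, gmap)
    bv = breeding_values(arch, lines, gmap, alpha=alpha)
    return float(np.var(bv))


def prediction_accuracy(
    true_values: np.ndarray,
    estimates: np.ndarray | None = None,
    mode: str = "genomic",
) -> float:
    """Pearson correlation of true values with their estimates.

    ``genomic`` correlates true values with genomic predictions,
    ``phenotypic`` with phenotypes; ``drift`` returns 0 by definition
    (selection is random, so no estimate is involved).  Zero variance in
    either vector makes the correlation undefined: recorded as NaN.
    """
    if mode not in ACCURACY_MODES:
        raise RRSimError(f"unknown accuracy mode {mode!r}")
    if mode == "drift":
        return 0.0
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.size < 3 or e.size != t.size:
        raise RRSimError("accuracy requires >= 3 hybrids with both quantities")
    if np.std(t) == 0.0 or np.std(e) == 0.0:
        return float("nan")
    return float(np.corrcoef(t, e)[0, 1])


def fst_between_pools(
    pool_a: Population,
    pool_b: Population,
    snp_sites: np.ndarray,
    method: str = "hudson",
) -> float:
    """Multi-locus fixation index between the two pools at the SNP panel.

    The default is the Hudson estimator combined across loci as a ratio of
    sums (low-bias multi-locus form); Weir-Cockerham theta is available as
    an option.  Loci monomorphic in both pools carry no information and are
    excluded; if every locus is, the index is undefined (NaN).  Small
    negative multi-locus estimates (no true divergence) are clipped to 0.
    """
    if len(pool_a) < 2 or len(pool_b) < 2:
        raise RRSimError("FST requires at least two individuals per pool")
    p1 = pool_a.allele_freq(snp_sites)
    p2 = pool_b.allele_freq(snp_sites)
    n1 = 2 * len(pool_a)
    n2 = 2 * len(pool_b)
    poly = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    if not poly.any():
        return float("nan")
    p1, p2 = p1[poly], p2[poly]
    if method == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif method == "weir-cockerham":
        # two-population Weir & Cockerham (1984) theta, haplotype-count form
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))  # = 2 * n1 n2 / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
        num, den = a, a + b
    else:
        raise RRSimError(f"unknown FST method {method!r}")
    total = float(den.sum())
    if total == 0.0:
        return float("nan")
    return float(min(max(num.sum() / total, 0.0), 1.0))


def aggregate_replicates(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation per scheme x size x cycle.

    A single replicate yields sd = 0 by convention.
    """
    metrics = [c for c in METRIC_COLUMNS if c in rows.columns]
    if not metrics:
        raise RRSimError("no metric columns found")
    grouped = rows.groupby(["scheme", "size", "cycle"])[metrics]
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    out.columns = [f"{m}_{stat}" for stat, m in out.columns]
    return out.reset_index()


def relative_gain(
    rows: pd.DataFrame,
    arm1: tuple[str, str],
    arm2: tuple[str, str],
    cycle: int,
    metric: str = "mean_hybrid_gv",
    baseline: str = "value",
) -> float:
    """Relative gain of arm1 over arm2 at a cycle, on replicate means.

    ``baseline='value'`` contrasts the cycle means directly,
    (m1 - m2) / m2; ``baseline='gain'`` contrasts gains from cycle 0,
    ((m1 - m0) - (m2 - m0)) / (m2 - m0).  Both arms must share the cycle
    grid (and, for 'gain', the cycle-0 state).
    """
    def arm_mean(arm: tuple[str, str], cyc: int) -> float:
        sel = rows[(rows["scheme"] == arm[0]) & (rows["size"] == arm[1]) & (rows["cycle"] == cyc)]
        if sel.empty:
            raise RRSimError(f"no rows for arm {arm} at cycle {cyc}")
        return float(sel[metric].mean())

    m1 = arm_mean(arm1, cycle)
    m2 = arm_mean(arm2, cycle)
    if baseline == "value":
        return (m1 - m2) / m2
    if baseline == "gain":
        m0 = arm_mean(arm2, 0)
        return ((m1 - m0) - (m2 - m0)) / (m2 - m0)
    raise RRSimError(f"unknown baseline {baseline!r}")
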