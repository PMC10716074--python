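"""Additive-dominance quantitative trait model.

Each causal locus (QTN) i carries an additive effect ``a_i`` drawn from a
gamma distribution (shape = scale = 1) with a random sign, and a dominance
effect ``d_i = |a_i| * delta_i`` where the dominance degree ``delta_i`` is
Gaussian.  With the default degree distribution N(0.22, 0.26) about a third
of loci show negative (opposite-direction) dominance and about 6% show
overdominance (delta > 1).

The true genetic value of an individual is

    G = sum_i a_i x_i + sum_i d_i h_i + intercept,

with centred dosage x in {-1, 0, +1} and heterozygosity indicator h in
{0, 1}.  A single rescaling constant applied to all a_i and d_i calibrates
the genetic variance of a reference population to a target (1 by default);
the intercept sets its mean to 0; the environmental variance implements a
target broad-sense heritability, Ve = VG (1 - H2) / H2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import CalibrationError, ConfigurationError, RRSimError
from .genome import GenomeMap
from .population import Population


@dataclass
class TraitArchitecture:
    additive_effects: np.ndarray     # a_i, after any rescaling
    dominance_degrees: np.ndarray    # delta_i (scale-free)
    dominance_effects: np.ndarray    # d_i = |a_i| * delta_i, same scaling
    scaling_constant: float = 1.0
    intercept: float = 0.0
    env_variance: float = np.nan

    @property
    def n_qtn(self) -> int:
        return self.additive_effects.size


@dataclass
class GeneticValues:
    additive: np.ndarray     # sum_i a_i x_i
    dominance: np.ndarray    # sum_i d_i h_i
    total: np.ndarray        # additive + dominance + intercept


def sample_effects(
    n_qtn: int,
    mean_dd: float = 0.22,
    var_dd: float = 0.26,
    rng: np.random.Generator | int | None = None,
) -> TraitArchitecture:
    """Draw uncalibrated QTN effects.

    a_i ~ Gamma(1, 1) with a uniform random sign (bidirectional trait);
    delta_i ~ N(mean_dd, var_dd); d_i = |a_i| * delta_i.
    """
    if n_qtn < 1:
        raise ConfigurationError("need at least one QTN")
    if var_dd <= 0:
        raise ConfigurationError("dominance-degree variance must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = rng.gamma(shape=1.0, scale=1.0, size=n_qtn) * rng.choice([-1.0, 1.0], size=n_qtn)
    delta = rng.normal(mean_dd, np.sqrt(var_dd), size=n_qtn)
    return TraitArchitecture(
        additive_effects=a,
        dominance_degrees=delta,
        dominance_effects=np.abs(a) * delta,
    )


def genetic_values(
    arch: TraitArchitecture,
    individuals: Population | np.ndarray,
    gmap: GenomeMap,
) -> GeneticValues:
    """True genetic values; accepts a Population or a (n, 2, m) array."""
    if isinstance(individuals, Population):
        haps = individuals.haplotypes
    else:
        haps = np.asarray(individuals)
    if haps.shape[-1] != gmap.n_sites:
        raise RRSimError("haplotypes do not conform to the genome map")
    q = gmap.qtn_indices
    h = haps[..., q]
    x = (h.sum(axis=-2, dtype=np.int16) - 1).astype(np.float64)   # {-1, 0, +1}
    het = (h[..., 0, :] != h[..., 1, :]).astype(np.float64)
    add = x @ arch.additive_effects
    dom = het @ arch.dominance_effects
    return GeneticValues(additive=add, dominance=dom, total=add + dom + arch.intercept)


def calibrate_trait(
    arch: TraitArchitecture,
    reference: Population,
    gmap: GenomeMap,
    target_var_g: float = 1.0,
    target_H2: float = 0.53,
) -> TraitArchitecture:
    """Rescale effects so the reference population has the target variance.

    One common constant multiplies every a_i and d_i (preserving all
    dominance degrees) such that Var(G) over the reference equals
    ``target_var_g`` exactly; the intercept zeroes the reference mean; the
    environmental variance is set from the broad-sense heritability target.
    """
    if len(reference) == 0:
        raise CalibrationError("reference population is empty")
    if not (0 < target_H2 < 1):
        raise ConfigurationError("target_H2 must be in (0, 1)")
    base = replace(arch, scaling_constant=1.0, intercept=0.0)
    raw = genetic_values(base, reference, gmap)
    var_raw = float(np.var(raw.total))
    scale = max(1.0, float(np.mean(raw.total)) ** 2)
    if var_raw <= 1e-24 * scale:
        raise CalibrationError("zero genetic variance in the reference population")
    c = float(np.sqrt(target_var_g / var_raw))
    intercept = -c * float(np.mean(raw.total))
    ve = target_var_g * (1.0 - target_H2) / target_H2
    return TraitArchitecture(
        additive_effects=arch.additive_effects * c,
        dominance_degrees=arch.dominance_degrees.copy(),
        dominance_effects=arch.dominance_effects * c,
        scaling_constant=c,
        intercept=intercept,
        env_variance=ve,
    )


def allele_substitution_effects(
    arch: TraitArchitecture,
    pool: Population,
    gmap: GenomeMap,
) -> np.ndarray:
    """Average allele-substitution effects alpha_i = a_i + (q_i - p_i) d_i.

    Allele frequencies p (of the 1-allele) are computed within the given
    pool, so alpha is a property of the pool, not of the trait alone.
    """
    if len(pool) == 0:
        raise RRSimError("cannot compute substitution effects for an empty pool")
    p = pool.allele_freq(gmap.qtn_indices)
    return arch.additive_effects + (1.0 - 2.0 * p) * arch.dominance_effects


def breeding_values(
    arch: TraitArchitecture,
    individuals: Population,
    gmap: GenomeMap,
    alpha: np.ndarray | None = None,
) -> np.ndarray:
    """Breeding values sum_i alpha_i x_i at the population's own frequencies."""
    if alpha is None:
        alpha = allele_substitution_effects(arch, individuals, gmap)
    x = individuals.centered_dosage(gmap.qtn_indices).astype(np.float64)
    return x @ alpha


def phenotype(
    values: GeneticValues | np.ndarray,
    env_variance: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """True value plus i.i.d. Gaussian error with variance ``env_variance``.

    Errors are redrawn independently at every phenotyping event; there is
    no permanent environmental effect.
    """
    if env_variance < 0:
        raise ConfigurationError("environmental variance must be non-negative")
    total = values.total if isinstance(values, GeneticValues) else np.asarray(values, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return total + rng.normal(0.0, np.sqrt(env_variance), size=total.shape)
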