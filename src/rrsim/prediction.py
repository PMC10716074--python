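"""RR-BLUP marker-effect estimation and single-cross hybrid prediction.

The training set holds hybrids genotyped at the SNP panel in additive
coding {aa, Aa, AA} = {-1, 0, +1} (matrix G) and dominance coding
{0, 1, 0} (matrix T), with one phenotype per hybrid.  The additive model

    y = G u + e,   u ~ N(0, I su2),   e ~ N(0, I se2)

is solved by ridge regression, u_hat = (G'G + lambda I)^-1 G'y with
lambda = se2 / su2; phenotypes are centred on the training mean (the only
fixed effect).  The additive + dominance model adds T d with its own ridge
parameter lambda_d = se2 / sd2 and solves the joint two-block mixed-model
equations, which reduce to the two separate one-kernel ridge solutions
exactly when G'T = 0.

Variance ratios are estimated by a REML-type profile likelihood over the
marker-to-residual variance ratio, evaluated from one eigendecomposition
of G'G (and of T'T for the dominance kernel) per fit.  Because every
quantity the profile needs (eigenvalues, G'y, y'y) is a sum over training
hybrids, per-cycle cross-product blocks are cached and reused as the
sliding training window advances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .exceptions import FittingError, RRSimError
from .population import Population

GPO_WINDOW = 3  # training window, in breeding cycles (grandparents/parents/offspring)


# ---------------------------------------------------------------------------
# genotype coding


def code_genotypes(
    individuals: Population | np.ndarray,
    snp_sites: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive (G) and dominance (T) marker codes at the SNP panel.

    G in {-1, 0, +1}; T = 1 exactly at heterozygous markers.
    """
    haps = individuals.haplotypes if isinstance(individuals, Population) else np.asarray(individuals)
    h = haps[..., snp_sites]
    G = (h.sum(axis=-2, dtype=np.int16) - 1).astype(np.int8)
    T = (h[..., 0, :] != h[..., 1, :]).astype(np.int8)
    return G, T


def hybrid_codes_from_lines(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deduce F1 marker codes from parental line genotypes in {-1, +1}.

    The F1 additive code is the parental mean; the F1 is heterozygous
    exactly where the parents differ.
    """
    G = ((ga + gb) // 2).astype(np.int8)
    T = (ga != gb).astype(np.int8)
    return G, T


# ---------------------------------------------------------------------------
# training set


@dataclass
class TrainingSet:
    """Hybrid marker genotypes, phenotypes and their cycle tags."""

    G: np.ndarray            # (n, p) int8
    T: np.ndarray            # (n, p) int8
    y: np.ndarray            # (n,) float
    cycle_tags: np.ndarray   # (n,) int32

    def __post_init__(self) -> None:
        n = self.y.size
        if self.G.shape[0] != n or self.T.shape[0] != n or self.cycle_tags.size != n:
            raise RRSimError("training-set arrays have inconsistent lengths")

    def __len__(self) -> int:
        return self.y.size

    @property
    def n_markers(self) -> int:
        return self.G.shape[1]

    @property
    def tags(self) -> np.ndarray:
        return np.unique(self.cycle_tags)

    def copy(self) -> "TrainingSet":
        return TrainingSet(self.G.copy(), self.T.copy(), self.y.copy(), self.cycle_tags.copy())


def update_training_set_gpo(
    ts: TrainingSet,
    G_new: np.ndarray,
    T_new: np.ndarray,
    y_new: np.ndarray,
    cycle: int,
    window: int = GPO_WINDOW,
) -> TrainingSet:
    """Append the newest hybrid data and keep only the last ``window`` cycles."""
    G = np.concatenate([ts.G, G_new.astype(np.int8)])
    T = np.concatenate([ts.T, T_new.astype(np.int8)])
    y = np.concatenate([ts.y, np.asarray(y_new, dtype=float)])
    tags = np.concatenate([ts.cycle_tags, np.full(len(y_new), cycle, dtype=np.int32)])
    keep_tags = np.unique(tags)[-window:]
    keep = np.isin(tags, keep_tags)
    return TrainingSet(G[keep], T[keep], y[keep], tags[keep])


# ---------------------------------------------------------------------------
# cross-product caching (sums over training hybrids, one block per cycle tag)


@dataclass
class _GramBlock:
    n: int
    sum_y: float
    yty: float
    Gty: np.ndarray
    G1: np.ndarray       # column sums of G
    GtG: np.ndarray
    Tty: np.ndarray | None = None
    T1: np.ndarray | None = None
    TtT: np.ndarray | None = None
    GtT: np.ndarray | None = None


def _block(G: np.ndarray, T: np.ndarray, y: np.ndarray, dominance: bool) -> _GramBlock:
    Gf = G.astype(np.float32)
    blk = _GramBlock(
        n=y.size,
        sum_y=float(y.sum()),
        yty=float(y @ y),
        Gty=Gf.T.astype(np.float64) @ y,
        G1=Gf.sum(axis=0).astype(np.float64),
        GtG=(Gf.T @ Gf).astype(np.float64),  # entries are integer counts: exact in float32
    )
    if dominance:
        Tf = T.astype(np.float32)
        blk.Tty = Tf.T.astype(np.float64) @ y
        blk.T1 = Tf.sum(axis=0).astype(np.float64)
        blk.TtT = (Tf.T @ Tf).astype(np.float64)
        blk.GtT = (Gf.T @ Tf).astype(np.float64)
    return blk


@dataclass
class GramCache:
    """Per-cycle-tag cross-product blocks for sliding-window refits."""

    blocks: dict[int, _GramBlock] = field(default_factory=dict)

    def get(self, ts: TrainingSet, dominance: bool) -> list[_GramBlock]:
        out = []
        for tag in ts.tags:
            blk = self.blocks.get(int(tag))
            sel = ts.cycle_tags == tag
            if blk is None or (dominance and blk.TtT is None) or blk.n != int(sel.sum()):
                blk = _block(ts.G[sel], ts.T[sel], ts.y[sel], dominance)
                self.blocks[int(tag)] = blk
            out.append(blk)
        # drop stale tags
        live = set(int(t) for t in ts.tags)
        for tag in list(self.blocks):
            if tag not in live:
                del self.blocks[tag]
        return out


# ---------------------------------------------------------------------------
# model


@dataclass
class MarkerEffectsModel:
    u: np.ndarray                # additive marker effects
    d: np.ndarray                # dominance marker effects (zeros for model "A")
    ridge_lambda: float          # se2 / su2
    ridge_lambda_d: float        # se2 / sd2 (nan for model "A")
    train_mean: float
    model: str                   # "A" or "AD"

    def predict(self, G: np.ndarray, T: np.ndarray | None = None) -> np.ndarray:
        pred = self.train_mean + G.astype(np.float64) @ self.u
        if self.model == "AD" and T is not None:
            pred = pred + T.astype(np.float64) @ self.d
        return pred


def _profile_ratio(eigvals: np.ndarray, vty: np.ndarray, yty_c: float, n: int) -> tuple[float, float]:
    """Maximise the profile restricted likelihood over gamma = su2/se2.

    ``eigvals`` are the eigenvalues of Z'Z, ``vty`` = V' Z' y_c.  Returns
    (gamma_hat, se2_hat).  The n-1 degrees of freedom account for the
    intercept absorbed by centring.
    """
    pos = eigvals > max(eigvals.max(), 1.0) * 1e-10
    lam = eigvals[pos]
    ytilde2 = (vty[pos] ** 2) / lam          # squared data projections in the kernel basis
    s0 = max(yty_c - ytilde2.sum(), 0.0)     # mass in the kernel's null space
    dof = n - 1

    def neg_restricted_ll(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        w = g * lam + 1.0
        sigma2 = (np.sum(ytilde2 / w) + s0) / dof
        return dof * np.log(sigma2) + np.sum(np.log(w))

    res = minimize_scalar(neg_restricted_ll, bounds=(-16.0, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    gamma = float(np.exp(res.x))
    w = gamma * lam + 1.0
    se2 = float((np.sum(ytilde2 / w) + s0) / dof)
    return gamma, se2


def _kernel_ratio(ZtZ: np.ndarray, Zty: np.ndarray, yty_c: float, n: int) -> tuple[float, float]:
    eigvals, V = scipy.linalg.eigh(ZtZ)
    if eigvals.max() <= 0:
        raise FittingError("marker kernel is identically zero (monomorphic panel?)")
    return _profile_ratio(eigvals, V.T @ Zty, yty_c, n)


def fit_rrblup(
    ts: TrainingSet,
    model: str = "A",
    ridge_lambda: float | None = None,
    ridge_lambda_d: float | None = None,
    gram_cache: GramCache | None = None,
) -> MarkerEffectsModel:
    """Estimate marker effects by RR-BLUP.

    ``model`` is "A" (additive) or "AD" (additive + dominance).  Ridge
    parameters are estimated by the REML-type profile unless given
    explicitly (fixed-lambda debug mode used by the oracle tests).
    """
    if model not in ("A", "AD"):
        raise RRSimError(f"unknown model {model!r}")
    n = len(ts)
    if n < 2:
        raise FittingError("need at least two training hybrids")
    p = ts.n_markers
    dominance = model == "AD"

    cache = gram_cache if gram_cache is not None else GramCache()
    blocks = cache.get(ts, dominance)
    ybar = sum(b.sum_y for b in blocks) / n
    yty_c = sum(b.yty for b in blocks) - n * ybar**2
    GtG = sum(b.GtG for b in blocks)
    Gty_c = sum(b.Gty for b in blocks) - ybar * sum(b.G1 for b in blocks)

    if ridge_lambda is None:
        gamma, _ = _kernel_ratio(GtG, Gty_c, yty_c, n)
        lam = 1.0 / gamma
    else:
        lam = float(ridge_lambda)
        if lam <= 0:
            raise FittingError("ridge_lambda must be positive")

    if not dominance:
        u = scipy.linalg.solve(GtG + lam * np.eye(p), Gty_c, assume_a="pos")
        return MarkerEffectsModel(u, np.zeros(p), lam, np.nan, ybar, "A")

    TtT = sum(b.TtT for b in blocks)
    GtT = sum(b.GtT for b in blocks)
    Tty_c = sum(b.Tty for b in blocks) - ybar * sum(b.T1 for b in blocks)
    if ridge_lambda_d is None:
        if TtT.max() <= 0:
            raise FittingError("dominance kernel is identically zero")
        gamma_d, _ = _kernel_ratio(TtT, Tty_c, yty_c, n)
        lam_d = 1.0 / gamma_d
    else:
        lam_d = float(ridge_lambda_d)
        if lam_d <= 0:
            raise FittingError("ridge_lambda_d must be positive")

    lhs = np.block([[GtG + lam * np.eye(p), GtT],
                    [GtT.T, TtT + lam_d * np.eye(p)]])
    rhs = np.concatenate([Gty_c, Tty_c])
    sol = scipy.linalg.solve(lhs, rhs, assume_a="pos")
    return MarkerEffectsModel(sol[:p], sol[p:], lam, lam_d, ybar, "AD")


def predict_hybrids(
    model: MarkerEffectsModel,
    lines_a: Population | np.ndarray,
    lines_b: Population | np.ndarray,
    snp_sites: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted total genetic values of all A x B single crosses.

    ``lines_a`` / ``lines_b`` are fully inbred Populations (with
    ``snp_sites`` giving the panel) or pre-extracted line genotype matrices
    in {-1, +1}.  Returns an (L_A, L_B) matrix; entry (i, j) is the
    prediction for the F1 of A-line i (female) and B-line j (male), using
    marker genotypes deduced from the parents.
    """
    ga = lines_a.line_genotypes(snp_sites) if isinstance(lines_a, Population) else np.asarray(lines_a)
    gb = lines_b.line_genotypes(snp_sites) if isinstance(lines_b, Population) else np.asarray(lines_b)
    ga = ga.astype(np.float64)
    gb = gb.astype(np.float64)
    # F1 additive code = (ga + gb)/2; dominance indicator = (1 - ga*gb)/2
    add = 0.5 * ((ga @ model.u)[:, None] + (gb @ model.u)[None, :])
    pred = model.train_mean + add
    if model.model == "AD":
        pred = pred + 0.5 * (model.d.sum() - (ga * model.d) @ gb.T)
    return pred
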