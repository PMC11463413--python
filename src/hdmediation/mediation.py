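"""High-dimensional mediation: composite genome/transcriptome/phenome scores.

The model projects three kernel matrices onto one-dimensional individual-level
scores — a composite genome score G_C, a composite transcriptome score T_C,
and a composite phenome score P_C — chosen to maximize the mediated path
rho(G_C, T_C) * rho(T_C, P_C) subject to the perfect-mediation constraint that
the genome and phenome scores are uncorrelated given the transcriptome score:
rho(G_C, P_C | T_C) = 0.

Each modality is represented by its top-rank kernel eigencomponents (factor
scores F = U sqrt(S)). The fit alternates between (i) setting the genome and
phenome scores to the projections of the current transcriptome score into
their factor spaces (each maximizing its correlation with T_C) and (ii)
updating the transcriptome score by exact maximization of the path product
within span{S^-1 a, S^-1 c}, where all stationary points of the objective lie;
this reduces to a 2x2 generalized symmetric eigenproblem. At convergence the
mediation constraint is enforced exactly by removing from P_C its projection
onto the component of G_C orthogonal to T_C.

Loadings are Pearson correlations of each measured variable with the relevant
composite score; transcript loadings are additionally z-standardized within
tissue to support standard-deviation-based selection of top mediators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .data_io import OmicsMatrix
from .kernels import KernelMatrix, concat_tissues, genome_kernel, linear_kernel

__all__ = [
    "HdmaFit",
    "LoadingVector",
    "HighDimensionalMediation",
    "fit_hdma",
    "path_coefficient",
    "partial_correlation",
    "variable_loadings",
    "variance_explained",
    "marker_set_test",
]


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def path_coefficient(g, t, p) -> float:
    """Strength of the mediated path: rho(g, t) * rho(t, p)."""
    g, t, p = (np.asarray(v, dtype=float) for v in (g, t, p))
    if not (len(g) == len(t) == len(p)):
        raise ValueError("score vectors must have equal length")
    if len(g) < 3:
        raise ValueError("need at least 3 observations")
    return _pearson(g, t) * _pearson(t, p)


def partial_correlation(x, y, z) -> float:
    """Pearson correlation of the residuals of x and y on [1, z]."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("vectors must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    X = np.column_stack([np.ones(len(z)), z])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if np.linalg.norm(rx) < 1e-12 * max(1.0, np.linalg.norm(x)):
        raise ValueError("x lies in the span of [1, z]; partial correlation undefined")
    if np.linalg.norm(ry) < 1e-12 * max(1.0, np.linalg.norm(y)):
        raise ValueError("y lies in the span of [1, z]; partial correlation undefined")
    return float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))


def _standardize(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant score")
    return (v - v.mean()) / sd


@dataclass
class HdmaFit:
    """Fitted composite scores and the mediated-path decomposition."""

    individual_ids: list
    G_C: np.ndarray
    T_C: np.ndarray
    P_C: np.ndarray
    path_coefficient: float
    rho_gt: float
    rho_tp: float
    rho_gp_given_t: float
    n_iterations: int
    converged: bool
    ranks: dict = field(default_factory=dict)
    seed: int = 0

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"G_C": self.G_C, "T_C": self.T_C, "P_C": self.P_C}, index=self.individual_ids
        )

    def summary(self) -> dict:
        return {
            "path_coefficient": self.path_coefficient,
            "rho_gt": self.rho_gt,
            "rho_tp": self.rho_tp,
            "rho_gp_given_t": self.rho_gp_given_t,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "ranks": self.ranks,
            "seed": self.seed,
        }


@dataclass
class LoadingVector:
    """Per-feature loadings (correlations with a composite score)."""

    table: pd.DataFrame  # index feature_id; columns tissue, loading, z_loading, constant

    @property
    def feature_ids(self) -> list:
        return list(self.table.index)

    @property
    def loadings(self) -> pd.Series:
        return self.table["loading"]

    @property
    def z_loadings(self) -> pd.Series:
        return self.table["z_loading"]


def _factor_scores(kernel: KernelMatrix, rank=None, psd_tol: float = 1e-8):
    """Top-rank eigencomponents F = U sqrt(S) of a centered kernel.

    Default rank: smallest rank capturing 95% of the kernel trace, capped at
    n/2 — a guard against the overfitting that unregularized CCA-style
    projections are prone to in high dimensions.
    """
    K = kernel.K
    w, U = np.linalg.eigh(K)
    w, U = w[::-1], U[:, ::-1]
    if w[0] <= 0:
        raise ValueError(f"{kernel.modality} kernel has no positive eigenvalues")
    if w[-1] < -psd_tol * w[0] * max(1.0, K.shape[0]):
        raise ValueError(
            f"{kernel.modality} kernel is not PSD (min eigenvalue {w[-1]:.3g})"
        )
    pos = w > 1e-10 * w[0]
    w, U = w[pos], U[:, pos]
    if rank is None:
        cum = np.cumsum(w) / np.sum(w)
        r = int(np.searchsorted(cum, 0.95) + 1)
        r = min(r, max(1, K.shape[0] // 2))
    else:
        r = int(rank)
    r = max(1, min(r, len(w)))
    w, U = w[:r], U[:, :r]
    # deterministic eigenvector orientation: largest-magnitude entry positive
    anchor = np.argmax(np.abs(U), axis=0)
    U = U * np.sign(U[anchor, np.arange(r)])
    return U * np.sqrt(w), w


def _project(F, evals, v):
    """Orthogonal projection of v onto the column span of F (F'F = diag(evals))."""
    return F @ ((F.T @ v) / evals)


def _t_update(F_T, wT, g, p):
    """Exact maximizer of rho(g, t) * rho(t, p) over t in the span of F_T.

    With unit-norm centered g, p and t = F_T b, the objective is
    (a'b)(c'b) / (b' S b) with a = F_T' g, c = F_T' p; every stationary point
    satisfies S b in span{a, c}, so the optimum lies in span{S^-1 a, S^-1 c}
    and reduces to a 2x2 generalized eigenproblem.
    """
    a = F_T.T @ g
    c = F_T.T @ p
    x1 = a / wT
    x2 = c / wT
    X = np.column_stack([x1, x2])
    u = X.T @ a
    v = X.T @ c
    A = 0.5 * (np.outer(u, v) + np.outer(v, u))
    B = X.T @ (X * wT[:, None])
    # collinear directions (g and p already aligned in T-space): 1-D subproblem
    if np.linalg.det(B) < 1e-14 * max(B[0, 0] * B[1, 1], 1e-300):
        b = x1 if B[0, 0] >= B[1, 1] else x2
        return F_T @ b
    evals, evecs = linalg.eigh(A, B)
    z = evecs[:, np.argmax(evals)]
    return F_T @ (X @ z)


def fit_hdma(K_G, K_T, K_P, rank=None, tol: float = 1e-8, max_iter: int = 500, seed: int = 0):
    """Fit the high-dimensional mediation model on three kernel matrices.

    Returns an :class:`HdmaFit` whose scores have zero mean, unit variance,
    and satisfy rho(G_C, P_C | T_C) = 0 exactly (enforced by projection).
    The algorithm is deterministic; ``seed`` is recorded for provenance.
    """
    if not (K_G.individual_ids == K_T.individual_ids == K_P.individual_ids):
        raise ValueError("kernels must share the same individuals in the same order")
    F_G, wG = _factor_scores(K_G, rank)
    F_T, wT = _factor_scores(K_T, rank)
    F_P, wP = _factor_scores(K_P, rank)
    return _fit_from_factors(
        F_G, wG, F_T, wT, F_P, wP,
        individual_ids=list(K_G.individual_ids), tol=tol, max_iter=max_iter, seed=seed,
    )


def _fit_from_factors(F_G, wG, F_T, wT, F_P, wP, individual_ids, tol, max_iter, seed=0):
    t = F_T[:, 0].copy()
    prev = np.inf
    path = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        t = t / np.linalg.norm(t)
        g = _project(F_G, wG, t)
        p = _project(F_P, wP, t)
        gn = np.linalg.norm(g)
        pn = np.linalg.norm(p)
        if gn < 1e-12 or pn < 1e-12:
            warnings.warn("transcriptome score orthogonal to a factor space; fit degenerate")
            break
        t = _t_update(F_T, wT, g / gn, p / pn)
        path = path_coefficient(g, t, p)
        if np.isfinite(prev) and abs(path - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = path

    # refresh g and p against the final transcriptome score
    t = t / np.linalg.norm(t)
    g = _project(F_G, wG, t)
    p = _project(F_P, wP, t)
    g, t, p = _standardize(g), _standardize(t), _standardize(p)

    # enforce perfect mediation: remove from p the part of g orthogonal to t
    g_perp = g - (g @ t / (t @ t)) * t
    g_perp -= g_perp.mean()
    vpp = g_perp @ g_perp
    if vpp > 1e-12:
        p = p - (p @ g_perp / vpp) * g_perp
    g, t, p = _standardize(g), _standardize(t), _standardize(p)

    rho_gt = _pearson(g, t)
    rho_tp = _pearson(t, p)
    if rho_tp < 0:  # joint flip of (G_C, T_C): path invariant, rho_tp >= 0
        g, t = -g, -t
        rho_gt, rho_tp = _pearson(g, t), _pearson(t, p)
    try:
        rho_gp_t = partial_correlation(g, p, t)
    except ValueError:
        # a score collinear with T_C leaves nothing to correlate: mediation
        # is trivially perfect
        rho_gp_t = 0.0

    return HdmaFit(
        individual_ids=individual_ids,
        G_C=g,
        T_C=t,
        P_C=p,
        path_coefficient=rho_gt * rho_tp,
        rho_gt=rho_gt,
        rho_tp=rho_tp,
        rho_gp_given_t=rho_gp_t,
        n_iterations=n_iter,
        converged=converged,
        ranks={"genome": F_G.shape[1], "transcriptome": F_T.shape[1], "phenome": F_P.shape[1]},
        seed=seed,
    )


def variable_loadings(features: OmicsMatrix, score) -> LoadingVector:
    """Loadings: Pearson correlation of each feature with a composite score.

    Constant features get loading 0 and are flagged. z-loadings are
    standardized within tissue (tissue taken from annotations, else from a
    ``tissue:`` feature-id prefix, else one global group).
    """
    score = np.asarray(score, dtype=float)
    X = features.array
    if X.shape[0] != len(score):
        raise ValueError("score length does not match individuals")
    sc = score - score.mean()
    s_norm = np.linalg.norm(sc)
    if s_norm == 0:
        raise ValueError("constant score")
    constant = np.ptp(X, axis=0) == 0
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        load = (Xc.T @ sc) / (norms * s_norm)
    load[constant] = 0.0

    tissues = _feature_tissues(features)
    table = pd.DataFrame(
        {"tissue": tissues, "loading": load, "constant": constant},
        index=pd.Index(features.feature_ids, name="feature_id"),
    )
    z = np.full(len(table), np.nan)
    for _, grp in table.groupby("tissue", sort=False):
        vals = grp["loading"].to_numpy()
        sd = vals.std()
        z[table.index.get_indexer(grp.index)] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    table["z_loading"] = z
    return LoadingVector(table=table)


def _feature_tissues(features: OmicsMatrix):
    ann = features.feature_annotations
    if ann is not None and "tissue" in ann.columns:
        return [
            str(ann["tissue"].get(f, "all")) if f in ann.index else "all"
            for f in features.feature_ids
        ]
    out = []
    for f in features.feature_ids:
        name = str(f)
        out.append(name.split(":", 1)[0] if ":" in name else "all")
    return out


def variance_explained(score, traits: OmicsMatrix) -> float:
    """Mean over traits of the squared correlation between trait and score."""
    score = np.asarray(score, dtype=float)
    r2 = []
    for trait in traits.feature_ids:
        y = traits.values[trait].to_numpy(dtype=float)
        if y.std() == 0:
            warnings.warn(f"constant trait {trait!r} excluded from variance explained")
            continue
        r2.append(_pearson(score, y) ** 2)
    if not r2:
        raise ValueError("no non-constant traits")
    return float(np.mean(r2))


def marker_set_test(loadings: LoadingVector, marker_ids, n_perm: int = 999, seed: int = 0):
    """Mean loading of a feature set against same-size random draws.

    Two-sided empirical p-value: p = (1 + #{|null mean| >= |observed mean|})
    / (n_perm + 1), with the null built from ``n_perm`` random same-size
    subsets of all features (matching the cell-type marker test design).
    """
    marker_ids = list(marker_ids)
    if not marker_ids:
        raise ValueError("empty marker set")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    all_ids = loadings.feature_ids
    missing = set(marker_ids) - set(all_ids)
    if missing:
        raise ValueError(f"marker ids not in loadings: {sorted(missing)[:5]}")
    values = loadings.loadings
    observed = float(values.loc[marker_ids].mean())
    pool = values.to_numpy()
    k = len(marker_ids)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pool[rng.choice(len(pool), size=k, replace=False)].mean()
    # small tolerance so draws equal to the observed set (up to float
    # summation order) count as ties
    p = (1 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1)
    return observed, float(p)


class HighDimensionalMediation(BaseEstimator):
    """Kernel-based high-dimensional mediation of genome -> transcriptome -> phenome.

    Fits composite scores G_C, T_C, P_C maximizing the mediated path
    rho(G_C, T_C) * rho(T_C, P_C) under the perfect-mediation constraint
    rho(G_C, P_C | T_C) = 0, then derives loadings for transcripts and traits.

    Parameters
    ----------
    rank : int or None
        Number of kernel eigencomponents per modality. ``None`` selects the
        smallest rank capturing 95% of each kernel's trace, capped at n/2.
    tol : float
        Relative convergence tolerance on the path coefficient.
    max_iter : int
        Maximum alternating iterations.
    random_state : int
        Recorded seed; the fit itself is deterministic.

    Attributes
    ----------
    scores_ : DataFrame with columns G_C, T_C, P_C indexed by individual.
    path_coefficient_, rho_gt_, rho_tp_, rho_gp_given_t_ : floats.
    transcript_loadings_, trait_loadings_ : LoadingVector (when matrices,
        not pre-built kernels, were supplied to :meth:`fit`).
    variance_explained_ : mean squared trait correlation of P_C.
    n_iter_, converged_ : fit diagnostics.
    """

    def __init__(self, rank=None, tol=1e-8, max_iter=500, random_state=0):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, genomes, transcriptome, phenotypes):
        """Fit from kernels or raw modalities.

        ``genomes`` may be a HaplotypeDosages or a pre-built KernelMatrix;
        ``transcriptome`` an OmicsMatrix, a list of per-tissue OmicsMatrix,
        or a KernelMatrix; ``phenotypes`` an OmicsMatrix or KernelMatrix.
        """
        K_G = genomes if isinstance(genomes, KernelMatrix) else genome_kernel(genomes)
        if isinstance(transcriptome, (list, tuple)):
            transcriptome = concat_tissues(transcriptome)
        if isinstance(transcriptome, KernelMatrix):
            K_T, expr = transcriptome, None
        else:
            expr = transcriptome
            K_T = linear_kernel(transcriptome, modality="transcriptome")
        if isinstance(phenotypes, KernelMatrix):
            K_P, traits = phenotypes, None
        else:
            traits = phenotypes
            K_P = linear_kernel(phenotypes, modality="phenome")

        fit = fit_hdma(
            K_G, K_T, K_P,
            rank=self.rank, tol=self.tol, max_iter=self.max_iter, seed=self.random_state,
        )
        if traits is not None:
            # anchor: the trait with the largest |loading| loads positively
            lv = variable_loadings(traits, fit.P_C)
            top = lv.loadings.abs().idxmax()
            if lv.loadings.loc[top] < 0:  # joint flip preserves all correlations
                fit.G_C, fit.T_C, fit.P_C = -fit.G_C, -fit.T_C, -fit.P_C
            self.trait_loadings_ = variable_loadings(traits, fit.P_C)
            self.variance_explained_ = variance_explained(fit.P_C, traits)
        if expr is not None:
            self.transcript_loadings_ = variable_loadings(expr, fit.T_C)

        self.fit_ = fit
        self.scores_ = fit.scores_frame()
        self.path_coefficient_ = fit.path_coefficient
        self.rho_gt_ = fit.rho_gt
        self.rho_tp_ = fit.rho_tp
        self.rho_gp_given_t_ = fit.rho_gp_given_t
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged
        self.ranks_ = fit.ranks
        return self
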