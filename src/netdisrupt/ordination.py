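"""Multivariate comparisons in network space.

Nodes are cases, the ten topology indices are variables. Resemblance is
the Steinhaus (Bray-Curtis) dissimilarity; groups are compared with
PERMANOVA (omnibus + protected Holm-adjusted pairwise tests, permutation
p-values) and visualized with non-metric multidimensional scaling
(lowest-stress solution over randomized restarts) plus per-variable
vector fits whose R^2 scale the arrows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .robust_stats import holm_adjust

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "OrdinationResult",
    "VectorFit",
    "steinhaus_dissimilarity",
    "permanova",
    "pairwise_permanova",
    "nmds",
    "fit_vectors",
]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with case labels."""

    labels: list
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("labels and matrix shape disagree")

    def subset(self, idx: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix([self.labels[i] for i in idx],
                              self.D[np.ix_(idx, idx)])


@dataclass
class PermanovaResult:
    statistic: float                 # pseudo-F
    df_between: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    p: float
    n_perm: int
    seed: int | None
    comparison: str = ""
    p_adjusted: float | None = None


@dataclass
class OrdinationResult:
    scores: pd.DataFrame             # N x k, axes NMDS1..NMDSk
    stress: float                    # Kruskal stress-1 of the best start
    stresses: list[float] = field(default_factory=list)
    n_starts: int = 0
    best_start_index: int = 0
    converged: bool = True


@dataclass
class VectorFit:
    variable: str
    direction: np.ndarray            # unit vector in ordination space
    r2: float
    degenerate: bool = False


def steinhaus_dissimilarity(X, labels=None, variable_names=None) -> DistanceMatrix:
    """Steinhaus (Bray-Curtis) dissimilarity between rows of ``X``.

    D_ij = sum_v |x_iv - x_jv| / sum_v (x_iv + x_jv), defined only for
    non-negative data and bounded in [0, 1]. A pair of all-zero rows
    gets D_ij = 0 (identical cases).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a cases x variables matrix")
    if np.any(X < 0):
        bad = np.unique(np.nonzero(np.min(X, axis=0) < 0)[0])
        names = ([variable_names[i] for i in bad] if variable_names is not None
                 else bad.tolist())
        raise ValueError(
            f"Steinhaus dissimilarity is undefined for negative values "
            f"(variables: {names})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    D[~np.isfinite(D)] = 0.0         # all-zero row pairs: 0/0 -> identical
    np.fill_diagonal(D, 0.0)
    if labels is None:
        labels = list(range(X.shape[0]))
    return DistanceMatrix(list(labels), D)


def _codes_and_sizes(labels) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    codes = np.array([uniq.index(l) for l in labels.tolist()], dtype=np.int64)
    sizes = np.bincount(codes, minlength=len(uniq)).astype(float)
    return codes, sizes, uniq


def _ss_within_batch(D2: np.ndarray, codes_mat: np.ndarray, a: int,
                     sizes: np.ndarray) -> np.ndarray:
    """SS_within for each row of ``codes_mat`` (P label assignments).

    Evaluates sum_g (1/n_g) sum_{i<j in g} D_ij^2 for all P assignments
    in one BLAS matmul against stacked one-hot indicators.
    """
    P, N = codes_mat.shape
    E = np.zeros((N, P * a))
    rows = np.tile(np.arange(N), P)
    cols = (np.arange(P)[:, None] * a + codes_mat).ravel()
    E[rows, cols] = 1.0
    M = D2 @ E
    S = np.einsum("ij,ij->j", E, M).reshape(P, a)   # sum over ordered pairs
    return (S / (2.0 * sizes)).sum(axis=1)


def permanova(dm: DistanceMatrix, labels, n_perm: int = 10_000,
              seed: int | None = 0, comparison: str = "") -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Partitions squared dissimilarities: SS_total = sum_{i<j} D_ij^2 / N,
    SS_within = sum_g (1/n_g) sum_{i<j in g} D_ij^2, SS_among the
    difference; pseudo-F = (SS_among/(a-1)) / (SS_within/(N-a)). The
    p-value permutes the label vector, with the add-one convention
    p = (1 + #{F_perm >= F_obs})/(1 + n_perm).
    """
    codes, sizes, uniq = _codes_and_sizes(labels)
    a, N = len(uniq), len(codes)
    if a < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if N < a + 1:
        raise ValueError("PERMANOVA requires N >= number of groups + 1")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    D2 = dm.D.astype(float) ** 2
    ss_total = float(D2.sum() / (2.0 * N))
    ss_within_obs = float(_ss_within_batch(D2, codes[None, :], a, sizes)[0])
    ss_among = ss_total - ss_within_obs
    dfb, dfw = a - 1, N - a

    def f_stat(ss_w: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(ss_w > 0, (ss_total - ss_w) / dfb / (ss_w / dfw), np.inf)

    F_obs = float(f_stat(np.array([ss_within_obs]))[0])
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(512, int(2**22 / max(N, 1))))
    done = 0
    while done < n_perm:
        P = min(chunk, n_perm - done)
        perm_codes = np.empty((P, N), dtype=np.int64)
        for i in range(P):
            perm_codes[i] = codes[rng.permutation(N)]
        F_perm = f_stat(_ss_within_batch(D2, perm_codes, a, sizes))
        hits += int(np.sum(F_perm >= F_obs))
        done += P
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(statistic=F_obs, df_between=dfb, df_within=dfw,
                           ss_among=ss_among, ss_within=ss_within_obs,
                           ss_total=ss_total, p=float(p), n_perm=n_perm,
                           seed=seed, comparison=comparison or " vs ".join(map(str, uniq)))


def pairwise_permanova(dm: DistanceMatrix, labels, n_perm: int = 10_000,
                       alpha: float = 0.05, seed: int | None = 0,
                       protect: bool = True):
    """Omnibus PERMANOVA plus protected Holm-adjusted pairwise tests.

    Each pairwise test is a plain PERMANOVA on the two groups' rows.
    Pairwise tests run only when the omnibus p <= alpha (set
    ``protect=False`` to force them). Returns ``(omnibus, pairwise)``.
    """
    labels = np.asarray(labels)
    codes, sizes, uniq = _codes_and_sizes(labels)
    omnibus = permanova(dm, labels, n_perm=n_perm, seed=seed)
    if protect and omnibus.p > alpha:
        return omnibus, []
    pairwise: list[PermanovaResult] = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            idx = np.flatnonzero((codes == i) | (codes == j))
            res = permanova(dm.subset(idx), labels[idx], n_perm=n_perm,
                            seed=seed, comparison=f"{uniq[i]} vs {uniq[j]}")
            pairwise.append(res)
    adj = holm_adjust([r.p for r in pairwise])
    for r, padj in zip(pairwise, adj):
        r.p_adjusted = float(padj)
    return omnibus, pairwise


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 500, tol: float = 1e-7,
         seed: int | None = 0) -> OrdinationResult:
    """Non-metric multidimensional scaling, best of ``n_starts`` restarts.

    Each restart runs SMACOF with isotonic (monotone) regression of the
    configuration distances on the input dissimilarity ranks, minimizing
    Kruskal stress-1. The lowest-stress configuration is returned,
    centered at the origin and rotated to its principal axes.
    """
    N = len(dm.labels)
    if not 1 <= k < N:
        raise ValueError(f"k must satisfy 1 <= k < N (k={k}, N={N})")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    base = np.random.SeedSequence(seed).generate_state(n_starts)
    best_Y, best_stress, best_idx, best_iter = None, np.inf, 0, 0
    stresses: list[float] = []
    for i in range(n_starts):
        model = MDS(n_components=k, metric_mds=False, n_init=1, init="random",
                    max_iter=max_iter, eps=tol, metric="precomputed",
                    random_state=int(base[i] % (2**31 - 1)),
                    normalized_stress=True)
        Y = model.fit_transform(dm.D)
        stresses.append(float(model.stress_))
        if model.stress_ < best_stress:
            best_Y, best_stress, best_idx = Y, float(model.stress_), i
            best_iter = int(getattr(model, "n_iter_", 0))
    Yc = best_Y - best_Y.mean(axis=0)
    _, _, Vt = np.linalg.svd(Yc, full_matrices=False)
    scores = Yc @ Vt.T
    df = pd.DataFrame(scores, index=pd.Index(dm.labels, name="node"),
                      columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(scores=df, stress=best_stress, stresses=stresses,
                            n_starts=n_starts, best_start_index=best_idx,
                            converged=best_iter < max_iter)


def fit_vectors(scores, X, variable_names=None) -> list[VectorFit]:
    """Per-variable linear fits onto the ordination axes.

    Each variable is regressed (with intercept) on the k axis-score
    columns; the fit's R^2 gives the arrow length and the normalized
    coefficient vector its direction. Constant variables are flagged
    degenerate with R^2 = 0.
    """
    S = np.asarray(scores, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if S.shape[0] != X.shape[0]:
        raise ValueError("scores and X must be row-aligned")
    if S.shape[0] < S.shape[1] + 2:
        raise ValueError("need at least k + 2 cases for vector fitting")
    if variable_names is None:
        variable_names = [f"v{i}" for i in range(X.shape[1])]
    A = np.column_stack([np.ones(S.shape[0]), S])
    fits = []
    for name, y in zip(variable_names, X.T):
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0.0:
            fits.append(VectorFit(variable=name,
                                  direction=np.full(S.shape[1], np.nan),
                                  r2=0.0, degenerate=True))
            continue
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        coef = beta[1:]
        norm = float(np.linalg.norm(coef))
        if norm == 0.0:
            fits.append(VectorFit(variable=name,
                                  direction=np.full(S.shape[1], np.nan),
                                  r2=max(r2, 0.0), degenerate=True))
        else:
            fits.append(VectorFit(variable=name, direction=coef / norm,
                                  r2=min(max(r2, 0.0), 1.0)))
    return fits
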