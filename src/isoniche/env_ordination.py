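"""Linking community metrics to environmental stressors.

Per-site Layman metric matrices are related to water-chemistry
variables by: z-scaling of the environment, a Mahalanobis (or
Euclidean) response dissimilarity, exhaustive BIOENV subset selection
by Spearman rank correlation, distance-based redundancy analysis
(dbRDA) via Gower double-centering, and permutation tests of the
constrained model, its terms and its axes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class EnvMatrix:
    """Site × variable environmental matrix."""

    sites: list[str]
    variables: list[str]
    values: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.variables)):
            raise ValueError("values shape does not match sites x variables")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scaled: bool = False) -> "EnvMatrix":
        return cls(
            sites=[str(i) for i in frame.index],
            variables=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            scaled=scaled,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.variables)

    def subset(self, names: list[str]) -> "EnvMatrix":
        idx = [self.variables.index(n) for n in names]
        return EnvMatrix(self.sites, list(names), self.values[:, idx], self.scaled)


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative site dissimilarity with zero diagonal."""

    sites: list[str]
    d: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.sites), len(self.sites)):
            raise ValueError("dissimilarity must be square over sites")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("dissimilarity must be symmetric")
        if np.any(np.diag(d) != 0) or np.any(d < -1e-12):
            raise ValueError("dissimilarity needs zero diagonal and d >= 0")
        self.d = d

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    rho: float
    all_subsets: list[tuple[tuple[str, ...], float]]


@dataclass
class DbrdaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    site_scores: np.ndarray
    biplot_scores: np.ndarray
    prop_explained: np.ndarray
    sites: list[str] = field(default_factory=list)
    constraint_names: list[str] = field(default_factory=list)

    @property
    def constrained_inertia(self) -> float:
        return float(self.constrained_eigenvalues.sum())

    @property
    def unconstrained_inertia(self) -> float:
        return float(self.unconstrained_eigenvalues.sum())


def zscore_env(raw: EnvMatrix) -> EnvMatrix:
    """Column-wise (x − mean) / sample SD; constant columns are fatal."""
    if len(raw.sites) < 2:
        raise ValueError("z-scaling needs at least 2 sites")
    sd = raw.values.std(axis=0, ddof=1)
    constant = [v for v, s in zip(raw.variables, sd) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) cannot be scaled: {constant}")
    scaled = (raw.values - raw.values.mean(axis=0)) / sd
    return EnvMatrix(list(raw.sites), list(raw.variables), scaled, scaled=True)


def dissimilarity(
    m: np.ndarray | pd.DataFrame,
    metric: str = "mahalanobis",
    sites: list[str] | None = None,
    strict: bool = False,
) -> DissimilarityMatrix:
    """Pairwise site dissimilarity of a site × metric matrix.

    ``mahalanobis`` whitens columns by the inverse square root of the
    column covariance before taking Euclidean distances; with more
    metrics than sites the covariance is singular and the Moore-Penrose
    pseudo-inverse is used (with a warning) unless ``strict``.
    """
    if isinstance(m, pd.DataFrame):
        sites = sites or [str(i) for i in m.index]
        x = m.to_numpy(dtype=float)
    else:
        x = np.asarray(m, dtype=float)
        sites = sites or [str(i) for i in range(x.shape[0])]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 sites")

    if metric == "euclidean":
        d = squareform(pdist(x))
    elif metric == "mahalanobis":
        cov = np.cov(x.T, ddof=1)
        cov = np.atleast_2d(cov)
        rank = np.linalg.matrix_rank(cov)
        if rank < cov.shape[0]:
            if strict:
                raise ValueError(
                    "singular column covariance; use strict=False for "
                    "pseudo-inverse whitening"
                )
            warnings.warn(
                "singular column covariance: Mahalanobis whitening uses the "
                "Moore-Penrose pseudo-inverse"
            )
        # eigendecomposition-based pinv square root
        w, v = np.linalg.eigh(cov)
        tol = max(cov.shape) * np.finfo(float).eps * max(w.max(), 0)
        inv_sqrt = np.where(w > tol, 1.0 / np.sqrt(np.where(w > tol, w, 1.0)), 0.0)
        white = (x - x.mean(axis=0)) @ v @ np.diag(inv_sqrt)
        d = squareform(pdist(white))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DissimilarityMatrix(sites=list(sites), d=d, metric=metric)


def bioenv_search(
    env: EnvMatrix, response: DissimilarityMatrix, max_vars: int | None = None
) -> BioenvResult:
    """Exhaustive best-subset search over environmental variables.

    For every non-empty subset of (scaled) variables, the Euclidean
    inter-site distance on that subset is rank-correlated (Spearman,
    average ranks for ties) with the response dissimilarity; the subset
    maximizing rho wins.  Exhaustive search is limited to 20 variables.
    """
    if env.sites != response.sites:
        raise ValueError("site ordering of env and response must match")
    if not env.scaled:
        env = zscore_env(env)
    k = len(env.variables)
    if k > 20:
        raise ValueError("exhaustive search limited to 20 variables")
    max_vars = max_vars or k
    resp = response.condensed()
    ranked: list[tuple[tuple[str, ...], float]] = []
    for r in range(1, max_vars + 1):
        for combo in itertools.combinations(range(k), r):
            d = pdist(env.values[:, combo])
            rho = stats.spearmanr(d, resp).statistic
            ranked.append((tuple(env.variables[i] for i in combo), float(rho)))
    ranked.sort(key=lambda t: -t[1])
    return BioenvResult(best_subset=ranked[0][0], rho=ranked[0][1], all_subsets=ranked)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d * d) @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix tolerates collinear constraints
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def dbrda_fit(response: DissimilarityMatrix, constraints: EnvMatrix) -> DbrdaResult:
    """Distance-based redundancy analysis.

    The Gower-centered matrix G = −½ J D∘D J is split by the hat matrix
    H of the (centered) constraint columns into a constrained part HGH
    and a residual part (I−H)G(I−H); each is eigendecomposed and
    eigenvalues are reported as proportions of the total inertia
    tr(G).  Small negative eigenvalues (possible for non-Euclidean
    dissimilarities) are clipped at zero with a warning.
    """
    if response.sites != constraints.sites:
        raise ValueError("site ordering of response and constraints must match")
    n = len(response.sites)
    q = len(constraints.variables)
    if n <= q:
        raise ValueError("need more sites than constraint variables")
    g = _gower_center(response.d)
    total = float(np.trace(g))
    if total <= 0:
        raise ValueError("non-positive total inertia: pathological dissimilarity")
    x = constraints.values - constraints.values.mean(axis=0)
    h = _hat(x)

    def eig_part(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w, v = np.linalg.eigh((m + m.T) / 2.0)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        if np.any(w < -1e-8 * max(total, 1.0)):
            warnings.warn("negative Gower eigenvalues clipped at 0")
        w = np.clip(w, 0.0, None)
        keep = w > 1e-10 * max(total, 1.0)
        return w[keep], v[:, keep]

    wc, vc = eig_part(h @ g @ h)
    r = np.eye(n) - h
    wr, vr = eig_part(r @ g @ r)

    site_scores = vc * np.sqrt(wc) if wc.size else np.zeros((n, 0))
    if wc.size and x.size:
        xs = x / x.std(axis=0, ddof=1)
        axes_std = vc  # unit-length axes
        biplot = np.array(
            [[float(np.corrcoef(xs[:, j], axes_std[:, a])[0, 1])
              for a in range(wc.size)] for j in range(q)]
        )
    else:
        biplot = np.zeros((q, 0))

    return DbrdaResult(
        constrained_eigenvalues=wc,
        unconstrained_eigenvalues=wr,
        total_inertia=total,
        site_scores=site_scores,
        biplot_scores=biplot,
        prop_explained=np.concatenate([wc, wr]) / total,
        sites=list(response.sites),
        constraint_names=list(constraints.variables),
    )


def _pseudo_f(d: np.ndarray, x: np.ndarray) -> float:
    n, q = d.shape[0], x.shape[1]
    g = _gower_center(d)
    h = _hat(x - x.mean(axis=0))
    constrained = float(np.trace(h @ g @ h))
    r = np.eye(n) - h
    residual = float(np.trace(r @ g @ r))
    return (constrained / q) / (residual / (n - q - 1))


def permutation_test(
    response: DissimilarityMatrix,
    constraints: EnvMatrix,
    n_perm: int = 999,
    seed: int = 0,
    scope: str = "model",
) -> pd.DataFrame:
    """Permutation test of the dbRDA constraints.

    The observed pseudo-F,

        F = (constrained inertia / q) / (residual inertia / (n−q−1)),

    is compared with its distribution under free permutation of the
    response's site rows; p = (1 + #{F* ≥ F}) / (1 + n_perm).
    ``scope='model'`` tests all constraints jointly; ``'terms'`` tests
    each variable sequentially (added in order, extra inertia over the
    previous model against the full-model residual); ``'axes'`` tests
    each constrained axis marginally (its eigenvalue against the
    residual).
    """
    if response.sites != constraints.sites:
        raise ValueError("site ordering of response and constraints must match")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = len(response.sites)
    if n <= 12 and math.factorial(n) <= n_perm:
        warnings.warn("fewer distinct permutations than n_perm")
    rng = np.random.default_rng(seed)
    d = response.d
    x = constraints.values
    q = x.shape[1]
    perms = [rng.permutation(n) for _ in range(n_perm)]

    def model_stats(dmat: np.ndarray) -> dict[str, float]:
        g = _gower_center(dmat)
        xc = x - x.mean(axis=0)
        h = _hat(xc)
        r = np.eye(n) - h
        resid = float(np.trace(r @ g @ r))
        denom = resid / (n - q - 1)
        out = {"model": (float(np.trace(h @ g @ h)) / q) / denom}
        if scope == "terms":
            prev = 0.0
            for k in range(1, q + 1):
                hk = _hat(xc[:, :k])
                ck = float(np.trace(hk @ g @ hk))
                out[constraints.variables[k - 1]] = (ck - prev) / denom
                prev = ck
        elif scope == "axes":
            w = np.linalg.eigvalsh((h @ g @ h + (h @ g @ h).T) / 2.0)[::-1]
            w = np.clip(w, 0.0, None)
            for i in range(min(q, int((w > 1e-10 * max(w[0], 1e-300)).sum()))):
                out[f"dbRDA{i + 1}"] = w[i] / denom
        return out

    obs = model_stats(d)
    if scope == "model":
        keys = ["model"]
    elif scope == "terms":
        keys = list(constraints.variables)
    elif scope == "axes":
        keys = [k for k in obs if k.startswith("dbRDA")]
    else:
        raise ValueError("scope must be 'model', 'terms' or 'axes'")

    exceed = {k: 0 for k in keys}
    for p in perms:
        stat = model_stats(d[np.ix_(p, p)])
        for k in keys:
            if stat.get(k, -np.inf) >= obs[k]:
                exceed[k] += 1
    rows = [
        {
            "term": k,
            "pseudo_F": obs[k],
            "p": (1 + exceed[k]) / (1 + n_perm),
            "n_perm": n_perm,
        }
        for k in keys
    ]
    return pd.DataFrame(rows)
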