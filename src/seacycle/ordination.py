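"""Ordination: PCA, multi-table co-inertia analysis (MCOA), and PERMANOVA.

The community matrices entering these methods are z-scored proportions, so
Euclidean geometry is appropriate and all three methods are linear.  PCA and
MCOA share one metric convention: uniform row weights 1/n, i.e. eigenvalues
are variances with divisor n.  Variance *fractions* — the quantities usually
reported — do not depend on that choice.

MCOA finds, per axis, one synthetic sample-score vector v maximizing the
summed squared covariances with the best unit direction in each of K feature
tables:

    maximize  sum_k w_k cov^2(X_k u_k, v)   s.t. |u_k| = 1, v'Dv = 1

which reduces to the eigen-decomposition of sum_k w_k X_k X_k' under the row
weight metric D = I/n.  PERMANOVA partitions the total sum of squares of a
sample distance matrix among sequential (Type-I) factors via Gower-centered
projection traces, with significance by free permutation of sample
identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import ZScoreTable

__all__ = [
    "pca",
    "PCAResult",
    "MCOA",
    "MCOAResults",
    "Permanova",
    "PermanovaResults",
    "permanova",
]


def _obs_matrix(table, mode: str) -> tuple[np.ndarray, list, list]:
    """Observations x variables array plus labels for the requested mode."""
    if isinstance(table, ZScoreTable):
        frame = table.data
    else:
        frame = pd.DataFrame(table)
    if mode == "samples":
        # features are rows in our tables; samples become observations
        A = frame.to_numpy(dtype=float).T
        obs, var = list(frame.columns), list(frame.index)
    elif mode == "features":
        A = frame.to_numpy(dtype=float)
        obs, var = list(frame.index), list(frame.columns)
    else:
        raise ValueError("mode must be 'samples' or 'features'")
    return A, obs, var


@dataclass
class PCAResult:
    scores: pd.DataFrame  # observations x components
    loadings: pd.DataFrame  # variables x components
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    def summary(self) -> str:
        head = "PCA: {} observations, {} variables".format(*self.scores.shape[:1] + self.loadings.shape[:1])
        parts = [head]
        for i, f in enumerate(self.variance_fractions[:5], start=1):
            parts.append(f"  PC{i}: {100 * f:.1f}% of variance")
        return "\n".join(parts)


def pca(table, mode: str = "samples", n_components: int | None = None) -> PCAResult:
    """Principal component analysis of a z-scored table.

    ``mode='samples'`` ordinates samples (observations) in gene/taxon space;
    ``mode='features'`` transposes, ordinating the features by the similarity
    of their temporal dynamics.  Columns of the observation matrix are
    centered; eigenvalues use divisor n (see module docstring).
    """
    A, obs, var = _obs_matrix(table, mode)
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    Ac = A - A.mean(axis=0)
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    eig = s**2 / A.shape[0]
    total = eig.sum()
    if total <= 0:
        raise ValueError("matrix has zero total variance")
    k = len(eig) if n_components is None else min(n_components, len(eig))
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame((U * s)[:, :k], index=obs, columns=cols),
        loadings=pd.DataFrame(Vt.T[:, :k], index=var, columns=cols),
        eigenvalues=eig[:k],
        variance_fractions=eig[:k] / total,
    )


class MCOA:
    """Multi-table co-inertia analysis across K feature tables.

    Parameters
    ----------
    tables : mapping or sequence of DataFrame / ZScoreTable
        Features x samples tables sharing an identical sample ordering
        (e.g. one per classification system: family, KO, COG, Pfam,
        TIGRfam).
    table_scaling : {"inertia", "none"}
        "inertia" rescales each table to total inertia 1 before summing, so
        no single (large) classification system dominates the compromise;
        "none" uses the tables as given.
    """

    def __init__(self, tables, table_scaling: str = "inertia"):
        if isinstance(tables, dict):
            names = list(tables)
            frames = [tables[k] for k in names]
        else:
            frames = list(tables)
            names = [f"table_{i + 1}" for i in range(len(frames))]
        if not frames:
            raise ValueError("at least one table required")
        if table_scaling not in ("inertia", "none"):
            raise ValueError("table_scaling must be 'inertia' or 'none'")
        mats, samples = [], None
        for f in frames:
            A, obs, _ = _obs_matrix(f, "samples")
            if samples is None:
                samples = obs
            elif obs != samples:
                raise ValueError("tables must share an identical sample ordering")
            mats.append(A - A.mean(axis=0))
        self.table_names = names
        self.samples = samples
        self.matrices = mats
        self.table_scaling = table_scaling

    def fit(self, n_axes: int = 2) -> "MCOAResults":
        n = len(self.samples)
        weights = {}
        mats = []
        for name, X in zip(self.table_names, self.matrices):
            inertia = (X**2).sum() / n
            if inertia <= 0:
                raise ValueError(f"table {name!r} has zero total variance")
            if self.table_scaling == "inertia":
                w = 1.0 / inertia
            else:
                w = 1.0
            weights[name] = w
            mats.append(X * np.sqrt(w))
        M = sum(X @ X.T for X in mats) / n
        eigval, eigvec = np.linalg.eigh(M)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        eigval = np.clip(eigval, 0, None)
        total = eigval.sum()
        k = min(n_axes, len(eigval))
        cols = [f"Axis{i + 1}" for i in range(k)]
        # synthetic scores: orthonormal under the 1/n row-weight metric
        V = eigvec[:, :k] * np.sqrt(n)
        scores = pd.DataFrame(V, index=self.samples, columns=cols)
        loadings = {}
        for name, X in zip(self.table_names, mats):
            u = X.T @ (V / n)
            norms = np.linalg.norm(u, axis=0)
            norms[norms == 0] = 1.0
            loadings[name] = pd.DataFrame(u / norms, columns=cols)
        return MCOAResults(
            scores=scores,
            loadings=loadings,
            eigenvalues=eigval[:k],
            variance_fractions=eigval[:k] / total,
            table_weights=weights,
            _matrices=mats,
            _n=n,
        )


@dataclass
class MCOAResults:
    scores: pd.DataFrame  # samples x axes, v' (I/n) v = 1 per axis
    loadings: dict  # table name -> variables x axes (unit norm)
    eigenvalues: np.ndarray  # pseudo-eigenvalues (attained criterion values)
    variance_fractions: np.ndarray  # per-axis shared-variance fractions
    table_weights: dict
    _matrices: list = field(repr=False, default_factory=list)
    _n: int = 0

    def criterion_value(self, v) -> float:
        """Co-inertia criterion sum_k ||X_k' D v||^2 for a direction v,
        normalized to v'Dv = 1 under row weights D = I/n.  By construction
        no direction can exceed the leading pseudo-eigenvalue."""
        v = np.asarray(v, dtype=float)
        v = v / np.sqrt((v**2).sum() / self._n)
        return float(
            sum(((X.T @ (v / self._n)) ** 2).sum() for X in self._matrices)
        )

    def summary(self) -> str:
        lines = [
            f"MCOA across {len(self.loadings)} tables "
            f"({', '.join(self.loadings)})"
        ]
        for i, f in enumerate(self.variance_fractions, start=1):
            lines.append(
                f"  Axis{i}: pseudo-eigenvalue {self.eigenvalues[i - 1]:.4g}, "
                f"{100 * f:.1f}% of shared variance"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PERMANOVA


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(X) and its rank, via thin SVD."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    r = int((s > tol).sum())
    Ur = U[:, :r]
    return Ur @ Ur.T, r


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    out = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        out[labels == lev, j] = 1.0
    return out


class Permanova:
    """Permutational multivariate ANOVA with sequential month/year factors.

    Parameters
    ----------
    data : square distance matrix (DataFrame/ndarray) or ZScoreTable/DataFrame
        If not square-symmetric, treated as a features x samples table and
        converted to Euclidean distances between samples.
    factors : DataFrame
        Samples x factor columns (categorical).  Factors enter the
        sequential SS in column order; pass month before year to mirror the
        anomaly model's convention.
    interaction : bool
        Append the interaction of the first two factors.  If any interaction
        cell is empty (an unbalanced multi-year series cannot fill all
        month x year cells) the term is dropped with a warning.
    """

    def __init__(self, data, factors: pd.DataFrame, interaction: bool = False):
        D = self._distances(data)
        n = D.shape[0]
        if len(factors) != n:
            raise ValueError("factors must have one row per sample")
        if (np.abs(np.diag(D)) > 1e-12).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        self.D = D
        self.n = n
        self.factors = factors.reset_index(drop=True)
        self.terms = [(str(c), self.factors[c].to_numpy()) for c in factors.columns]
        if interaction:
            if len(self.terms) < 2:
                raise ValueError("interaction requires at least two factors")
            a, b = self.terms[0][1], self.terms[1][1]
            cells = pd.MultiIndex.from_arrays([a, b])
            n_obs_cells = len(set(cells))
            n_full = len(set(a)) * len(set(b))
            if n_obs_cells < n_full:
                warnings.warn(
                    f"interaction dropped: {n_full - n_obs_cells} empty "
                    "factor cell(s)",
                    stacklevel=2,
                )
            else:
                name = f"{self.terms[0][0]}:{self.terms[1][0]}"
                inter = np.array([f"{x}|{y}" for x, y in zip(a, b)])
                self.terms.append((name, inter))

    @staticmethod
    def _distances(data) -> np.ndarray:
        if isinstance(data, ZScoreTable):
            return squareform(pdist(data.matrix))
        arr = np.asarray(
            data.data if hasattr(data, "data") else data, dtype=float
        )
        # a square matrix with a zero diagonal is taken to be a distance
        # matrix; symmetry is enforced by the constructor
        if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.allclose(
            np.diag(arr), 0, atol=1e-12
        ):
            return arr
        # features x samples table -> Euclidean distances between samples
        frame = pd.DataFrame(data)
        return squareform(pdist(frame.to_numpy(dtype=float).T))

    def fit(self, n_perm: int = 999, seed: int = 42) -> "PermanovaResults":
        n = self.n
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (self.D**2) @ J

        # nested hat matrices: intercept, +term1, +term1+term2, ...
        X = np.ones((n, 1))
        hats, ranks = [], []
        H0, r0 = _hat(X)
        hats.append(H0)
        ranks.append(r0)
        for _, labels in self.terms:
            X = np.hstack([X, _dummies(labels)])
            H, r = _hat(X)
            hats.append(H)
            ranks.append(r)
        deltas = [hats[i + 1] - hats[i] for i in range(len(self.terms))]
        dfs = [ranks[i + 1] - ranks[i] for i in range(len(self.terms))]
        H_full = hats[-1]
        df_res = n - ranks[-1]
        if df_res <= 0:
            raise ValueError("no residual degrees of freedom")
        R = np.eye(n) - H_full

        def stats(Gm):
            ss = np.array([float((dH * Gm.T).sum()) for dH in deltas])
            ss_res = float((R * Gm.T).sum())
            return ss, ss_res

        ss_obs, ss_res = stats(G)
        ss_total = float(np.trace(G))
        F_obs = (ss_obs / dfs) / (ss_res / df_res)

        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(self.terms))
        # tolerance so permutations exactly tied with the observed statistic
        # count as >= despite round-off in the trace computations
        tol = 1e-10 * np.maximum(np.abs(F_obs), 1.0)
        for _ in range(n_perm):
            p = rng.permutation(n)
            Gp = G[np.ix_(p, p)]
            ss_p, ss_res_p = stats(Gp)
            F_p = (ss_p / dfs) / (ss_res_p / df_res)
            exceed += F_p >= F_obs - tol
        pvals = (1.0 + exceed) / (1.0 + n_perm)

        rows = []
        for (name, _), df, ss, F, p in zip(self.terms, dfs, ss_obs, F_obs, pvals):
            rows.append((name, df, ss, ss / ss_total, F, p))
        rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
        rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "SS", "R2", "pseudo_F", "p_value"]
        ).set_index("term")
        return PermanovaResults(table=table, n_perm=n_perm, seed=seed)


@dataclass
class PermanovaResults:
    table: pd.DataFrame
    n_perm: int
    seed: int

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"].drop(["Residual", "Total"])

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"].drop(["Residual", "Total"])

    def summary(self) -> str:
        return (
            f"PERMANOVA ({self.n_perm} permutations, seed {self.seed})\n"
            + self.table.to_string(float_format=lambda v: f"{v:.4g}")
        )


def permanova(data, factors, interaction=False, n_perm=999, seed=42):
    """One-call PERMANOVA; see :class:`Permanova`."""
    return Permanova(data, factors, interaction=interaction).fit(
        n_perm=n_perm, seed=seed
    )
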