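"""Multivariate co-structure of two marker tables.

Workflow: Jaccard (S3) distances on dominant presence/absence data ->
principal-coordinate embedding (with Lingoes correction for
non-Euclidean matrices) -> between-class analysis with populations as
groups -> co-inertia analysis of the two between-class ordinations, with
the RV coefficient and a row-permutation test of the global
co-structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def jaccard_s3_distance(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise ``sqrt(1 - S3)`` distances between presence/absence rows.

    S3 = a / (a + b + c) with a the shared presences and b, c the
    asymmetric ones; the square-root transform makes the matrix
    Euclidean-embeddable in most cases.  All-zero rows are rejected.
    """
    B = np.asarray(matrix, dtype=float)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("matrix must be 0/1")
    ids = (
        list(matrix.index)
        if isinstance(matrix, pd.DataFrame)
        else list(range(len(B)))
    )
    rows = B.sum(axis=1)
    if (rows == 0).any():
        bad = [ids[i] for i in np.flatnonzero(rows == 0)]
        raise ValueError(f"all-zero rows have undefined Jaccard similarity: {bad}")
    shared = B @ B.T
    union = rows[:, None] + rows[None, :] - shared
    s = shared / union
    d = np.sqrt(np.clip(1.0 - s, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class Ordination:
    """Row coordinates on orthogonal axes with their eigenvalues."""

    ids: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    kind: str  # pcoa | between_class
    groups: dict | None = None
    between_inertia_fraction: float | None = None
    group_scores: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Orient each axis so its largest-magnitude coordinate is positive."""
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def principal_coordinates(
    dist: pd.DataFrame, correction: str = "lingoes", tol: float = 1e-9
) -> Ordination:
    """Classical scaling (PCoA) of a symmetric distance matrix.

    Double-centers the squared distances and eigendecomposes; axes with
    eigenvalues <= tol are dropped.  With ``correction='lingoes'`` a
    constant is added to the off-diagonal squared distances when negative
    eigenvalues appear, making the matrix Euclidean; with ``'none'`` a
    warning is recorded instead.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(n))

    def decompose(D2: np.ndarray):
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    D2 = D ** 2
    vals, vecs = decompose(D2)
    notes: list[str] = []
    scale = max(abs(vals).sum(), tol)
    if vals[-1] < -tol * scale:
        if correction == "lingoes":
            c1 = -vals[-1]
            D2c = D2 + 2 * c1 * (1 - np.eye(n))
            vals, vecs = decompose(D2c)
            notes.append(f"lingoes correction applied (c1={c1:.6g})")
        elif correction == "none":
            notes.append(
                f"negative eigenvalues present (min {vals[-1]:.6g}); "
                "coordinates are approximate"
            )
        else:
            raise ValueError(f"unknown correction {correction!r}")
    keep = vals > tol * max(vals.max(), 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return Ordination(ids, _fix_signs(coords), vals[keep], "pcoa", warnings=notes)


def between_class_analysis(
    ordination: Ordination, groups: dict | pd.Series
) -> Ordination:
    """Principal axes of the (size-weighted) group-centroid cloud.

    Rows are projected onto the axes that maximize between-group
    variance in the ordination space; the reported between-class inertia
    fraction is between-group variance over total variance.
    """
    groups = dict(groups)
    missing = [i for i in ordination.ids if i not in groups]
    if missing:
        raise ValueError(f"rows without a group: {missing[:5]}")
    X = ordination.coordinates
    ids = ordination.ids
    labels = [groups[i] for i in ids]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    lab_arr = np.array(labels, dtype=object)
    n = len(ids)
    m = X.mean(axis=0)
    Xc = X - m
    cents, sizes = [], []
    for g in uniq:
        idx = np.flatnonzero(lab_arr == g)
        if len(idx) == 0:
            raise ValueError(f"empty group {g!r}")
        cents.append(Xc[idx].mean(axis=0))
        sizes.append(len(idx))
    C = np.array(cents)
    w = np.array(sizes) / n
    # weighted centroid cloud; global weighted mean of centroids is 0
    Cw = C * np.sqrt(w)[:, None]
    U, s, Vt = np.linalg.svd(Cw, full_matrices=False)
    keep = s ** 2 > 1e-12 * max(s.max() ** 2, 1.0)
    axes = Vt[keep].T
    eig = (s ** 2)[keep]
    # deterministic orientation via row scores
    row_scores = Xc @ axes
    flip = np.ones(axes.shape[1])
    for j in range(axes.shape[1]):
        col = row_scores[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            flip[j] = -1
    axes = axes * flip
    row_scores = row_scores * flip
    group_scores = pd.DataFrame(
        C @ axes, index=uniq,
        columns=[f"axis{i + 1}" for i in range(axes.shape[1])],
    )
    total_inertia = (Xc ** 2).sum() / n
    between = float((w[:, None] * C ** 2).sum())
    return Ordination(
        ids,
        row_scores,
        eig,
        "between_class",
        groups=groups,
        between_inertia_fraction=(between / total_inertia if total_inertia > 0 else 0.0),
        group_scores=group_scores,
    )


@dataclass
class CoinertiaResult:
    eigenvalues: np.ndarray
    rv: float
    p_value: float | None
    n_permutations: int
    row_scores_x: pd.DataFrame
    row_scores_y: pd.DataFrame
    population_scores_x: pd.DataFrame | None
    population_scores_y: pd.DataFrame | None
    vector_lengths: pd.Series | None

    @property
    def eigenvalue_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


def _rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    Sxy = X.T @ Y
    Sxx = X.T @ X
    Syy = Y.T @ Y
    denom = np.sqrt((Sxx ** 2).sum() * (Syy ** 2).sum())
    if denom == 0:
        raise ValueError("zero total inertia in one table")
    return float((Sxy ** 2).sum() / denom)


def coinertia(
    ord_x: Ordination,
    ord_y: Ordination,
    n_perm: int = 1000,
    seed: int | None = None,
) -> CoinertiaResult:
    """Co-inertia analysis of two ordinations over the same rows.

    Decomposes the cross-covariance of the centered score tables by SVD;
    the RV coefficient is the total co-inertia normalized by the tables'
    own inertias, and its significance comes from permuting the rows of
    the second table.

    When both ordinations carry group assignments (the between-class
    case) the analyzed tables are the group-size-weighted population
    centroid tables, matching group-aggregated co-inertia: the RV and
    its permutation test then operate at the population level, while
    individual row scores are still reported as projections onto the
    co-inertia axes.  Without groups the analysis is row-level.

    Convention: ``ord_x`` is the adaptive marker (arrow tips in the
    factorial map), ``ord_y`` the neutral one (arrow starts).
    """
    if list(ord_x.ids) != list(ord_y.ids):
        raise ValueError("ordinations must share the same rows in the same order")
    X = ord_x.coordinates - ord_x.coordinates.mean(axis=0)
    Y = ord_y.coordinates - ord_y.coordinates.mean(axis=0)
    n = X.shape[0]

    grouped = ord_x.groups is not None and ord_y.groups is not None
    if grouped:
        # population-level co-structure: the analyzed tables are the
        # group-size-weighted centroid tables, so the permutation unit is
        # the population (low-power by design with few populations, as in
        # group-aggregated co-inertia)
        lab = np.array([ord_x.groups[i] for i in ord_x.ids], dtype=object)
        uniq = list(dict.fromkeys(lab))
        w = np.array([(lab == g).sum() / n for g in uniq])
        GX = np.array([X[lab == g].mean(axis=0) for g in uniq])
        GY = np.array([Y[lab == g].mean(axis=0) for g in uniq])
        TX = GX * np.sqrt(w)[:, None]
        TY = GY * np.sqrt(w)[:, None]
    else:
        TX = X / np.sqrt(n)
        TY = Y / np.sqrt(n)

    C = TX.T @ TY
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eig = s ** 2
    sx = X @ U
    sy = Y @ Vt.T
    # deterministic orientation
    for j in range(sx.shape[1]):
        if len(sx) and sx[np.argmax(np.abs(sx[:, j])), j] < 0:
            sx[:, j] = -sx[:, j]
            sy[:, j] = -sy[:, j]
    rv = _rv_coefficient(TX, TY)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        m = TX.shape[0]
        for _ in range(n_perm):
            perm = rng.permutation(m)
            if _rv_coefficient(TX, TY[perm]) >= rv - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)

    cols = [f"axis{i + 1}" for i in range(sx.shape[1])]
    rx = pd.DataFrame(sx, index=ord_x.ids, columns=cols)
    ry = pd.DataFrame(sy, index=ord_y.ids, columns=cols)
    px = py = lengths = None
    if grouped:
        lab_s = pd.Series({i: ord_x.groups[i] for i in ord_x.ids})
        px = rx.groupby(lab_s).mean()
        py = ry.groupby(lab_s).mean()
        lengths = pd.Series(
            np.sqrt(((px - py.loc[px.index]) ** 2).sum(axis=1)),
            name="vector_length",
        )
    return CoinertiaResult(eig, rv, p, n_perm, rx, ry, px, py, lengths)


def plot_coinertia(result: CoinertiaResult, path=None):
    """Arrow plot: per population, dot = neutral position, tip = MHC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    px, py = result.population_scores_x, result.population_scores_y
    if px is None:
        raise ValueError("no population groups recorded in the result")
    for pop in px.index:
        x0, y0 = py.loc[pop, "axis1"], py.loc[pop, "axis2"] if "axis2" in py else 0.0
        x1, y1 = px.loc[pop, "axis1"], px.loc[pop, "axis2"] if "axis2" in px else 0.0
        ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops=dict(arrowstyle="->", color="steelblue"))
        ax.plot([x0], [y0], "o", color="black", ms=4)
        ax.annotate(pop, (x1, y1), fontsize=8)
    fr = result.eigenvalue_fractions
    ax.set_xlabel(f"CoA axis 1 ({100 * fr[0]:.0f}%)")
    if len(fr) > 1:
        ax.set_ylabel(f"CoA axis 2 ({100 * fr[1]:.0f}%)")
    ax.set_title(f"Co-inertia: RV={result.rv:.2f}, p={result.p_value}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
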