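"""Isolation-by-distance tests and cross-marker correlations.

Great-circle geographic distances (log-transformed for linearity),
simple Mantel correlation with one-sided permutation significance, the
partial Mantel test with permutation of residuals (Legendre's method),
and the Pearson correlation between per-population diversity measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = map(math.radians, (*a, *b))
    h = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_log_distance(
    coordinates: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    """Natural-log great-circle distance matrix over populations."""
    pops = list(coordinates)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            km = haversine_km(coordinates[a], coordinates[b])
            if km == 0:
                raise ValueError(f"populations {a} and {b} are coincident; "
                                 "log distance undefined")
            D.loc[a, b] = D.loc[b, a] = math.log(km)
    return D


@dataclass
class MantelResult:
    r: float
    p_value: float | None
    n_permutations: int
    kind: str  # simple | partial
    alternative: str = "greater"


def _triangle(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _check_pair(dA: pd.DataFrame, dB: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if list(dA.index) != list(dB.index):
        raise ValueError("matrices must share the same labels in the same order")
    A, B = np.asarray(dA, float), np.asarray(dB, float)
    for M in (A, B):
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError("matrices must be symmetric")
    return A, B


def mantel(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Simple Mantel test: Pearson r of the upper triangles.

    The permutation null shuffles the labels (rows and columns jointly)
    of the second matrix; one-sided positive association by default
    (the isolation-by-distance hypothesis), two-sided available.
    """
    A, B = _check_pair(dA, dB)
    a, b = _triangle(A), _triangle(B)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a distance triangle")
    r = float(np.corrcoef(a, b)[0, 1])
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = A.shape[0]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            rp = np.corrcoef(a, _triangle(B[np.ix_(perm, perm)]))[0, 1]
            if alternative == "greater":
                hits += rp >= r - 1e-12
            else:
                hits += abs(rp) >= abs(r) - 1e-12
        p = (hits + 1) / (n_perm + 1)
    return MantelResult(r, p, n_perm, "simple", alternative)


def _residual_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Matrix of residuals of the off-diagonal linear fit Y ~ X."""
    y, x = _triangle(Y), _triangle(X)
    beta, alpha = np.polyfit(x, y, 1)
    R = Y - (alpha + beta * X)
    np.fill_diagonal(R, 0.0)
    return R


def partial_mantel(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    dC: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel correlation of dA and dB controlling for dC.

    r is the partial Pearson correlation of the upper triangles;
    significance permutes the residual matrix of dA on dC (rows and
    columns jointly) and correlates it against the residuals of dB on dC.
    """
    A, B = _check_pair(dA, dB)
    _, C = _check_pair(dA, dC)
    a, b, c = _triangle(A), _triangle(B), _triangle(C)
    for v in (a, b, c):
        if v.std() == 0:
            raise ValueError("zero variance in a distance triangle")
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    if 1 - r_ac ** 2 < 1e-12 or 1 - r_bc ** 2 < 1e-12:
        raise ValueError("perfect collinearity with the control matrix")
    denom = math.sqrt((1 - r_ac ** 2) * (1 - r_bc ** 2))
    r = float((r_ab - r_ac * r_bc) / denom)
    p = None
    if n_perm > 0:
        RA = _residual_matrix(A, C)
        rb = _triangle(_residual_matrix(B, C))
        ra = _triangle(RA)
        r_res = float(np.corrcoef(ra, rb)[0, 1])
        rng = np.random.default_rng(seed)
        n = A.shape[0]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            rp = np.corrcoef(_triangle(RA[np.ix_(perm, perm)]), rb)[0, 1]
            if alternative == "greater":
                hits += rp >= r_res - 1e-12
            else:
                hits += abs(rp) >= abs(r_res) - 1e-12
        p = (hits + 1) / (n_perm + 1)
    return MantelResult(r, p, n_perm, "partial", alternative)


def linearized(fst: pd.DataFrame) -> pd.DataFrame:
    """Rousset's F_ST / (1 - F_ST) linearization (optional for Mantel)."""
    M = fst.copy().astype(float)
    return M / (1.0 - M)


def exclude_population(D: pd.DataFrame, *populations: str) -> pd.DataFrame:
    """Drop populations from a labelled square matrix (e.g. outlying RU)."""
    keep = [p for p in D.index if p not in populations]
    return D.loc[keep, keep]


def diversity_correlation(
    x: Sequence[float] | pd.Series, y: Sequence[float] | pd.Series
) -> tuple[float, float]:
    """Pearson correlation between two per-population diversity vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
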