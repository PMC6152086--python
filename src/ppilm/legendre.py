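"""Two-dimensional Legendre-moment descriptors of PSSMs.

The R x 20 profile is treated as an image f on [-1, 1]^2 (rows = sequence
positions on the x axis, amino-acid columns on the y axis) and projected
onto the orthogonal basis V_m(x) V_n(y) of Legendre polynomials:

    L_mn = mu_mn * int int V_m(x) V_n(y) f(x, y) dx dy,
    mu_mn = (2m + 1)(2n + 1) / 4.

Orthogonality (int V_m V_n dx = 2 delta_mn / (2m + 1)) makes the moments
non-redundant, so the set {L_mn : 0 <= m, n <= max_order} is a compact
descriptor of the conservation pattern in the profile.  With the default
max_order = 20 this yields (20 + 1)^2 = 441 values per protein.

The piecewise-constant image is integrated exactly: each cell's
contribution uses the antiderivative identity

    int V_m dx = (V_{m+1} - V_{m-1}) / (2m + 1),

so the "exact" evaluator has no quadrature error.  A dense Gauss-Legendre
evaluator built on scipy's polynomial routines is provided as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import eval_legendre

from .pssm import PSSM

__all__ = [
    "LegendreConfig",
    "LMFeatureVector",
    "legendre_poly",
    "integrated_poly_difference",
    "legendre_moments_exact",
    "legendre_moments_naive",
    "features_to_frame",
    "frame_to_features",
]

_DOMAIN_TOL = 1e-12


@dataclass(frozen=True)
class LegendreConfig:
    """Descriptor configuration.

    max_order is the largest order per axis; the descriptor has
    (max_order + 1)^2 entries, 441 under the default of 20.
    min_max_scale optionally rescales the profile to [0, 1] before the
    moments are taken (off by default: profiles are used as-is).
    """

    max_order: int = 20
    min_max_scale: bool = False

    def __post_init__(self) -> None:
        if self.max_order < 0:
            raise ValueError("max_order must be >= 0")

    @property
    def n_features(self) -> int:
        return (self.max_order + 1) ** 2


@dataclass
class LMFeatureVector:
    """Flat Legendre-moment descriptor of one protein.

    Entry (m, n) sits at flat index m * (max_order + 1) + n (row-major);
    the same layout is used at training and prediction time.
    """

    protein_id: str
    values: np.ndarray = field(repr=False)
    max_order: int = 20

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = (self.max_order + 1) ** 2
        if self.values.size != expected:
            raise ValueError(
                f"descriptor for {self.protein_id!r} has {self.values.size} "
                f"values, expected {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"descriptor for {self.protein_id!r} has non-finite values")

    def moment(self, m: int, n: int) -> float:
        return float(self.values[m * (self.max_order + 1) + n])


def legendre_poly(m: int, x) -> np.ndarray | float:
    """Evaluate the Legendre polynomial V_m at x in [-1, 1].

    Uses the stable three-term recurrence
    (m + 1) V_{m+1} = (2m + 1) x V_m - m V_{m-1}.  The order m = -1 is
    admitted with V_{-1} == 1: the antiderivative identity only ever uses
    V_{-1} inside differences of definite integrals, where any constant
    cancels, and the constant 1 keeps single-cell integrals of V_0 exact.
    """
    if m < -1:
        raise ValueError("order must be >= -1")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + _DOMAIN_TOL):
        raise ValueError("argument outside [-1, 1]")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if m == -1 or m == 0:
        out = np.ones_like(x)
    else:
        prev = np.ones_like(x)   # V_0
        cur = x.copy()           # V_1
        for k in range(1, m):
            prev, cur = cur, ((2 * k + 1) * x * cur - k * prev) / (k + 1)
        out = cur
    return float(out[0]) if scalar else out


def integrated_poly_difference(m: int, a, b) -> np.ndarray | float:
    """Definite integral of V_m over [a, b] within [-1, 1].

    Evaluated through the antiderivative identity
    int_a^b V_m dx = [V_{m+1} - V_{m-1}]_a^b / (2m + 1).
    """
    if m < 0:
        raise ValueError("order must be >= 0")
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr - a_arr < -_DOMAIN_TOL):
        raise ValueError("integration bounds must satisfy a <= b")
    hi = legendre_poly(m + 1, b_arr) - legendre_poly(m - 1, b_arr)
    lo = legendre_poly(m + 1, a_arr) - legendre_poly(m - 1, a_arr)
    return (hi - lo) / (2 * m + 1)


def _cell_edges(n_cells: int) -> np.ndarray:
    """Edges of n_cells equal cells tiling [-1, 1]."""
    return -1.0 + 2.0 * np.arange(n_cells + 1) / n_cells


def _cell_integral_table(n_cells: int, max_order: int) -> np.ndarray:
    """Table I[i, m] = int over cell i of V_m, for m = 0..max_order."""
    edges = _cell_edges(n_cells)
    # clip guards the last edge against accumulated rounding just past 1
    edges = np.clip(edges, -1.0, 1.0)
    table = np.empty((n_cells, max_order + 1))
    for m in range(max_order + 1):
        vals = integrated_poly_difference(m, edges[:-1], edges[1:])
        table[:, m] = vals
    return table


def _as_matrix(pssm: PSSM | np.ndarray) -> tuple[str, np.ndarray]:
    if isinstance(pssm, PSSM):
        return pssm.protein_id, pssm.matrix
    mat = np.asarray(pssm, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return "", mat


def legendre_moments_exact(
    pssm: PSSM | np.ndarray, cfg: LegendreConfig = LegendreConfig()
) -> LMFeatureVector:
    """Legendre moments of a profile, cell-exact.

    The P x Q matrix is laid out cell-centered on [-1, 1]^2 (cell i has
    center x_i = -1 + (i + 1/2) * 2/P and width 2/P; columns likewise)
    and integrated exactly per cell:

        L_mn = mu_mn * sum_ij f(i, j) * Idx_m(i) * Idy_n(j)

    with Idx_m(i) the integral of V_m over cell i.  The per-cell
    integral tables make the cost O(P Q K^2) after O((P + Q) K)
    polynomial evaluations, K = max_order + 1.
    """
    pid, mat = _as_matrix(pssm)
    if cfg.min_max_scale:
        lo, hi = mat.min(), mat.max()
        mat = (mat - lo) / (hi - lo) if hi > lo else np.zeros_like(mat)
    P, Q = mat.shape
    K = cfg.max_order + 1
    Idx = _cell_integral_table(P, cfg.max_order)  # P x K
    Idy = _cell_integral_table(Q, cfg.max_order)  # Q x K
    mu = ((2 * np.arange(K) + 1)[:, None] * (2 * np.arange(K) + 1)[None, :]) / 4.0
    moments = mu * (Idx.T @ mat @ Idy)
    return LMFeatureVector(protein_id=pid, values=moments.ravel(), max_order=cfg.max_order)


def legendre_moments_naive(
    pssm: PSSM | np.ndarray,
    cfg: LegendreConfig = LegendreConfig(),
    points_per_cell: int = 16,
) -> LMFeatureVector:
    """Oracle: dense numerical double integration of the moment integral.

    Integrates V_m(x) V_n(y) f(x, y) over [-1, 1]^2 with per-cell
    Gauss-Legendre quadrature (the image is piecewise constant, so the
    integrand restricted to a cell is a polynomial; 16 nodes per axis
    integrate it essentially to machine precision for orders <= 30).
    Polynomials are evaluated with scipy's eval_legendre, independent of
    the recurrence used by the exact path.  Test oracle — O(P Q K^2 g^2).
    """
    pid, mat = _as_matrix(pssm)
    if cfg.min_max_scale:
        lo, hi = mat.min(), mat.max()
        mat = (mat - lo) / (hi - lo) if hi > lo else np.zeros_like(mat)
    P, Q = mat.shape
    K = cfg.max_order + 1
    nodes, weights = np.polynomial.legendre.leggauss(points_per_cell)

    def quad_table(n_cells: int) -> np.ndarray:
        edges = _cell_edges(n_cells)
        half = (edges[1:] - edges[:-1]) / 2.0
        mid = (edges[1:] + edges[:-1]) / 2.0
        # all quadrature abscissae, cell by cell: (n_cells, g)
        xs = mid[:, None] + half[:, None] * nodes[None, :]
        vand = eval_legendre(np.arange(K)[None, None, :], xs[:, :, None])
        return np.einsum("g,cgm->cm", weights, vand) * half[:, None]

    Idx = quad_table(P)
    Idy = quad_table(Q)
    mu = ((2 * np.arange(K) + 1)[:, None] * (2 * np.arange(K) + 1)[None, :]) / 4.0
    moments = mu * (Idx.T @ mat @ Idy)
    return LMFeatureVector(protein_id=pid, values=moments.ravel(), max_order=cfg.max_order)


def features_to_frame(features: Iterable[LMFeatureVector]) -> pd.DataFrame:
    """Tabulate descriptors: one row per protein, columns named L_m_n."""
    feats = list(features)
    if not feats:
        raise ValueError("no feature vectors given")
    K = feats[0].max_order + 1
    cols = [f"L_{m}_{n}" for m in range(K) for n in range(K)]
    data = np.vstack([f.values for f in feats])
    return pd.DataFrame(data, index=[f.protein_id for f in feats], columns=cols)


def frame_to_features(frame: pd.DataFrame) -> dict[str, LMFeatureVector]:
    """Inverse of :func:`features_to_frame` keyed by protein id."""
    K = int(np.sqrt(frame.shape[1]))
    if K * K != frame.shape[1]:
        raise ValueError("column count is not a perfect square")
    return {
        str(pid): LMFeatureVector(protein_id=str(pid), values=row.to_numpy(), max_order=K - 1)
        for pid, row in frame.iterrows()
    }
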