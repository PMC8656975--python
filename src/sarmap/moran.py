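"""Global and local spatial autocorrelation on tract-level risk maps.

Global Moran's I measures whether smoothed relative risks cluster in space
(expectation -1/(n-1) under spatial randomness); Anselin's local Moran
statistic decomposes it per tract, and the LISA classification labels each
tract high-high / low-low (clusters) or high-low / low-high (spatial
outliers) when its local statistic is significant under conditional
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import AdjacencyGraph

LISA_CLASSES = ("high-high", "low-low", "high-low", "low-high", "not-significant")


@dataclass(frozen=True)
class SpatialWeights:
    """Spatial weights derived from tract contiguity.

    ``binary`` style sets w_ij = 1 on edges; ``row-standardized`` (the
    GeoDa convention for LISA) divides each row by its neighbour count.
    Isolated tracts get a zero weight row.
    """

    tract_ids: tuple[str, ...]
    matrix: sp.csr_matrix
    style: str

    @property
    def n(self) -> int:
        return len(self.tract_ids)

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.matrix.sum())

    @property
    def cardinalities(self) -> np.ndarray:
        return np.asarray((self.matrix != 0).sum(axis=1)).ravel()


def make_weights(graph: AdjacencyGraph, style: str = "row-standardized") -> SpatialWeights:
    """Build binary or row-standardised weights from an adjacency graph."""
    if style not in ("binary", "row-standardized"):
        raise ValueError(f"style must be 'binary' or 'row-standardized', got {style!r}")
    W = graph.adjacency_matrix().astype(float)
    if style == "row-standardized":
        deg = np.asarray(W.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        W = sp.diags(inv) @ W
    islands = graph.isolated_tracts()
    if islands:
        import warnings
        warnings.warn(f"{len(islands)} isolated tract(s) have zero weight rows",
                      stacklevel=2)
    return SpatialWeights(graph.tract_ids, W.tocsr(), style)


def _check_x(x, W: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (W.n,):
        raise ValueError("value vector must match the weight matrix tract set")
    if W.n < 3:
        raise ValueError("need at least 3 tracts")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: Moran statistics undefined for constant values")
    return x


def morans_i(x, W: SpatialWeights) -> float:
    """Global Moran's I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    x = _check_x(x, W)
    z = x - x.mean()
    num = float(z @ (W.matrix @ z))
    return W.n / W.s0 * num / float(z @ z)


def _moran_expectation_variance(x, W: SpatialWeights) -> tuple[float, float]:
    """Moments of I under the randomization (permutation) null."""
    n = W.n
    z = np.asarray(x, float) - np.mean(x)
    Wd = W.matrix
    s0 = W.s0
    A = (Wd + Wd.T)
    s1 = 0.5 * float((A.multiply(A)).sum())
    rc = np.asarray(Wd.sum(axis=1)).ravel() + np.asarray(Wd.sum(axis=0)).ravel()
    s2 = float((rc**2).sum())
    b2 = n * float((z**4).sum()) / float((z**2).sum()) ** 2
    e_i = -1.0 / (n - 1)
    var = (n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
           - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2))
    var /= (n - 1) * (n - 2) * (n - 3) * s0**2
    var -= e_i**2
    return e_i, var


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with permutation (or analytic normal) inference."""

    i: float
    expected_i: float
    z_score: float
    p_value: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None

    def __str__(self):
        return (f"Moran's I = {self.i:.4f} (E[I] = {self.expected_i:.4f}), "
                f"z = {self.z_score:.2f}, p = {self.p_value:.4g} [{self.method}]")


def _permuted_i(x, W: SpatialWeights, n_perm: int, rng) -> np.ndarray:
    z = x - x.mean()
    perms = np.tile(np.arange(W.n), (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    Z = z[perms]                                  # (n_perm, n)
    lag = (W.matrix @ Z.T).T
    num = (Z * lag).sum(axis=1)
    return W.n / W.s0 * num / float(z @ z)


def morans_i_test(x, W: SpatialWeights, n_perm: int = 999, seed: int = 0,
                  method: str = "permutation") -> MoranResult:
    """Test the null of no global spatial autocorrelation.

    Permutation method (default): random relabelling of x over tracts,
    two-sided pseudo p = (#{|I_perm| >= |I_obs|} + 1)/(n_perm + 1), z-score
    against the permutation distribution.  ``method="normal"`` uses the
    analytic randomization moments with a normal reference instead.
    """
    x = _check_x(x, W)
    i_obs = morans_i(x, W)
    e_i = -1.0 / (W.n - 1)
    if method == "normal":
        e, var = _moran_expectation_variance(x, W)
        from scipy.stats import norm
        z = (i_obs - e) / np.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
        return MoranResult(i_obs, e, float(z), float(p), "normal")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    i_perm = _permuted_i(x, W, n_perm, rng)
    p = (np.sum(np.abs(i_perm) >= abs(i_obs)) + 1.0) / (n_perm + 1.0)
    z = (i_obs - i_perm.mean()) / i_perm.std(ddof=1)
    return MoranResult(i_obs, e_i, float(z), float(p), "permutation", n_perm, seed)


def local_moran(x, W: SpatialWeights) -> np.ndarray:
    """Anselin's local Moran I_i = (z_i / m2) * sum_j w_ij z_j.

    z are mean deviations and m2 the population (divide-by-n) variance;
    with row-standardised weights sum_i I_i = n * I (global).
    """
    x = _check_x(x, W)
    z = x - x.mean()
    m2 = float(z @ z) / W.n
    return (z / m2) * (W.matrix @ z)


@dataclass(frozen=True)
class LisaResult:
    """Local Moran statistics with conditional-permutation inference."""

    tract_ids: tuple[str, ...]
    i_local: np.ndarray
    p_value: np.ndarray
    cluster: np.ndarray          # one of LISA_CLASSES per tract
    alpha: float
    n_permutations: int
    seed: int
    fdr: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tract_id": list(self.tract_ids),
            "I_local": self.i_local,
            "pseudo_p": self.p_value,
            "class": self.cluster,
        })

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.cluster == c)) for c in LISA_CLASSES}


def lisa(x, W: SpatialWeights, n_perm: int = 999, alpha: float = 0.05,
         seed: int = 0, fdr: bool = False) -> LisaResult:
    """LISA cluster map: per-tract conditional permutation test + classes.

    For each tract i its own value is held fixed while the remaining n-1
    values are randomly reassigned to its neighbours; the pseudo p-value is
    two-sided (doubled smaller tail rank of the observed I_i among the
    permuted ones, +1 correction).  Significant tracts are classed by the quadrant of
    (z_i, spatial lag of z): high-high / low-low for clusters (I_i > 0),
    high-low / low-high for spatial outliers (I_i < 0).  ``fdr`` applies
    Benjamini-Hochberg across tracts before classification.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x = _check_x(x, W)
    n = W.n
    z = x - x.mean()
    m2 = float(z @ z) / n
    i_obs = (z / m2) * (W.matrix @ z)
    lag = W.matrix @ z

    rng = np.random.default_rng(seed)
    card = W.cardinalities
    k_max = int(card.max()) if n > 0 else 0
    # one permutation table shared across tracts (standard LISA shortcut):
    # each row is a random order of the n-1 "other" positions
    base = np.tile(np.arange(n - 1), (n_perm, 1))
    perm_table = rng.permuted(base, axis=1)[:, :max(k_max, 1)]

    Wl = W.matrix.tolil()
    p = np.ones(n)
    for i in range(n):
        d = int(card[i])
        if d == 0:
            continue  # isolated: statistic undefined, stays not-significant
        others = np.concatenate([z[:i], z[i + 1:]])
        draws = others[perm_table[:, :d]]          # (n_perm, d)
        wrow = np.asarray(Wl.data[i], dtype=float)
        lag_perm = draws @ wrow
        i_perm = (z[i] / m2) * lag_perm
        n_ge = np.sum(i_perm >= i_obs[i])
        n_le = np.sum(i_perm <= i_obs[i])
        # two-sided: double the smaller tail so that under the null the
        # significant fraction is calibrated at alpha rather than 2*alpha
        p[i] = min(1.0, 2.0 * (min(n_ge, n_le) + 1.0) / (n_perm + 1.0))

    p_class = p.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests
        p_class = multipletests(p, alpha=alpha, method="fdr_bh")[1]

    cluster = np.full(n, "not-significant", dtype=object)
    sig = (p_class <= alpha) & (card > 0)
    hh = sig & (z > 0) & (lag > 0)
    ll = sig & (z < 0) & (lag < 0)
    hl = sig & (z > 0) & (lag < 0)
    lh = sig & (z < 0) & (lag > 0)
    cluster[hh] = "high-high"
    cluster[ll] = "low-low"
    cluster[hl] = "high-low"
    cluster[lh] = "low-high"
    return LisaResult(W.tract_ids, i_obs, p, cluster.astype(str), alpha, n_perm,
                      seed, fdr)
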