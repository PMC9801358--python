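"""Spatial weights, global Moran's I, and multicollinearity diagnostics.

The neighborhood unit is a census-tract centroid on a planar grid, so all
weights are built from centroid Euclidean distances (k nearest neighbors,
binary then row-standardized).  Global Moran's I quantifies spatial
autocorrelation of a tract attribute under such a weights matrix;
inference uses a seeded permutation null.  The multicollinearity tools
(VIF and an iterative elimination cascade) reproduce the standard
variance-inflation-factor workflow with a cut-off of 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

from .errors import (
    DegenerateInputError,
    ExhaustionError,
    InvalidConfigError,
    UnderdeterminedDesignError,
)

VIF_CUTOFF = 5.0  # conventional variance-inflation cut-off


@dataclass
class SpatialWeights:
    """A sparse spatial weights matrix aligned to an ordered id list.

    ``matrix`` is n x n CSR with zero diagonal (no self-neighbors).  When
    ``row_standardized`` is set, every non-isolated row sums to 1.
    """

    ids: list[str]
    matrix: sparse.csr_matrix
    row_standardized: bool = True

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise InvalidConfigError("weights matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def neighbors(self, i: int) -> dict[int, float]:
        row = self.matrix.getrow(i).tocoo()
        return dict(zip(row.col.tolist(), row.data.tolist()))

    @classmethod
    def from_neighbors(
        cls,
        ids: list[str],
        neighbor_map: dict[str, list[str]],
        row_standardize: bool = True,
    ) -> "SpatialWeights":
        """Build binary weights from explicit neighbor lists (e.g. rook
        adjacency), optionally row-standardized."""
        index = {t: i for i, t in enumerate(ids)}
        rows, cols = [], []
        for t, nbrs in neighbor_map.items():
            for u in nbrs:
                if u == t:
                    continue
                rows.append(index[t])
                cols.append(index[u])
        data = np.ones(len(rows))
        w = sparse.csr_matrix((data, (rows, cols)), shape=(len(ids), len(ids)))
        if row_standardize:
            w = _row_standardize(w)
        return cls(ids=list(ids), matrix=w, row_standardized=row_standardize)


def _row_standardize(w: sparse.csr_matrix) -> sparse.csr_matrix:
    sums = np.asarray(w.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sparse.diags(inv) @ w


def build_weights(
    tracts: pd.DataFrame,
    k: int = 8,
    symmetrize: bool = False,
    row_standardize: bool = True,
) -> SpatialWeights:
    """k-nearest-neighbor weights on tract-centroid Euclidean distance.

    Binary adjacency to the k nearest neighbors of each centroid, then
    row-standardized (unless disabled).  Exact distance ties are broken by
    tract order in the table, which is the tract_id sort order as written
    by the generator.  ``symmetrize`` ORs the adjacency with its transpose
    before standardizing.
    """
    n = len(tracts)
    if k < 1 or k >= n:
        raise InvalidConfigError(f"k must satisfy 1 <= k < n_tracts (got k={k}, n={n})")
    coords = tracts[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise InvalidConfigError("tract centroids must be finite")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k)
    # drop self wherever it appears (always nearest unless duplicated points)
    cols = np.empty((n, k), dtype=int)
    for i in range(n):
        nbrs = [j for j in idx[i] if j != i][:k]
        if len(nbrs) < k:  # duplicate centroid: self removed elsewhere in list
            nbrs = [j for j in idx[i]][: k + 1]
            nbrs = [j for j in nbrs if j != i][:k]
        cols[i] = nbrs
    w = sparse.csr_matrix(
        (np.ones(n * k), (rows, cols.ravel())), shape=(n, n)
    )
    if symmetrize:
        w = w.maximum(w.T)
    if row_standardize:
        w = _row_standardize(w)
    return SpatialWeights(
        ids=list(tracts["tract_id"].astype(str)),
        matrix=w,
        row_standardized=row_standardize,
    )


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Global Moran's I with a seeded permutation test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the mean
    deviations and S0 the sum of all weights.  The permutation p-value is
    two-sided around the null expectation E[I] = -1/(n-1); a normal
    approximation based on the permutation moments is reported alongside.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 1 or len(z) != weights.n:
        raise InvalidConfigError("values must be 1-D and aligned to the weights ids")
    if not np.all(np.isfinite(z)):
        raise DegenerateInputError("values contain non-finite entries")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise DegenerateInputError("Moran's I undefined for a constant field")
    n = weights.n
    w = weights.matrix
    s0 = float(w.sum())
    scale = n / (s0 * denom)
    i_obs = scale * float(z @ (w @ z))
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        zp = rng.permutation(z)
        perms[b] = scale * float(zp @ (w @ zp))
    dev = abs(i_obs - expected)
    p_perm = (1.0 + np.sum(np.abs(perms - expected) >= dev)) / (n_permutations + 1.0)
    mu, sd = perms.mean(), perms.std(ddof=1)
    zscore = (i_obs - mu) / sd if sd > 0 else np.inf
    p_norm = 2.0 * stats.norm.sf(abs(zscore))
    return {
        "I": i_obs,
        "expected_I": expected,
        "p_value": float(p_perm),
        "p_value_normal": float(p_norm),
        "z_score": float(zscore),
        "n_permutations": n_permutations,
    }


def standardize(design: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score every column (sample sd, ddof=1); returns (Z, mean, sd).

    The returned mean/sd invert the transform:  X = Z * sd + mean.
    """
    means = design.mean()
    sds = design.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise DegenerateInputError(
            f"zero-variance column(s): {', '.join(zero.index)}"
        )
    z = (design - means) / sds
    return z, means, sds


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor of every column.

    VIF_j = 1 / (1 - R^2_j), R^2_j from regressing column j on all the
    others plus an intercept.  Exactly collinear columns report +inf.
    """
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise UnderdeterminedDesignError(
            f"need more rows ({n}) than columns ({p}) for VIF"
        )
    out: dict[str, float] = {}
    cols = list(design.columns)
    for j, name in enumerate(cols):
        y = x[:, j]
        others = np.delete(x, j, axis=1)
        a = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ beta
        ss_res = float(resid @ resid)
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot == 0.0:
            raise DegenerateInputError(f"constant column: {name}")
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


@dataclass
class VifTrace:
    """Record of an iterative VIF elimination cascade."""

    rounds: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)
    cutoff: float = VIF_CUTOFF

    def removed_variables(self) -> list[str]:
        return [v for r in self.rounds for v in r["removed"]]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "rounds": self.rounds,
            "retained": self.retained,
            "final_vifs": self.final_vifs,
        }


def vif_cascade(
    design: pd.DataFrame,
    cutoff: float = VIF_CUTOFF,
    forced_removals: list[str] | None = None,
) -> VifTrace:
    """Iteratively eliminate high-VIF variables until all VIFs < cutoff.

    Each round removes the single highest-VIF variable (ties broken by the
    lexicographically first name); an optional ``forced_removals`` list is
    consumed first, in order, so a published manual elimination sequence
    can be replayed exactly.  Raises if the cascade would empty the design.
    """
    forced = list(forced_removals or [])
    current = design.copy()
    trace = VifTrace(cutoff=cutoff)
    while True:
        vifs = vif(current)
        worst = max(vifs.values())
        if forced:
            target = forced.pop(0)
            if target not in current.columns:
                raise InvalidConfigError(f"forced removal of absent variable {target!r}")
        elif worst >= cutoff:
            top = worst
            candidates = sorted(v for v, val in vifs.items() if val == top)
            target = candidates[0]
        else:
            trace.retained = list(current.columns)
            trace.final_vifs = dict(vifs)
            return trace
        if current.shape[1] <= 1:
            raise ExhaustionError("VIF cascade would remove every variable")
        trace.rounds.append({"vifs": dict(vifs), "removed": [target]})
        current = current.drop(columns=[target])


def correlations(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson and Spearman correlations with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidConfigError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }
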