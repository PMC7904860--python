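"""Cell-to-cell heterogeneity in strand-specific methylation.

Builds cells × regions strand-bias matrices, clusters cells with
k-means (cluster count chosen by mean silhouette score), summarises the
within-cell variance of strand bias, and detects candidate sister-cell
pairs as mutually best, strongly anti-correlated rows — after a
division without maintenance the two daughters inherit complementary
parental strands, so their chromosome-wise biases mirror each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

#: neutral imputation value for masked entries — the maintenance expectation
IMPUTE_F = 0.5


@dataclass
class StrandBiasMatrix:
    """Cells × regions matrix of strand-bias f with missingness mask."""

    values: np.ndarray          # float, NaN where masked
    cells: List[str]
    regions: List[str]
    context: str = "CpG"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.regions)):
            raise ValueError("matrix shape does not match labels")

    @property
    def mask(self) -> np.ndarray:
        """True where the entry is missing/masked."""
        return np.isnan(self.values)

    def imputed(self, fill: float = IMPUTE_F) -> np.ndarray:
        out = self.values.copy()
        out[np.isnan(out)] = fill
        return out

    def row(self, cell: str) -> np.ndarray:
        return self.values[self.cells.index(cell)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.regions)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, context: str = "CpG") -> "StrandBiasMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), context)


def build_matrix(
    records: pd.DataFrame,
    min_regions: int = 3,
    context: Optional[str] = None,
) -> StrandBiasMatrix:
    """Pivot strand-bias records into a cells × regions matrix.

    Masked records (low coverage) and absent (cell, region) pairs become
    NaN.  Cells with fewer than ``min_regions`` unmasked entries are
    dropped with a log entry; an empty result is an error.
    """
    df = records
    contexts = df["context"].unique()
    if context is not None:
        df = df[df["context"] == context]
    elif len(contexts) > 1:
        raise ValueError("records mix contexts; pass an explicit context")
    if df.empty:
        raise ValueError("no strand-bias records to build a matrix from")
    df = df.copy()
    df.loc[df["masked"].astype(bool), "f"] = np.nan
    wide = df.pivot_table(index="cell", columns="region", values="f",
                          aggfunc="mean", observed=True, dropna=False)
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    keep = wide.notna().sum(axis=1) >= min_regions
    dropped = wide.index[~keep]
    if len(dropped):
        logger.info("dropped %d cells with < %d unmasked regions: %s",
                    len(dropped), min_regions, list(dropped))
    wide = wide[keep]
    if wide.empty:
        raise ValueError("no cells retained after min_regions filtering")
    ctx = context if context is not None else str(contexts[0])
    return StrandBiasMatrix.from_frame(wide, context=ctx)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    mean_silhouette: Dict[int, float]
    seed: int
    n_restarts: int
    cells: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.cells, "cluster": self.labels})


def cluster_cells(
    matrix: StrandBiasMatrix,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_restarts: int = 10,
    seed: int = 0,
    features: str = "deviation",
) -> ClusterResult:
    """k-means over strand-bias rows with silhouette-selected k.

    Masked entries are imputed with 0.5 (the maintenance expectation)
    for both the clustering and the silhouette evaluation.

    ``features`` selects the representation the cells are clustered on:

    * ``"deviation"`` (default) — |f - 0.5| per region.  Which strand of
      a chromosome kept the methylation after a division is an arbitrary
      label (the two daughters inherit complementary patterns), so cells
      that lost maintenance form one population only in the magnitude of
      their bias, not in its direction.
    * ``"bias"`` — the raw f matrix.

    If no k in the range yields a defined silhouette (e.g. all cells
    identical), k = 1 is reported with a single cluster.  Deterministic
    for a fixed seed.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in k_range):
        raise ValueError("candidate k values must be >= 2 (k=1 is the fallback)")
    if features not in ("deviation", "bias"):
        raise ValueError("features must be 'deviation' or 'bias'")
    X = matrix.imputed()
    if features == "deviation":
        X = np.abs(X - 0.5)
    n_cells = X.shape[0]
    if max(k_range) > n_cells:
        raise ValueError("k_range exceeds the number of cells")
    sil: Dict[int, float] = {}
    labelings: Dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue  # degenerate: silhouette undefined
        sil[k] = float(silhouette_score(X, labels))
        labelings[k] = labels
    if not sil:
        return ClusterResult(k=1, labels=np.zeros(n_cells, dtype=int),
                             mean_silhouette={}, seed=seed,
                             n_restarts=n_restarts, cells=list(matrix.cells))
    best_k = max(sil, key=lambda k: (sil[k], -k))
    return ClusterResult(k=best_k, labels=labelings[best_k],
                         mean_silhouette=sil, seed=seed,
                         n_restarts=n_restarts, cells=list(matrix.cells))


# ---------------------------------------------------------------------------
# per-cell variance
# ---------------------------------------------------------------------------

def cell_bias_variance(matrix: StrandBiasMatrix,
                       cell: Optional[str] = None):
    """Sample variance of unmasked f values across regions.

    With ``cell`` given returns a float (NaN when fewer than 2 unmasked
    regions); otherwise a Series over all cells.
    """
    def one(row: np.ndarray) -> float:
        vals = row[~np.isnan(row)]
        if vals.size < 2:
            return float("nan")
        return float(np.var(vals, ddof=1))

    if cell is not None:
        return one(matrix.row(cell))
    return pd.Series({c: one(matrix.values[i])
                      for i, c in enumerate(matrix.cells)}, name="bias_variance")


# ---------------------------------------------------------------------------
# sister-cell detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SisterPair:
    cell_a: str
    cell_b: str
    r: float


def _pairwise_r(matrix: StrandBiasMatrix, min_shared: int) -> np.ndarray:
    """Pairwise Pearson r over shared unmasked regions (NaN if < min_shared)."""
    V = matrix.values
    n = V.shape[0]
    R = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(V[i]) & ~np.isnan(V[j])
            if shared.sum() < min_shared:
                continue
            x, y = V[i, shared], V[j, shared]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            R[i, j] = R[j, i] = np.corrcoef(x, y)[0, 1]
    return R


def find_sisters(
    matrix: StrandBiasMatrix,
    r_threshold: float = -0.8,
    min_shared: int = 3,
) -> List[SisterPair]:
    """Detect candidate sister pairs by chromosome-wise anti-correlation.

    A pair is reported iff its Pearson r over shared regions is at most
    ``r_threshold`` and each cell is the other's most-negative partner
    (mutual best).  Conflicts are resolved greedily by ascending r, so
    the result is a matching: no cell appears in two pairs.
    """
    if r_threshold >= 0:
        raise ValueError("r_threshold must be negative")
    R = _pairwise_r(matrix, min_shared)
    n = R.shape[0]
    best = np.full(n, -1, dtype=int)
    for i in range(n):
        row = R[i]
        if np.all(np.isnan(row)):
            continue
        best[i] = int(np.nanargmin(row))
    candidates = []
    for i in range(n):
        j = best[i]
        if j > i and best[j] == i and R[i, j] <= r_threshold:
            candidates.append((R[i, j], i, j))
    candidates.sort()
    used: set = set()
    pairs: List[SisterPair] = []
    for r, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(SisterPair(matrix.cells[i], matrix.cells[j], float(r)))
    return pairs
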