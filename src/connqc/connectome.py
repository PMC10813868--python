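"""Individual and group-level connectome construction.

Structural connectomes (SC) carry relative tract volume (tract voxels x voxel
volume / ICV) for region pairs joined by at least two tracts; functional
connectomes (FC) carry nuisance-adjusted Pearson correlations of regional
BOLD time-series with negative values clipped to zero. Group-averaged
consensus connectomes are proportionally thresholded (default sparsity 0.80)
and the resulting edge mask is applied to every individual connectome before
graph analysis. Overall connectivity — the mean over all region-pair weights,
zeros included — is computed on the *unmasked* individual connectome and is
therefore sparsity-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def _check_square_symmetric(W: np.ndarray, name: str = "weights") -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    return W


@dataclass
class Connectome:
    """Symmetric nonnegative region-by-region edge-weight matrix.

    ``hemispheres`` tags each region 'L'/'R'; the default assigns odd region
    labels (1-based) to the left hemisphere.
    """

    weights: np.ndarray
    modality: str = "SC"
    region_labels: np.ndarray = field(default=None)
    hemispheres: np.ndarray = field(default=None)
    validate: bool = True

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if self.validate:
            W = _check_square_symmetric(W)
            if np.any(np.diag(W) != 0):
                raise ValueError("diagonal (self-self connections) must be zero")
            if np.any(W < 0):
                raise ValueError("edge weights must be nonnegative")
            if self.modality == "FC" and np.any(W > 1):
                raise ValueError("FC weights must lie in [0, 1]")
        self.weights = W
        n = W.shape[0]
        if self.region_labels is None:
            self.region_labels = np.arange(1, n + 1)
        if self.hemispheres is None:
            self.hemispheres = np.array(["L" if r % 2 == 1 else "R"
                                         for r in self.region_labels])

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2


@dataclass
class EdgeMask:
    """Binary symmetric edge-retention mask with zero diagonal."""

    edges: np.ndarray
    validate: bool = True

    def __post_init__(self):
        E = np.asarray(self.edges, dtype=bool)
        if self.validate:
            _check_square_symmetric(E.astype(float), "edges")
            if np.any(np.diag(E)):
                raise ValueError("mask diagonal must be zero")
        self.edges = E

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.edges, 1).sum())

    @property
    def sparsity(self) -> float:
        n = self.edges.shape[0]
        return 1.0 - self.n_edges / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_sc(tract_volumes: Iterable[tuple], voxel_volume: float, icv: float,
             n_regions: int = 94, min_tracts: int = 2) -> Connectome:
    """Structural connectome from per-pair tract summaries.

    ``tract_volumes`` yields ``(region_i, region_j, n_tracts,
    total_tract_voxels)`` with 1-based region indices. Pairs connected by
    fewer than ``min_tracts`` tracts get weight zero; otherwise the weight is
    the relative tract volume ``total_tract_voxels * voxel_volume / icv``.
    """
    if icv <= 0 or voxel_volume <= 0:
        raise ValueError("icv and voxel_volume must be positive")
    W = np.zeros((n_regions, n_regions))
    for i, j, n_tracts, voxels in tract_volumes:
        i, j = int(i), int(j)
        if n_tracts < 0 or voxels < 0:
            raise ValueError(f"negative counts for pair ({i}, {j})")
        if i == j:
            if voxels > 0:
                raise ValueError(f"self-connection with nonzero volume at region {i}")
            continue
        if not (1 <= i <= n_regions and 1 <= j <= n_regions):
            raise ValueError(f"region index out of range: ({i}, {j})")
        if n_tracts >= min_tracts:
            w = voxels * voxel_volume / icv
            W[i - 1, j - 1] = W[j - 1, i - 1] = w
    return Connectome(W, modality="SC")


def build_fc(timeseries: np.ndarray, nuisance: np.ndarray) -> Connectome:
    """Functional connectome from regional time-series.

    Each region's series (column of ``timeseries``, T x p) is residualized by
    OLS on the nuisance series (T x k; typically 6 motion parameters plus CSF
    and WM means) and an intercept; the edge weight is the Pearson correlation
    of the residual pair, with negative correlations set to zero. Regions
    whose residual series is constant produce undefined correlations; those
    edges are set to zero and counted in ``fc.n_undefined``.
    """
    Y = np.asarray(timeseries, dtype=float)
    X = np.asarray(nuisance, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T, p = Y.shape
    if X.shape[0] != T:
        raise ValueError("time-series and nuisance lengths differ")
    k = X.shape[1]
    if T <= k + 1:
        raise ValueError(f"need more time points ({T}) than nuisance regressors + 1 ({k + 1})")

    D = np.column_stack([np.ones(T), X])
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    R = Y - D @ beta

    sd = R.std(axis=0, ddof=1)
    ok = sd > 1e-12
    Rn = np.zeros_like(R)
    Rn[:, ok] = (R[:, ok] - R[:, ok].mean(axis=0)) / sd[ok]
    C = (Rn.T @ Rn) / (T - 1)
    C = np.clip(C, 0.0, 1.0)
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.fill_diagonal(C, 0.0)
    C = (C + C.T) / 2
    fc = Connectome(C, modality="FC")
    fc.n_undefined = int((~ok).sum()) * (p - 1)  # edges touching a constant residual
    return fc


# ---------------------------------------------------------------------------
# group-level operations
# ---------------------------------------------------------------------------

def overall_connectivity(c: Connectome | np.ndarray) -> float:
    """Mean over all off-diagonal region pairs (zeros included), pre-masking."""
    W = c.weights if isinstance(c, Connectome) else np.asarray(c, float)
    iu = np.triu_indices(W.shape[0], 1)
    return float(W[iu].mean())


def group_average(connectomes: Iterable[Connectome | np.ndarray],
                  binarize: bool = True) -> Connectome:
    """Group-averaged consensus connectome.

    ``binarize=True`` (SC convention): each edge value is the *prevalence* —
    the fraction of participants with nonzero weight. ``binarize=False``
    (FC convention): mean weight across participants.
    """
    total = None
    count = 0
    modality = "SC" if binarize else "FC"
    for c in connectomes:
        W = c.weights if isinstance(c, Connectome) else np.asarray(c, float)
        contrib = (W > 0).astype(float) if binarize else W
        if total is None:
            total = contrib.copy()
        else:
            if contrib.shape != total.shape:
                raise ValueError("connectome shapes differ")
            total += contrib
        count += 1
    if count < 2:
        raise ValueError("need at least two connectomes")
    return Connectome(total / count, modality=modality, validate=False)


def proportional_threshold(group: Connectome | np.ndarray, sparsity: float) -> EdgeMask:
    """Retain the top ``(1 - sparsity)`` fraction of edges of a group connectome.

    K = round((1 - sparsity) * n_pairs) edges with the largest group values
    are kept (round-half-to-even). Ties are broken deterministically: larger
    group value first, then lexicographic (i, j) region order. For 94 regions
    at the default sparsity 0.80 this retains exactly 874 edges.
    """
    W = group.weights if isinstance(group, Connectome) else np.asarray(group, float)
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    n = W.shape[0]
    iu = np.triu_indices(n, 1)
    n_pairs = iu[0].size
    K = round((1.0 - sparsity) * n_pairs)
    if K == 0:
        raise ValueError(f"sparsity {sparsity} retains zero edges (degenerate network)")
    vals = W[iu]
    order = np.lexsort((iu[1], iu[0], -vals))  # value desc, then (i, j) asc
    keep = order[:K]
    E = np.zeros((n, n), dtype=bool)
    E[iu[0][keep], iu[1][keep]] = True
    return EdgeMask(E | E.T, validate=False)


def prevalence_threshold(group: Connectome | np.ndarray, min_prevalence: float = 0.8) -> EdgeMask:
    """Alternative consensus rule: keep edges with group value >= ``min_prevalence``.

    A literal at-least-80%-of-participants cut; unlike proportional
    thresholding the retained edge count is data-dependent.
    """
    W = group.weights if isinstance(group, Connectome) else np.asarray(group, float)
    E = np.triu(W >= min_prevalence, 1)
    return EdgeMask(E | E.T, validate=False)


def apply_group_mask(c: Connectome, mask: EdgeMask) -> Connectome:
    """Zero all weights outside the consensus mask (weights inside untouched)."""
    if c.weights.shape != mask.edges.shape:
        raise ValueError("connectome and mask shapes differ")
    return Connectome(np.where(mask.edges, c.weights, 0.0), modality=c.modality,
                      region_labels=c.region_labels, hemispheres=c.hemispheres,
                      validate=False)


def interhemispheric_fraction(mask: EdgeMask, hemispheres: Sequence[str] | None = None) -> float:
    """Fraction of retained edges linking opposite hemispheres."""
    n = mask.edges.shape[0]
    if hemispheres is None:
        hemispheres = np.array(["L" if r % 2 == 1 else "R" for r in range(1, n + 1)])
    h = np.asarray(hemispheres)
    iu = np.triu_indices(n, 1)
    kept = mask.edges[iu]
    total = int(kept.sum())
    if total == 0:
        return 0.0
    inter = (h[iu[0]] != h[iu[1]]) & kept
    return float(inter.sum() / total)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def connectome_to_csv(c: Connectome, path) -> None:
    pd.DataFrame(c.weights, index=c.region_labels, columns=c.region_labels).to_csv(path)


def connectome_from_csv(path, modality: str = "SC") -> Connectome:
    df = pd.read_csv(path, index_col=0)
    return Connectome(df.to_numpy(float), modality=modality,
                      region_labels=df.index.to_numpy(int))


def edgelist(c: Connectome) -> pd.DataFrame:
    """Nonzero upper-triangle edges as an (i, j, weight) table (1-based labels)."""
    iu = np.triu_indices(c.n_regions, 1)
    w = c.weights[iu]
    nz = w > 0
    return pd.DataFrame({
        "i": c.region_labels[iu[0][nz]],
        "j": c.region_labels[iu[1][nz]],
        "weight": w[nz],
    })
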