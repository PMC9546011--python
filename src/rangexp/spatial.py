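"""Individual-level genetic and geographic distances, Mantel IBD tests, NJ trees.

Isolation by distance (IBD) is tested by correlating pairwise genetic distances
(Edwards' angular distance or identity-by-state) against great-circle
geographic distances with a one-sided Mantel permutation test. Neighbour
joining provides a quick distance-based summary tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .genotypes import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class DistanceMatrix:
    """Labelled symmetric distances; NaN marks pairs with no shared information."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "edwards" | "ibs" | "geographic_km" | ...

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = ~np.isnan(self.values)
        if not np.allclose(self.values[finite & finite.T],
                           self.values.T[finite & finite.T], atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("distances must be non-negative")

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = np.array([self.labels.index(l) for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Genetic distances


def _pairwise(gm: GenotypeMatrix, fn, kind: str) -> DistanceMatrix:
    n = gm.n_samples
    d = np.zeros((n, n))
    obs = gm.calls != MISSING
    for x in range(n):
        for y in range(x + 1, n):
            shared = obs[x] & obs[y]
            if not shared.any():
                d[x, y] = d[y, x] = np.nan
                continue
            d[x, y] = d[y, x] = fn(gm.calls[x, shared], gm.calls[y, shared])
    return DistanceMatrix(list(gm.sample_ids), d, kind)


def edwards_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Edwards' angular distance between individuals.

    Each individual is treated as a two-gene-copy population with allele
    frequencies in {0, 1/2, 1}; over the L loci genotyped in both,
    ``D = sqrt(1 - (1/L) * sum_l sum_alleles sqrt(p_x * p_y))``.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")

    def fn(gx, gy):
        px = gx / 2.0
        py = gy / 2.0
        sim = np.sqrt(px * py) + np.sqrt((1 - px) * (1 - py))
        return float(np.sqrt(max(0.0, 1.0 - sim.mean())))

    return _pairwise(gm, fn, "edwards")


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - identity-by-state: mean |g_x - g_y| / 2 over loci genotyped in both."""
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")

    def fn(gx, gy):
        return float(np.abs(gx.astype(float) - gy).mean() / 2.0)

    return _pairwise(gm, fn, "ibs")


EARTH_RADIUS_KM = 6371.0


def geographic_distance(popmap: PopulationMap, samples: list[str] | None = None) -> DistanceMatrix:
    """Haversine great-circle distances (km) between sample coordinates."""
    if samples is None:
        samples = [s for s in popmap.populations if s in popmap.coordinates]
    coords = []
    for s in samples:
        if s not in popmap.coordinates:
            raise ValueError(f"no coordinates for sample {s!r}")
        coords.append(popmap.coordinates[s])
    lat = np.radians([c[0] for c in coords])
    lon = np.radians([c[1] for c in coords])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(samples), d, "geographic_km")


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int


def mantel_test(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (greater) Mantel test of matrix association.

    r is the Pearson correlation of corresponding off-diagonal entries; the
    null distribution jointly permutes rows and columns of the second matrix;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if set(genetic.labels) != set(geographic.labels):
        raise ValueError("distance matrices must share the same label set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    geo = geographic.reorder(genetic.labels)
    n = len(genetic.labels)
    iu = np.triu_indices(n, k=1)
    x = genetic.values[iu]
    y = geo.values[iu]
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("Mantel test requires complete distance matrices")
    r_obs = float(pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    xm = genetic.values
    n_ge = 0
    sy = y - y.mean()
    sy_norm = np.sqrt((sy**2).sum())
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = xm[np.ix_(perm, perm)][iu]
        sx = xp - xp.mean()
        r_perm = float((sx * sy).sum() / (np.sqrt((sx**2).sum()) * sy_norm))
        if r_perm >= r_obs:
            n_ge += 1
    return MantelResult(r_obs, (1 + n_ge) / (1 + n_perm), n_perm, seed)


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class PhyloTree:
    """Unrooted NJ tree; negative branch lengths are clamped to zero."""

    tree: object  # skbio TreeNode
    negative_clamped: bool = False

    def newick(self) -> str:
        return str(self.tree)

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining on a labelled distance matrix."""
    if len(d.labels) < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if np.isnan(d.values).any():
        raise ValueError("neighbour joining requires a complete matrix")
    dm = _SkbioDM(d.values, ids=d.labels)
    raw = _skbio_nj(dm)
    clamped = False
    for node in raw.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return PhyloTree(raw, negative_clamped=clamped)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")
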