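"""Population structure: IBS distances, pairwise Fst, NJ trees, PCA.

Distances feed a Saitou-Nei neighbor-joining tree (Studier-Keppler
Q-criterion, deterministic tie-breaks); PCA uses the GCTA convention of
frequency-standardized genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, GenotypePanel, PopulationMap
from .selection import wc_site_terms

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labels and zero diagonal."""

    labels: list[str]
    values: np.ndarray
    raw: np.ndarray | None = None  # pre-flooring values where applicable

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


# ----------------------------------------------------------------------
def ibs_distance(panel: GenotypePanel) -> DistanceMatrix:
    """1 - identity-by-state similarity between all sample pairs.

    Per pair, similarity = shared allele count / (2 x sites called in
    both); a site missing in either sample is excluded.  With dosages
    g_i, g_j the shared allele count at one site is ``2 - |g_i - g_j|``.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    g = panel.genotypes.astype(np.int64)
    called = g != MISSING
    n = panel.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {panel.samples[i]!r} and {panel.samples[j]!r} share "
                    f"no co-called sites"
                )
            shared = (2 - np.abs(g[i, both] - g[j, both])).sum()
            d[i, j] = d[j, i] = 1.0 - shared / (2.0 * m)
    return DistanceMatrix(list(panel.samples), d)


def pairwise_fst_matrix(panel: GenotypePanel, pops: PopulationMap) -> DistanceMatrix:
    """Genome-wide Weir-Cockerham Fst between every breed pair.

    Each pair's value is the ratio-of-sums estimator over all sites.
    For distance use, negative genome-wide values are floored at zero;
    the raw values are kept on the ``raw`` attribute.
    """
    pops.validate_against(panel)
    breeds = pops.breeds()
    if len(breeds) < 2:
        raise ValueError("need at least two breeds")
    idx = {}
    for b in breeds:
        bi = pops.indices(panel, b)
        if len(bi) < 2:
            raise ValueError(f"breed {b!r} has n={len(bi)} < 2 samples")
        idx[b] = bi
    k = len(breeds)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            num, den, _ = wc_site_terms(panel, idx[breeds[i]], idx[breeds[j]])
            ok = np.isfinite(num) & np.isfinite(den)
            denom = den[ok].sum()
            raw[i, j] = raw[j, i] = num[ok].sum() / denom if denom > 0 else np.nan
    return DistanceMatrix(breeds, np.maximum(raw, 0.0), raw=raw)


# ----------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Node of an unrooted NJ tree, stored with an arbitrary trifurcating root."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for ch, _ in self.children:
            out.extend(ch.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{ch._newick()}:{bl:.10g}" for ch, bl in self.children)
        return f"({inner})"

    def splits(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as frozensets of one side)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset] = set()

        def walk(node: "TreeNode"):
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for ch, _ in node.children:
                sub = walk(ch)
                if 1 < len(sub) < len(all_leaves) - 1:
                    out.add(min(sub, all_leaves - sub, key=sorted))
                below = below | sub
            return below

        walk(self)
        return out


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-matrix.

    Ties in Q are broken by the (lexicographically smallest) pair of
    current node labels, so the result is deterministic.  Negative branch
    lengths are clamped to zero with a log message.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least three labels for a tree")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    names: list[str] = list(dm.labels)
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        pairs = sorted(
            (tuple(sorted((names[i], names[j]))), i, j)
            for i, j in ties if i < j
        )
        _, i, j = pairs[0]
        li_raw = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        li = clamp(li_raw)
        lj = clamp(d[i, j] - li_raw)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_name = f"({min(names[i], names[j])})"
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [new_name]

    # final trifurcation: three-point formulas
    (a, b, c) = (0, 1, 2)
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    if clamped:
        logger.info("neighbor_joining: clamped %d negative branch lengths to 0", clamped)
    return root


# ----------------------------------------------------------------------
def pca(panel: GenotypePanel, n_components: int = 10):
    """PCA of the frequency-standardized genotype matrix (GCTA convention).

    Monomorphic sites are dropped; each remaining site is centered at
    2p and scaled by sqrt(2p(1-p)); missing genotypes are mean-imputed
    (zero after centering).  Returns ``(coords, explained_variance_fractions)``
    with components ordered by decreasing eigenvalue and the sign of each
    component fixed so its largest-magnitude coordinate is positive.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < n_components:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic sites for {n_components} components"
        )
    x = g[:, poly]
    p = p[poly]
    x = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[~np.isfinite(x)] = 0.0  # mean imputation of missing genotypes
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2
    coords = u[:, :n_components] * s[:n_components]
    for k in range(coords.shape[1]):
        jmax = int(np.argmax(np.abs(coords[:, k])))
        if coords[jmax, k] < 0:
            coords[:, k] = -coords[:, k]
    evr = eig[:n_components] / eig.sum()
    return coords, evr
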