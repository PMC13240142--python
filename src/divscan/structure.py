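"""Population-structure summaries: shared-allele p-distances, neighbor
joining with Newick output, genotype PCA, and a DAPC-style procedure
(PCA reduction -> k-means elbow -> linear discriminants)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix has nonzero diagonal")

    def to_phylip(self, path: str) -> None:
        """PHYLIP square format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                name = lab.replace(" ", "_")
                fh.write(name + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; children carry their branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at the final NJ join (a trifurcation)."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (for additivity checks)."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def below(node: TreeNode, dist: float) -> list[tuple[int, float]]:
            if node.is_leaf:
                return [(index[node.name], dist)]
            out = []
            for child, bl in node.children:
                out.extend(below(child, dist + bl))
            return out

        def walk(node: TreeNode) -> None:
            groups = [below(child, bl) for child, bl in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            d[i, j] = d[j, i] = di + dj
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return DistanceMatrix(labels=names, d=d)


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    explained_variance: np.ndarray  # fraction per component
    loadings: np.ndarray  # sites x components


@dataclass
class DapcResult:
    k: int
    assignments: np.ndarray
    wcss: dict[int, float]
    n_components: int
    discriminant_scores: np.ndarray | None


# ---------------------------------------------------------------------------
# p-distance


def p_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """d(i, j) = 1 - mean shared-allele fraction over co-called sites.

    The shared-allele fraction of two diploid dosages g, h is
    1 - |g - h| / 2 (multiset allele overlap / 2). Symmetric and zero on
    identical samples; the triangle inequality is not guaranteed when
    missingness patterns differ between pairs.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = gm.calls.astype(np.float64)
    called = gm.calls != MISSING
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share "
                    "no co-called sites"
                )
            dist = float(np.abs(calls[i, both] - calls[j, both]).sum()) / (2.0 * m)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=list(gm.samples), d=d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration.

    Joins the active pair minimizing the Q-criterion (ties broken by the
    lexicographically smallest index pair in node-creation order), computes
    branch lengths by the rate-corrected formulas, and stops at the final
    three-node trifurcation. Negative branch lengths are clamped to zero with
    the deficit shifted to the sister branch, preserving their sum.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))
    d = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i < j}

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = dist(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        u = len(nodes)
        nodes.append(TreeNode(children=[(nodes[i], li), (nodes[j], lj)]))
        new_d = {}
        for k in active:
            if k in (i, j):
                continue
            new_d[k] = (dist(i, k) + dist(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]
        for k, v in new_d.items():
            d[(min(k, u), max(k, u))] = v

    i, j, k = active
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return PhyloTree(root=root)


def _newick_label(name: str, quote_spaces: bool) -> str:
    if " " in name:
        return f"'{name}'" if quote_spaces else name.replace(" ", "_")
    return name


def to_newick(tree: PhyloTree, quote_spaces: bool = False) -> str:
    """Standard Newick with branch lengths and terminating semicolon."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.name, quote_spaces)
        inner = ",".join(
            f"{render(child)}:{bl:.10g}" for child, bl in node.children
        )
        return f"({inner})"

    return render(tree.root) + ";"


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, canonicalized as the side NOT
    containing the lexicographically smallest leaf name."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    parts: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            parts.add(below if anchor not in below else all_leaves - below)
        return below

    for child, _ in tree.root.children:
        walk(child)
    return parts


def nj_bootstrap_support(
    gm: GenotypeMatrix, n_replicates: int = 100, seed: int = 0
) -> dict[frozenset[str], float]:
    """Site-resampling bootstrap support for the NJ tree's bipartitions."""
    base = bipartitions(neighbor_joining(p_distance_matrix(gm)))
    counts = dict.fromkeys(base, 0)
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, gm.n_sites, size=gm.n_sites)
        rep = gm.take_sites(np.sort(idx))
        for part in bipartitions(neighbor_joining(p_distance_matrix(rep))):
            if part in counts:
                counts[part] += 1
    return {part: c / n_replicates for part, c in counts.items()}


# ---------------------------------------------------------------------------
# PCA / DAPC


def _imputed_dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(mean-imputed float dosage matrix, per-site allele frequency)."""
    calls = gm.calls.astype(np.float64)
    missing = gm.calls == MISSING
    with np.errstate(invalid="ignore"):
        site_mean = np.where(missing, 0.0, calls).sum(axis=0) / np.maximum(
            (~missing).sum(axis=0), 1
        )
    x = np.where(missing, site_mean[None, :], calls)
    return x, site_mean / 2.0


def genotype_pca(gm: GenotypeMatrix, scaling: str = "none") -> PcaResult:
    """PCA of the (mean-imputed, centered) dosage matrix.

    Under ``patterson`` scaling each site is divided by sqrt(p(1-p)) with p
    its allele frequency. Deterministic up to component sign. Monomorphic
    sites carry zero variance and are excluded from the decomposition.
    """
    if scaling not in ("none", "patterson"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x, p = _imputed_dosage(gm)
    poly = x.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic sites")
    x = x[:, poly]
    x = x - x.mean(axis=0, keepdims=True)
    if scaling == "patterson":
        pp = p[poly]
        x = x / np.sqrt(pp * (1.0 - pp))[None, :]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s > 1e-12 * (s[0] if s.size else 1.0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    var = s**2
    return PcaResult(
        scores=u * s,
        explained_variance=var / var.sum(),
        loadings=vt.T,
    )


def _elbow_k(wcss: dict[int, float], min_drop: float = 0.30) -> int:
    """Maximum-curvature (second-difference) elbow over the WCSS curve.

    When the total relative WCSS drop from k=1 to k=2 is below ``min_drop``
    there is no meaningful elbow and k=1 is returned (curvature needs
    interior points, so the homogeneous case must be handled explicitly).
    """
    ks = sorted(wcss)
    if len(ks) == 1:
        return ks[0]
    w = np.asarray([wcss[k] for k in ks])
    if w[0] <= 0:
        return ks[0]
    if 1 in wcss and (w[0] - w[1]) / w[0] < min_drop:
        return 1
    if len(ks) < 3:
        return ks[-1] if (w[0] - w[-1]) / w[0] >= min_drop else ks[0]
    curv = w[:-2] - 2.0 * w[1:-1] + w[2:]
    return ks[1 + int(np.argmax(curv))]


def dapc_lite(
    gm: GenotypeMatrix,
    var_retained: float = 0.95,
    k_max: int = 4,
    seed: int = 0,
    elbow_min_drop: float = 0.30,
) -> DapcResult:
    """PCA retaining ``var_retained`` of the variance, k-means over
    k = 1..k_max with the elbow rule, then LDA on the retained components
    against the chosen clusters (skipped when k = 1)."""
    if k_max >= gm.n_samples:
        raise ValueError(f"k_max {k_max} must be < n_samples {gm.n_samples}")
    pca = genotype_pca(gm)
    cum = np.cumsum(pca.explained_variance)
    n_comp = int(np.searchsorted(cum, var_retained) + 1)
    n_comp = min(n_comp, pca.scores.shape[1])
    x = pca.scores[:, :n_comp]

    wcss: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    centered = x - x.mean(axis=0, keepdims=True)
    wcss[1] = float((centered**2).sum())
    labels[1] = np.zeros(gm.n_samples, dtype=int)
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        wcss[k] = float(km.inertia_)
        labels[k] = km.labels_
    k_best = _elbow_k(wcss, min_drop=elbow_min_drop)

    scores = None
    if k_best > 1:
        lda = LinearDiscriminantAnalysis(
            n_components=min(k_best - 1, n_comp)
        ).fit(x, labels[k_best])
        scores = lda.transform(x)
    return DapcResult(
        k=k_best,
        assignments=labels[k_best],
        wcss=wcss,
        n_components=n_comp,
        discriminant_scores=scores,
    )
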