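"""Jukes-Cantor distances, neighbor joining, bootstrap, JC likelihood.

The whole-alignment phylogeny stage: pairwise p-distances (pairwise
deletion of gap/N sites) corrected under the one-parameter Jukes-Cantor
model, d = -(3/4) ln(1 - (4/3) p); neighbor-joining topology search with
deterministic tie-breaking; non-parametric bootstrap of alignment columns
with supports attached to bipartitions of the full-data tree; and
Felsenstein-pruning log-likelihood under JC (uniform base frequencies,
single rate) for ranking fixed topologies.  NJ search plus JC likelihood
scoring stands in for a full maximum-likelihood topology search: both
halves are exactly specified and independently testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import NoComparableSitesError, PlastomicsError, SaturationError
from .io import MultipleAlignment

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, pairwise deletion of non-ACGT sites."""
    if len(a) != len(b):
        raise PlastomicsError("sequences must be equally long (aligned)")
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    bases = np.array([b"A", b"C", b"G", b"T"])
    ok = np.isin(x, bases) & np.isin(y, bases)
    n = int(ok.sum())
    if n == 0:
        raise NoComparableSitesError("no site with unambiguous bases in both")
    return float((x[ok] != y[ok]).sum() / n)


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise PlastomicsError("p must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond the JC ceiling of 3/4")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jc_expected_p(d: float) -> float:
    """Expected p-distance after evolving for d substitutions/site."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise PlastomicsError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise PlastomicsError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any():
            raise PlastomicsError("distance matrix must have a zero diagonal")
        if not np.isfinite(m).all():
            raise PlastomicsError("distances must be finite")
        self.matrix = m


def jc_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    n = aln.n_rows
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jc_correct(p_distance(aln.rows[i], aln.rows[j]))
    return DistanceMatrix(list(aln.ids), m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The minimal Q entry is chosen in row-major index order; negative
    branch lengths are clamped to zero.  Returns an unrooted tree (the
    seed node is the final trifurcation).
    """
    n = len(dm.ids)
    if n < 3:
        raise PlastomicsError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = [
        dendropy.Node(taxon=taxa.get_taxon(label=name)) for name in dm.ids
    ]
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (k - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major order => smallest indices win ties
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        new_index = d.shape[0]
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_index, : new_index] = new_row
        d[: new_index, new_index] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [new_index]

    root = dendropy.Node()
    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (the side not
    containing the lexicographically smallest label, for a canonical form)."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        if anchor in side:
            side = frozenset(leaves - side)
        out.add(side)
    return out


@dataclass
class SupportTree:
    """Full-data tree plus bootstrap support per non-trivial bipartition."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_valid: int
    degenerate: bool = False

    def newick(self, hide_below: float | None = 70.0) -> str:
        """Newick with supports as internal-node labels; supports under
        ``hide_below`` (the usual 70% display convention) are omitted."""
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        anchor = min(leaves) if leaves else ""
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node is self.tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if anchor in side:
                side = frozenset(leaves - side)
            support = self.supports.get(side)
            if support is not None and (
                hide_below is None or support >= hide_below
            ):
                node.label = f"{support:.0f}"
            else:
                node.label = None
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"


def bootstrap_support(
    aln: MultipleAlignment,
    replicates: int = 100,
    seed: int | None = None,
) -> SupportTree:
    """NJ tree with column-bootstrap supports on its bipartitions.

    Columns are resampled with replacement per replicate; replicates where
    some pair has no comparable site (or is saturated) are discarded and
    logged.  An alignment of identical sequences yields a degenerate star
    with no defined supports.
    """
    rng = np.random.default_rng(seed)
    try:
        full_dm = jc_distance_matrix(aln)
    except (SaturationError, NoComparableSitesError) as exc:
        raise PlastomicsError(f"full-data distances unavailable: {exc}") from exc

    if np.allclose(full_dm.matrix, 0.0):
        taxa = dendropy.TaxonNamespace(aln.ids)
        root = dendropy.Node()
        for name in aln.ids:
            leaf = dendropy.Node(taxon=taxa.get_taxon(label=name))
            root.add_child(leaf)
            leaf.edge.length = 0.0
        star = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        star.is_rooted = False
        return SupportTree(star, {}, replicates, 0, degenerate=True)

    full_tree = neighbor_joining(full_dm)
    target = _bipartitions(full_tree)
    counts = {bp: 0 for bp in target}
    arr = aln.to_array()
    n_cols = aln.n_cols
    n_valid = 0
    for rep in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = arr[:, cols]
        rows = [sub[i].tobytes().decode("ascii") for i in range(aln.n_rows)]
        rep_aln = MultipleAlignment(list(aln.ids), rows)
        try:
            rep_tree = neighbor_joining(jc_distance_matrix(rep_aln))
        except (SaturationError, NoComparableSitesError) as exc:
            log.warning("bootstrap replicate %d discarded: %s", rep, exc)
            continue
        n_valid += 1
        rep_bips = _bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bips:
                counts[bp] += 1
    supports = (
        {bp: 100.0 * c / n_valid for bp, c in counts.items()} if n_valid else {}
    )
    return SupportTree(full_tree, supports, replicates, n_valid)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _jc_transition(t: float) -> np.ndarray:
    """JC transition probability matrix over branch length t."""
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def jc_log_likelihood(tree: dendropy.Tree, aln: MultipleAlignment) -> float:
    """Felsenstein-pruning log-likelihood under Jukes-Cantor.

    Uniform base frequencies, a single rate, complete deletion of columns
    containing anything but A/C/G/T.  Invariant under re-rooting (the
    pulley principle), so unrooted trees score identically however the
    seed node is placed.
    """
    leaf_labels = sorted(
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon
    )
    if leaf_labels != sorted(aln.ids):
        raise PlastomicsError(
            f"tree leaves {leaf_labels} do not match alignment ids "
            f"{sorted(aln.ids)}"
        )
    arr = aln.to_array()
    bases = np.array([b"A", b"C", b"G", b"T"])
    ok = np.isin(arr, bases).all(axis=0)
    if not ok.any():
        raise NoComparableSitesError("no gap-free column to score")
    sub = arr[:, ok]
    codes = np.searchsorted(bases, sub)
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    n_pat = patterns.shape[1]
    row_of = {sid: i for i, sid in enumerate(aln.ids)}

    def partial(node) -> np.ndarray:
        if node.is_leaf():
            L = np.zeros((n_pat, 4))
            L[np.arange(n_pat), patterns[row_of[node.taxon.label]]] = 1.0
            return L
        L = np.ones((n_pat, 4))
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if t < 0:
                raise PlastomicsError("negative branch length")
            L *= partial(child) @ _jc_transition(t).T
        return L

    site_lik = partial(tree.seed_node).mean(axis=1)  # uniform 1/4 prior
    if (site_lik <= 0).any():
        return float("-inf")
    return float((counts * np.log(site_lik)).sum())


def rank_topologies(
    trees: list[dendropy.Tree], aln: MultipleAlignment
) -> list[tuple[float, dendropy.Tree]]:
    """Score fixed topologies by JC log-likelihood, best first."""
    scored = [(jc_log_likelihood(t, aln), t) for t in trees]
    scored.sort(key=lambda st: -st[0])
    return scored
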