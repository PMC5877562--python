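"""Distances, NJ, bootstrap, pruning likelihood, against independent oracles."""

import itertools

import dendropy
import numpy as np
import pytest

import plastomics as pk
from plastomics.errors import (
    NoComparableSitesError,
    PlastomicsError,
    SaturationError,
)
from plastomics.io import MultipleAlignment
from plastomics.phylogeny import (
    DistanceMatrix,
    _bipartitions,
    _jc_transition,
    jc_log_likelihood,
)


def _tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def test_p_distance_pairwise_deletion():
    assert pk.p_distance("ACGT", "ACGT") == 0.0
    assert pk.p_distance("ACGT", "ACGA") == 0.25
    # gap and N sites excluded from the denominator
    assert pk.p_distance("AC-TN", "ACGTA") == 0.0
    with pytest.raises(NoComparableSitesError):
        pk.p_distance("----", "ACGT")


def test_jc_correction_closed_form():
    assert pk.jc_correct(0.0) == 0.0
    # d = -(3/4) ln(1 - 4p/3) at p = 0.15, cross-checked numerically by
    # root-finding on the forward map
    d = pk.jc_correct(0.15)
    assert d == pytest.approx(0.75 * -np.log(0.8), abs=1e-12)
    from scipy.optimize import brentq

    d_numeric = brentq(lambda x: pk.jc_expected_p(x) - 0.15, 0, 5, xtol=1e-12)
    assert d == pytest.approx(d_numeric, abs=1e-9)
    with pytest.raises(SaturationError):
        pk.jc_correct(0.75)


def test_jc_correction_dominates_p():
    for p in np.linspace(0.01, 0.74, 40):
        assert pk.jc_correct(p) >= p


def test_jc_distance_triangle_inequality_on_simulated_triples():
    # random triples of sequences at moderate divergence: corrected
    # distances behave as a metric
    for seed in range(10):
        rng = np.random.default_rng(50 + seed)
        root = "".join(rng.choice(list("ACGT"), 5_000))
        d1, d2, d3 = rng.uniform(0.01, 0.2, size=3)
        tree = _tree(f"(a:{d1},b:{d2},c:{d3});")
        leaves = pk.evolve_clade(root, tree, seed=60 + seed)
        dab = pk.jc_correct(pk.p_distance(leaves["a"], leaves["b"]))
        dac = pk.jc_correct(pk.p_distance(leaves["a"], leaves["c"]))
        dbc = pk.jc_correct(pk.p_distance(leaves["b"], leaves["c"]))
        assert dab <= dac + dbc + 1e-12
        assert dac <= dab + dbc + 1e-12
        assert dbc <= dab + dac + 1e-12


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = pk.neighbor_joining(DistanceMatrix(ids, m))
    lengths = {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lengths["a"] == pytest.approx(0.1)
    assert lengths["b"] == pytest.approx(0.2)
    assert lengths["c"] == pytest.approx(0.4)


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
    ids = ["A", "B", "C", "D"]
    m = np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
    )
    tree = pk.neighbor_joining(DistanceMatrix(ids, m))
    assert _bipartitions(tree) == {frozenset({"C", "D"})}
    lengths = {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}


def _random_additive(n, seed):
    """Distances from a random binary tree with positive edge lengths."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n)]
    nodes = [(label,) for label in labels]
    newick = {(label,): f"{label}:{rng.uniform(0.1, 1.0):.4f}" for label in labels}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = tuple(sorted(a + b))
        bl = rng.uniform(0.1, 1.0)
        newick[merged] = f"({newick[a]},{newick[b]}):{bl:.4f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = _tree(newick[nodes[0]] + ";")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    m = np.array(
        [[pdm.patristic_distance(taxa[x], taxa[y]) for y in labels]
         for x in labels]
    )
    return labels, m, tree


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_recovers_random_additive_trees(n):
    for seed in range(3):
        labels, m, true_tree = _random_additive(n, seed=10 * n + seed)
        nj = pk.neighbor_joining(DistanceMatrix(labels, m))
        assert _bipartitions(nj) == _bipartitions(true_tree)


def test_nj_topology_agrees_with_independent_implementation(small_study):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    ids = list(small_study.sequences)[:6]
    aln = MultipleAlignment(
        ids, [small_study.alignment.row(i) for i in ids]
    )
    dm = pk.jc_distance_matrix(aln)
    ours = pk.neighbor_joining(dm)
    theirs = sk_nj(SkDM(dm.matrix, ids))
    their_bips = set()
    leaves = set(ids)
    anchor = min(leaves)
    for node in theirs.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            if anchor in side:
                side = frozenset(leaves - side)
            their_bips.add(side)
    assert _bipartitions(ours) <= their_bips | _bipartitions(ours)
    # topologies must agree on every clade both methods resolve
    assert _bipartitions(ours) == their_bips


def test_nj_rejects_bad_input():
    with pytest.raises(PlastomicsError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
    with pytest.raises(PlastomicsError):
        pk.neighbor_joining(
            DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_identical_sequences_degenerate_star():
    aln = MultipleAlignment(["a", "b", "c", "d"], ["ACGTACGT"] * 4)
    support = pk.bootstrap_support(aln, replicates=10, seed=1)
    assert support.degenerate
    assert support.supports == {}


def test_fixed_seed_reproducible_supports(small_study):
    ids = list(small_study.sequences)[:6]
    aln = MultipleAlignment(ids, [small_study.alignment.row(i) for i in ids])
    s1 = pk.bootstrap_support(aln, replicates=20, seed=5)
    s2 = pk.bootstrap_support(aln, replicates=20, seed=5)
    assert s1.supports == s2.supports


def test_long_internal_edges_get_high_support():
    # six taxa, deep split with long internal edge: every true bipartition
    # should be near-unanimous across 100 replicates
    root = "".join(
        np.random.default_rng(40).choice(list("ACGT"), 20_000)
    )
    tree = _tree(
        "(((a:0.01,b:0.01):0.05,c:0.02):0.05,((d:0.01,e:0.01):0.05,f:0.02));"
    )
    leaves = pk.evolve_clade(root, tree, seed=41)
    aln = MultipleAlignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
    support = pk.bootstrap_support(aln, replicates=100, seed=42)
    true_bips = _bipartitions(tree)
    assert true_bips <= set(support.supports)
    for bp in true_bips:
        assert support.supports[bp] >= 95.0
    newick = support.newick(hide_below=70.0)
    assert newick.count(")") >= 3


def test_newick_hides_low_supports(small_study):
    ids = list(small_study.sequences)[:5]
    aln = MultipleAlignment(ids, [small_study.alignment.row(i) for i in ids])
    support = pk.bootstrap_support(aln, replicates=20, seed=9)
    shown = support.newick(hide_below=101.0)  # hide everything
    import re

    assert not re.search(r"\)\d", shown)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def brute_force_likelihood(tree, aln):
    """Sum over all internal-state assignments, per site."""
    bases = "ACGT"
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = {n.taxon.label: n for n in nodes if n.is_leaf()}
    arr = [
        {sid: row[c] for sid, row in zip(aln.ids, aln.rows)}
        for c in range(aln.n_cols)
    ]
    P = {}

    def prob(parent_state, child_state, t):
        key = round(t, 12)
        if key not in P:
            P[key] = _jc_transition(t)
        return P[key][parent_state, child_state]

    total = 0.0
    for site in arr:
        if any(site[s] not in bases for s in site):
            continue
        site_sum = 0.0
        for assignment in itertools.product(range(4), repeat=len(internal)):
            states = dict(zip(internal, assignment))
            for label, leaf in leaves.items():
                states[leaf] = bases.index(site[label])
            lik = 0.25  # uniform root prior
            for node in nodes:
                if node is tree.seed_node:
                    continue
                lik *= prob(
                    states[node.parent_node], states[node],
                    node.edge.length or 0.0,
                )
            site_sum += lik
        total += np.log(site_sum)
    return total


def test_two_taxon_single_site_closed_form():
    tree = _tree("(A:0.07,B:0.03);")
    same = MultipleAlignment(["A", "B"], ["G", "G"])
    diff = MultipleAlignment(["A", "B"], ["G", "T"])
    d = 0.1
    p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
    p_diff = (0.25 - 0.25 * np.exp(-4 * d / 3))
    assert jc_log_likelihood(tree, same) == pytest.approx(
        np.log(0.25 * p_same), abs=1e-9
    )
    assert jc_log_likelihood(tree, diff) == pytest.approx(
        np.log(0.25 * p_diff), abs=1e-9
    )


@pytest.mark.parametrize(
    "newick",
    [
        "((A:0.1,B:0.2):0.05,C:0.15);",
        "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.1);",
        "(((A:0.1,B:0.2):0.05,C:0.15):0.02,(D:0.1,E:0.3):0.07);",
    ],
)
def test_pruning_matches_brute_force_enumeration(newick):
    tree = _tree(newick)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    rng = np.random.default_rng(len(labels))
    rows = ["".join(rng.choice(list("ACGT"), 12)) for _ in labels]
    aln = MultipleAlignment(labels, rows)
    assert jc_log_likelihood(tree, aln) == pytest.approx(
        brute_force_likelihood(tree, aln), abs=1e-9
    )


def test_likelihood_invariant_under_rerooting():
    tree = _tree("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.1);")
    rng = np.random.default_rng(3)
    aln = MultipleAlignment(
        ["A", "B", "C", "D"],
        ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)],
    )
    base = jc_log_likelihood(tree, aln)
    for leaf_label in ["A", "C"]:
        t2 = _tree(tree.as_string(schema="newick", unquoted_underscores=True))
        node = [
            lf for lf in t2.leaf_node_iter() if lf.taxon.label == leaf_label
        ][0]
        t2.reroot_at_edge(node.edge, length1=node.edge.length / 2,
                          length2=node.edge.length / 2)
        assert jc_log_likelihood(t2, aln) == pytest.approx(base, abs=1e-9)


def test_generating_topology_beats_alternatives():
    # four taxa: three unrooted topologies; the generating one must win
    # in nearly every replicate at this sequence length
    topologies = [
        "((A:0.02,B:0.02):0.06,(C:0.02,D:0.02):0.06);",
        "((A:0.02,C:0.02):0.06,(B:0.02,D:0.02):0.06);",
        "((A:0.02,D:0.02):0.06,(B:0.02,C:0.02):0.06);",
    ]
    gen_tree = _tree(topologies[0])
    wins = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        root = "".join(rng.choice(list("ACGT"), 5_000))
        leaves = pk.evolve_clade(root, _tree(topologies[0]), seed=2000 + rep)
        aln = MultipleAlignment(
            sorted(leaves), [leaves[k] for k in sorted(leaves)]
        )
        scored = pk.rank_topologies([_tree(t) for t in topologies], aln)
        best_bips = _bipartitions(scored[0][1])
        if best_bips == _bipartitions(gen_tree):
            wins += 1
    assert wins >= int(0.95 * reps)


def test_leaf_mismatch_rejected():
    tree = _tree("((A:0.1,B:0.1):0.1,C:0.1);")
    aln = MultipleAlignment(["A", "B", "X"], ["ACG", "ACG", "ACG"])
    with pytest.raises(PlastomicsError):
        jc_log_likelihood(tree, aln)
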