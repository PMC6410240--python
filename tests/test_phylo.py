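"""Distance, neighbor-joining, bootstrap and admixture-detection tests,
including NJ consistency on additive matrices and a scikit-bio cross-check."""

import itertools

import numpy as np
import pytest

from mtna import phylo, simulate
from mtna.io import read_newick, write_newick
from mtna.phylo import Alignment


def tree_bipartitions(tree):
    """Nontrivial bipartitions as frozensets of leaf names (canonical side)."""
    leaves = frozenset(t.name for t in tree.get_terminals())
    ref = min(leaves)
    out = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def random_additive_tree(n_taxa, rng):
    """Random binary topology with U(0.5, 2) edge lengths; returns the
    path-length distance matrix (the additive metric of the tree)."""
    nodes = {i: [i] for i in range(n_taxa)}  # node id -> leaf list
    dist = np.zeros((n_taxa, n_taxa))
    depth = {i: np.zeros(n_taxa) for i in range(n_taxa)}  # leaf distances
    active = list(range(n_taxa))
    next_id = n_taxa
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.5, 2.0, size=2)
        for x in nodes[a]:
            for y in nodes[b]:
                dist[x, y] = dist[y, x] = depth[a][x] + la + depth[b][y] + lb
        merged = nodes[a] + nodes[b]
        d = np.zeros(n_taxa)
        for x in nodes[a]:
            d[x] = depth[a][x] + la
        for y in nodes[b]:
            d[y] = depth[b][y] + lb
        nodes[next_id] = merged
        depth[next_id] = d
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return dist


class TestPDistance:
    def test_identical_sequences(self):
        aln = Alignment.from_records([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert phylo.p_distance(aln)[0, 1] == 0.0

    def test_one_difference_in_four(self):
        aln = Alignment.from_records([("a", "ACGT"), ("b", "ACGA")])
        assert phylo.p_distance(aln)[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded_pairwise(self):
        aln = Alignment.from_records([("a", "AC-T"), ("b", "ACGT")])
        assert phylo.p_distance(aln)[0, 1] == 0.0

    def test_gap_free_equals_hamming_over_length(self, rng):
        n, L = 5, 200
        codes = rng.integers(0, 4, size=(n, L)).astype(np.uint8)
        aln = Alignment([f"t{i}" for i in range(n)], codes)
        d = phylo.p_distance(aln)
        for i in range(n):
            for j in range(n):
                assert d[i, j] == pytest.approx((codes[i] != codes[j]).mean())

    def test_no_comparable_columns_rejected(self):
        aln = Alignment.from_records([("a", "A--"), ("b", "-CC")])
        with pytest.raises(ValueError, match="comparable"):
            phylo.p_distance(aln)

    def test_jukes_cantor_larger_than_p(self):
        aln = Alignment.from_records([("a", "ACGTACGTAC"), ("b", "ACGTACGTGG")])
        p = phylo.p_distance(aln)[0, 1]
        jc = phylo.p_distance(aln, model="jc")[0, 1]
        assert jc > p


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        """Distances from a 4-leaf tree with a 1-unit internal edge are
        recovered exactly (topology and branch lengths)."""
        # tree: (A:1, B:2) -- 1 -- (C:3, D:4)
        names = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        tree = phylo.neighbor_joining(d, names)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        internal = [
            c.branch_length for c in tree.get_nonterminals() if c.branch_length
        ]
        assert internal == pytest.approx([1.0])

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = phylo.neighbor_joining(d, ["x", "y", "z"])
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == pytest.approx({"x": 1, "y": 3, "z": 5})

    def test_consistency_on_random_additive_matrices(self):
        """NJ recovers the generating topology for additive inputs."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = random_additive_tree(8, rng)
            names = [str(i) for i in range(8)]
            tree = phylo.neighbor_joining(d, names)
            rebuilt = np.zeros((8, 8))
            depths = tree.depths()
            # verify additivity instead: distances on the NJ tree match input
            clade_path = {
                t.name: tree.get_path(t) for t in tree.get_terminals()
            }
            for i, j in itertools.combinations(range(8), 2):
                pi = clade_path[str(i)]
                pj = clade_path[str(j)]
                shared = 0
                for a, b in zip(pi, pj):
                    if a is b:
                        shared += 1
                    else:
                        break
                length = sum(c.branch_length for c in pi[shared:]) + sum(
                    c.branch_length for c in pj[shared:]
                )
                assert length == pytest.approx(d[i, j], abs=1e-9)

    def test_taxon_order_invariance(self, rng):
        d = random_additive_tree(7, np.random.default_rng(5))
        names = [f"t{i}" for i in range(7)]
        base = tree_bipartitions(phylo.neighbor_joining(d, names))
        for _ in range(5):
            perm = rng.permutation(7)
            dp = d[np.ix_(perm, perm)]
            tree = phylo.neighbor_joining(dp, [names[k] for k in perm])
            assert tree_bipartitions(tree) == base

    def test_matches_scikit_bio(self):
        """Independent NJ implementation recovers the same topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        d = random_additive_tree(9, rng)
        d += rng.uniform(0, 0.01, size=d.shape)  # perturb off additivity
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"t{i}" for i in range(9)]
        mine = phylo.neighbor_joining(d, names)
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
        ref_bips = set()
        leaves = frozenset(names)
        refname = min(leaves)
        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if refname in side:
                side = leaves - side
            if 1 < len(side) < len(leaves) - 1:
                ref_bips.add(side)
        assert tree_bipartitions(mine) == ref_bips

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            phylo.neighbor_joining(d, list("abc"))


class TestBootstrapSupport:
    def test_divergent_clade_gets_full_support(self, rng):
        """One clade at 20% divergence among otherwise identical sequences
        is supported in every replicate."""
        L = 10_000
        base = rng.integers(0, 4, size=L).astype(np.uint8)
        divergent = base.copy()
        flip = rng.random(L) < 0.2
        divergent[flip] = (divergent[flip] + rng.integers(1, 4, int(flip.sum()))) % 4
        codes = np.vstack([base] * 4 + [divergent] * 3)
        # tiny per-sequence noise so distances are not all exactly zero
        for row in codes:
            m = rng.random(L) < 0.001
            row[m] = (row[m] + rng.integers(1, 4, int(m.sum()))) % 4
        aln = Alignment([f"s{i}" for i in range(4)] + [f"div{i}" for i in range(3)], codes)
        tree = phylo.bootstrap_support(aln, n_reps=200, seed=1)
        support, members = phylo.clade_support(tree, ["div0", "div1", "div2"])
        assert set(members) == {"div0", "div1", "div2"}
        assert support == 100.0

    def test_supports_bounded_and_deterministic(self):
        config = simulate.SimConfig(seed=2)
        config.alignment.length_bp = 2000
        config.alignment.n_per_population = 6
        config.alignment.n_migrants = 2
        aln, _ = simulate.simulate_admixed_alignment(config)
        t1 = phylo.bootstrap_support(aln, n_reps=100, seed=9)
        t2 = phylo.bootstrap_support(aln, n_reps=100, seed=9)
        s1 = [c.confidence for c in t1.get_nonterminals() if c.confidence is not None]
        s2 = [c.confidence for c in t2.get_nonterminals() if c.confidence is not None]
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)


class TestRootingAndAdmixture:
    def small_admixed(self, seed=31, n_migrants=2):
        config = simulate.SimConfig(seed=seed)
        config.alignment.length_bp = 3000
        config.alignment.n_per_population = 8
        config.alignment.n_migrants = n_migrants
        return config, *simulate.simulate_admixed_alignment(config)

    def test_outgroup_rooting(self):
        _, aln, meta = self.small_admixed()
        tree = phylo.neighbor_joining(phylo.p_distance(aln), aln.names)
        outgroups = meta[meta.outgroup].taxon.tolist()
        rooted = phylo.root_with_outgroup(tree, outgroups)
        first_split = {
            frozenset(t.name for t in c.get_terminals()) for c in rooted.root.clades
        }
        assert frozenset(outgroups) in first_split

    def test_nonmonophyletic_outgroup_warns(self):
        tree = read_newick("((A:1,O1:1):1,(B:1,O2:1):1,C:1);")
        with pytest.warns(UserWarning, match="monophyletic"):
            phylo.root_with_outgroup(tree, ["O1", "O2"])

    def test_migrants_cluster_with_source_population(self):
        config, aln, meta = self.small_admixed()
        tree = phylo.neighbor_joining(phylo.p_distance(aln), aln.names)
        tree = phylo.root_with_outgroup(tree, meta[meta.outgroup].taxon.tolist())
        focal = meta[meta.migrant].taxon.tolist()
        source = meta[
            (meta.population == config.alignment.population_b) & ~meta.outgroup
        ].taxon.tolist()
        verdict = phylo.is_admixed(tree, focal, source)
        assert verdict.admixed
        assert set(focal) <= set(verdict.clade_taxa) <= set(focal) | set(source)

    def test_no_migration_negative_control(self):
        """Without migrants, no subset of one population ever shows the
        admixture signature with the other."""
        for seed in range(20):
            config = simulate.SimConfig(seed=seed)
            config.alignment.length_bp = 2000
            config.alignment.n_per_population = 8
            config.alignment.n_migrants = 0
            aln, meta = simulate.simulate_admixed_alignment(config)
            tree = phylo.neighbor_joining(phylo.p_distance(aln), aln.names)
            tree = phylo.root_with_outgroup(tree, meta[meta.outgroup].taxon.tolist())
            pop_a = meta[
                (meta.population == config.alignment.population_a) & ~meta.outgroup
            ].taxon.tolist()
            pop_b = meta[
                (meta.population == config.alignment.population_b) & ~meta.outgroup
            ].taxon.tolist()
            rng = np.random.default_rng(seed)
            subsets = [[t] for t in pop_a] + [
                list(rng.choice(pop_a, size=k, replace=False)) for k in (2, 3, 5)
            ]
            for focal in subsets:
                assert not phylo.is_admixed(tree, focal, pop_b).admixed

    def test_single_leaf_focal_sister_to_source(self):
        tree = read_newick("(((F1:1,(S1:1,S2:1):1):1,(A1:1,A2:1):1):1,O1:3);")
        verdict = phylo.is_admixed(tree, ["F1"], ["S1", "S2"])
        assert verdict.admixed
        assert set(verdict.clade_taxa) == {"F1", "S1", "S2"}

    def test_disjoint_sets_required(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            phylo.is_admixed(tree, ["A"], ["A", "C"])


class TestNewickRoundTrip:
    def test_supports_survive_round_trip(self):
        config = simulate.SimConfig(seed=3)
        config.alignment.length_bp = 1500
        config.alignment.n_per_population = 5
        config.alignment.n_migrants = 1
        aln, _ = simulate.simulate_admixed_alignment(config)
        tree = phylo.bootstrap_support(aln, n_reps=50, seed=4)
        text = write_newick(tree)
        back = read_newick(text)
        orig = sorted(
            c.confidence for c in tree.get_nonterminals() if c.confidence is not None
        )
        rt = sorted(
            c.confidence for c in back.get_nonterminals() if c.confidence is not None
        )
        assert rt == pytest.approx(orig)
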