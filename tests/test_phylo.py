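import io
import itertools
import math
import random

import numpy as np
import pytest
import skbio.tree
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode

from larvid.phylo import (
    SaturationError,
    bootstrap_support,
    k2p_distance,
    k2p_matrix,
    monophyly_fraction,
    nj_tree,
    p_distance,
    read_newick,
    write_newick,
)
from larvid.synthdata import mutate_sequence


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_worked_value(self):
        # 100 sites, 10 transitions, 5 transversions
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log((1 - 2 * 0.10 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert k2p_distance(s1, s2) == pytest.approx(expected)
        assert k2p_distance(s1, s2) == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_raises(self):
        s1 = "A" * 100
        s2 = "G" * 50 + "A" * 50  # P = 0.5, Q = 0
        with pytest.raises(SaturationError):
            k2p_distance(s1, s2)

    def test_sites_with_n_or_gap_excluded(self):
        assert k2p_distance("ACGTN", "ACGTA") == 0.0
        with pytest.raises(ValueError, match="no unambiguous"):
            k2p_distance("NNNN", "ACGT")

    def test_k2p_at_least_p_distance(self):
        rng = random.Random(0)
        base = "".join(rng.choice("ACGT") for _ in range(300))
        for seed in range(20):
            other = mutate_sequence(base, rng.uniform(0.0, 0.2), kappa=3.0, seed=seed)
            assert k2p_distance(base, other) >= p_distance(base, other) - 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pair=st.lists(
            st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")),
            min_size=20,
            max_size=200,
        )
    )
    def test_correction_inequality_property(self, pair):
        s1 = "".join(a for a, _ in pair)
        s2 = "".join(b for _, b in pair)
        try:
            d = k2p_distance(s1, s2)
        except SaturationError:
            return  # correction undefined beyond saturation, by contract
        assert d >= p_distance(s1, s2) - 1e-12


def _random_additive_tree(rng, n):
    """Random topology + branch lengths; returns (skbio tree, DistanceMatrix)."""
    labels = [f"t{i + 1}" for i in range(n)]
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        a.length = rng.uniform(0.05, 1.0)
        b.length = rng.uniform(0.05, 1.0)
        nodes.append(parent)
    tree = nodes[0]
    tree.length = None
    dm = tree.tip_tip_distances()
    return tree, DistanceMatrix(dm.data, ids=list(dm.ids))


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    @pytest.mark.parametrize("seed", range(5))
    def test_five_taxon_additive_recovery(self, seed):
        rng = random.Random(seed)
        true_tree, dm = _random_additive_tree(rng, 5)
        est = nj_tree(dm)
        # exact path-length matrix recovery implies exact topology
        got = est.tip_tip_distances()
        for i, j in itertools.combinations(dm.ids, 2):
            assert got[i, j] == pytest.approx(dm[i, j], abs=1e-9)

    def test_four_taxon_topology_matches_four_point_condition(self):
        rng = random.Random(11)
        for _ in range(10):
            _, dm = _random_additive_tree(rng, 4)
            a, b, c, d = dm.ids
            sums = {
                frozenset([frozenset([a, b]), frozenset([c, d])]): dm[a, b] + dm[c, d],
                frozenset([frozenset([a, c]), frozenset([b, d])]): dm[a, c] + dm[b, d],
                frozenset([frozenset([a, d]), frozenset([b, c])]): dm[a, d] + dm[b, c],
            }
            best_split = min(sums, key=sums.get)
            est = nj_tree(dm)
            cherries = {
                frozenset(t.name for t in n.tips())
                for n in est.non_tips(include_self=False)
            }
            (pair,) = [s for s in best_split if s in cherries] or [None]
            assert pair is not None

    def test_agrees_with_reference_implementation(self):
        rng = random.Random(23)
        _, dm = _random_additive_tree(rng, 8)
        assert nj_tree(dm).compare_rfd(skbio.tree.nj(dm)) == 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))

    def test_branch_lengths_nonnegative(self):
        # near-degenerate matrix that produces negative NJ estimates
        d = np.array(
            [[0, 0.1, 0.4, 0.4], [0.1, 0, 0.4, 0.4], [0.4, 0.4, 0, 0.01], [0.4, 0.4, 0.01, 0]]
        )
        tree = nj_tree(DistanceMatrix(d, ["a", "b", "c", "d"]))
        assert all(n.length >= 0 for n in tree.traverse() if n.length is not None)


class TestBootstrap:
    def _two_clades(self):
        rng = random.Random(5)
        base = "".join(rng.choice("ACGT") for _ in range(630))
        left = mutate_sequence(base, 0.15, seed=1)
        right = mutate_sequence(base, 0.15, seed=2)
        seqs, labels = [], []
        for i, anc in enumerate([left, right]):
            for k in range(4):
                seqs.append(mutate_sequence(anc, 0.01, seed=10 * i + k))
                labels.append(f"c{i}x{k}")
        return seqs, labels

    def test_separated_clades_get_high_support(self):
        seqs, labels = self._two_clades()
        boot = bootstrap_support(seqs, labels, n_reps=100, seed=0)
        clade = frozenset(l for l in labels if l.startswith("c1"))
        supports = {
            frozenset(t.name for t in n.tips()): int(n.name)
            for n in boot.tree.non_tips(include_self=False)
            if n.name is not None
        }
        all_leaves = frozenset(labels)
        value = supports.get(clade, supports.get(all_leaves - clade))
        assert value is not None and value >= 95

    def test_single_replicate_supports_binary(self):
        seqs, labels = self._two_clades()
        boot = bootstrap_support(seqs, labels, n_reps=1, seed=3)
        values = {
            int(n.name)
            for n in boot.tree.non_tips(include_self=False)
            if n.name is not None
        }
        assert values <= {0, 100}

    def test_seed_determinism(self):
        seqs, labels = self._two_clades()
        t1 = bootstrap_support(seqs, labels, n_reps=20, seed=7).tree
        t2 = bootstrap_support(seqs, labels, n_reps=20, seed=7).tree
        assert str(t1) == str(t2)

    def test_conspecific_monophyly_on_synthetic_data(self, clean_sim):
        seqs, labels, groups = [], [], {}
        for sp, ref in clean_sim.refs.items():
            label = sp.replace(" ", ".")
            seqs.append(ref)
            labels.append(label)
            groups[sp] = {label}
        for q in clean_sim.queries[:20]:
            sp = clean_sim.truth.queries[q.id].species
            seqs.append(q.sequence)
            labels.append(q.id)
            groups[sp].add(q.id)
        tree = nj_tree(k2p_matrix(seqs, labels))
        assert monophyly_fraction(tree, groups) >= 0.9


class TestNewick:
    def test_three_leaf_roundtrip(self, tmp_path):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        p = tmp_path / "t.nwk"
        write_newick(nj_tree(dm), p)
        back = read_newick(p)
        assert {t.name for t in back.tips()} == {"a", "b", "c"}

    def test_support_is_internal_label(self, tmp_path):
        seqs, labels = TestBootstrap()._two_clades()
        boot = bootstrap_support(seqs, labels, n_reps=10, seed=1)
        p = tmp_path / "t.nwk"
        write_newick(boot.tree, p)
        text = p.read_text()
        assert any(f"){v}" in text for v in ("100", "0", "90", "80"))

    def test_label_with_space_roundtrips(self, tmp_path):
        tree = TreeNode.read(io.StringIO("('sp. A':1,'sp. B':2,c:1);"))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        assert {t.name for t in read_newick(p).tips()} == {"sp. A", "sp. B", "c"}
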