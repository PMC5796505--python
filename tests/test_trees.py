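import numpy as np
import pytest
from scipy.stats import chisquare
from helpers import pa_from_columns, quartet

from parsboot import (
    PhyloTree,
    hill_climb_spr,
    parse_newick,
    random_nni_perturb,
    random_stepwise_addition,
    score_tree,
    spr_neighbors,
    write_newick,
)
from parsboot.scoring import tree_total
from parsboot.trees import NewickError, apply_spr, undo_spr
from oracles import all_topologies


class TestNewick:
    def test_quartet_split(self):
        t = parse_newick("((t1,t2),(t3,t4));")
        assert t.splits() == frozenset({0b1100})

    def test_roundtrip_random_trees(self, rng):
        from parsboot import random_tree

        for _ in range(50):
            t = random_tree(20, rng)
            back = parse_newick(write_newick(t), taxa=t.taxa)
            assert back.splits() == t.splits()

    def test_support_label_roundtrip(self):
        t = parse_newick("((t1,t2)87,(t3,t4));")
        assert t.support == {0b1100: 87.0}
        out = write_newick(t, with_support=True)
        assert "87" in out
        again = parse_newick(out, taxa=t.taxa)
        assert again.support == {0b1100: 87.0}

    def test_malformed_raises(self):
        with pytest.raises(NewickError):
            parse_newick("((t1,t2,(t3);")

    def test_unknown_taxa_raises(self):
        with pytest.raises(NewickError):
            parse_newick("((t1,t2),(t3,tX));", taxa=("t1", "t2", "t3", "t4"))

    def test_polytomy_input_allowed(self):
        t = parse_newick("(t1,t2,t3,t4,(t5,t6));")
        assert t.splits() == frozenset({0b110000})


class TestValidatorAndSplits:
    def test_validator_catches_broken_tree(self):
        t = quartet()
        u, v = next(iter(t.internal_edges()))
        t.remove_edge(u, v)
        with pytest.raises(ValueError):
            t.validate()

    def test_split_equality_is_topology_equality(self, rng):
        from parsboot import random_tree

        seen = {}
        for _ in range(30):
            t = random_tree(6, rng)
            key = t.topology_key()
            nwk = write_newick(t)
            if key in seen:
                # same splits -> same canonical newick after reparsing
                assert parse_newick(nwk, taxa=t.taxa).splits() == key
            seen[key] = nwk
        assert len(seen) > 1


class TestSpr:
    def test_quartet_radius2_covers_other_topologies(self):
        t = quartet()
        found = set()
        for move in spr_neighbors(t, radius=2):
            apply_spr(t, move)
            found.add(t.topology_key())
            undo_spr(t, move)
        others = {x.topology_key() for x in all_topologies(4)} - {t.topology_key()}
        assert others <= found

    @pytest.mark.parametrize("n,expected", [(5, 12), (6, 30)])
    def test_neighborhood_size_matches_closed_form(self, rng, n, expected):
        # one-SPR neighborhoods of a binary tree contain 2(n-3)(2n-7)
        # distinct topologies (Allen & Steel)
        from parsboot import random_tree

        t = random_tree(n, rng)
        found = set()
        for move in spr_neighbors(t, radius=None):
            apply_spr(t, move)
            t.validate()
            found.add(t.topology_key())
            undo_spr(t, move)
        assert t.topology_key() not in found
        assert len(found) == 2 * (n - 3) * (2 * n - 7)
        assert len(found) == expected

    def test_radius_monotonicity(self, rng):
        from parsboot import random_tree

        t = random_tree(8, rng)
        small = {(m.sub, m.attach, m.target) for m in spr_neighbors(t, radius=1)}
        large = {(m.sub, m.attach, m.target) for m in spr_neighbors(t, radius=6)}
        assert small <= large
        assert all(m.radius >= 1 for m in spr_neighbors(t, radius=None))

    def test_apply_undo_identity(self, rng):
        from parsboot import random_tree

        t = random_tree(7, rng)
        before = t.topology_key()
        for move in spr_neighbors(t, radius=3):
            apply_spr(t, move)
            t.validate()
            undo_spr(t, move)
            assert t.topology_key() == before

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            list(spr_neighbors(quartet(), radius=0))


class TestNni:
    def test_quartet_single_edge(self, rng):
        t = quartet()
        results = set()
        for seed in range(40):
            r = np.random.default_rng(seed)
            p = random_nni_perturb(t, 0.5, r)
            p.validate()
            results.add(p.topology_key())
        others = {x.topology_key() for x in all_topologies(4)} - {t.topology_key()}
        assert results == others  # exactly one NNI applied, both alternatives seen

    def test_fraction_rounding(self):
        # n=10 -> 7 internal edges -> ceil(0.5 * 7) = 4 NNI applications
        class CountingRng:
            def __init__(self, rng):
                self.rng, self.nni_draws = rng, 0

            def choice(self, *a, **k):
                return self.rng.choice(*a, **k)

            def integers(self, *a, **k):
                if a == (2,):
                    self.nni_draws += 1
                return self.rng.integers(*a, **k)

        from parsboot import random_tree

        t = random_tree(10, np.random.default_rng(3))
        counter = CountingRng(np.random.default_rng(4))
        p = random_nni_perturb(t, 0.5, counter)
        p.validate()
        assert counter.nni_draws == 4

    def test_deterministic_under_seed(self, rng):
        from parsboot import random_tree

        t = random_tree(9, rng)
        a = random_nni_perturb(t, 0.5, np.random.default_rng(11))
        b = random_nni_perturb(t, 0.5, np.random.default_rng(11))
        assert a.topology_key() == b.topology_key()

    def test_valid_after_many_perturbations(self, rng):
        from parsboot import random_tree

        for _ in range(20):
            t = random_tree(12, rng)
            p = random_nni_perturb(t, 1.0, rng)
            p.validate()


class TestStepwiseAddition:
    def test_signal_free_uniform_over_topologies(self, uniform_dna):
        # symmetric alignment: every quartet topology scores the same
        pa = pa_from_columns(["AACC", "ACAC", "ACCA"])
        counts = {t.topology_key(): 0 for t in all_topologies(4)}
        for seed in range(600):
            t = random_stepwise_addition(pa, uniform_dna, np.random.default_rng(seed))
            counts[t.topology_key()] += 1
        stat = chisquare(list(counts.values()))
        assert stat.pvalue > 1e-3

    def test_perfect_split_recovered(self, uniform_dna):
        pa = pa_from_columns(["AACC", "AACC", "AAGG"], weights=[3, 2, 4])
        best = min(
            score_tree(t, pa, uniform_dna).total for t in all_topologies(4)
        )
        for seed in range(25):
            t = random_stepwise_addition(pa, uniform_dna, np.random.default_rng(seed))
            assert score_tree(t, pa, uniform_dna).total == best
            assert t.splits() == frozenset({0b1100})

    def test_deterministic_under_seed(self, uniform_dna, rng):
        from parsboot import simulate_pair
        from parsboot.patterns import compress_informative

        _, aln = simulate_pair(7, 100, rng)
        pa = compress_informative(aln)
        a = random_stepwise_addition(pa, uniform_dna, np.random.default_rng(5))
        b = random_stepwise_addition(pa, uniform_dna, np.random.default_rng(5))
        assert a.topology_key() == b.topology_key()


class TestHillClimb:
    def _fixture(self, rng, uniform_dna):
        cols = ["".join(rng.choice(list("ACGT")) for _ in range(5)) for _ in range(25)]
        return pa_from_columns(cols)

    def test_reaches_global_optimum_like_oracle_descent(self, rng, uniform_dna):
        # exhaustive basin analysis on all 15 five-taxon topologies
        pa = self._fixture(rng, uniform_dna)
        trees = all_topologies(5)
        totals = {t.topology_key(): tree_total(t, pa, uniform_dna) for t in trees}

        def oracle_descent(t):
            current, score = t.topology_key(), totals[t.topology_key()]
            tree = t.copy()
            while True:
                best_key, best_score = None, score
                for move in spr_neighbors(tree, None):
                    apply_spr(tree, move)
                    k = tree.topology_key()
                    undo_spr(tree, move)
                    if totals[k] < best_score:
                        best_key, best_score = k, totals[k]
                if best_key is None:
                    return best_score
                score = best_score
                tree = next(x.copy() for x in trees if x.topology_key() == best_key)

        for start in trees:
            climbed = hill_climb_spr(start, pa, uniform_dna, radius=None)
            assert tree_total(climbed, pa, uniform_dna) == oracle_descent(start)

    def test_local_optimum_is_fixed_point(self, rng, uniform_dna):
        pa = self._fixture(rng, uniform_dna)
        t = hill_climb_spr(all_topologies(5)[0], pa, uniform_dna, radius=None)
        again = hill_climb_spr(t, pa, uniform_dna, radius=None)
        assert again.topology_key() == t.topology_key()

    def test_score_never_worsens(self, rng, uniform_dna):
        pa = self._fixture(rng, uniform_dna)
        for t in all_topologies(5)[::3]:
            before = tree_total(t, pa, uniform_dna)
            after = tree_total(hill_climb_spr(t, pa, uniform_dna, 3), pa, uniform_dna)
            assert after <= before

    def test_on_accept_sees_monotone_totals(self, rng, uniform_dna):
        pa = self._fixture(rng, uniform_dna)
        seen = []
        hill_climb_spr(
            all_topologies(5)[7], pa, uniform_dna, None,
            on_accept=lambda tree, psv: seen.append(psv.total),
        )
        assert seen == sorted(seen, reverse=True) or len(seen) == 1
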