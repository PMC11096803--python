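"""nPH85 distance and DTL reconciliation against independent oracles."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from oracles import dendropy_rf, enumerate_reconciliations
from picobirnatax.cophylogeny import (
    EventCosts,
    TipHostMap,
    event_likelihoods,
    expand_host_tree,
    nph85,
    reconcile_mpr,
    resolve_polytomies,
    sample_reconciliation,
)
from picobirnatax.simulate import yule_tree
from picobirnatax.trees import bipartitions, parse_newick, write_newick


def random_instance(rng, max_hosts=5, max_viruses=5):
    host = yule_tree(rng.randint(2, max_hosts), seed=rng.randrange(10**6),
                     tip_prefix="H")
    virus = yule_tree(rng.randint(2, max_viruses), seed=rng.randrange(10**6),
                      tip_prefix="v")
    v2h = {v: rng.choice(host.tip_labels()) for v in virus.tip_labels()}
    return virus, host, v2h


class TestExpandHostTree:
    def test_one_virus_per_host_relabels(self):
        host = parse_newick("(H1,(H2,H3));")
        m = TipHostMap({"v1": "H1", "v2": "H2", "v3": "H3"})
        assert write_newick(expand_host_tree(host, m)) == "(v1,(v2,v3));"

    def test_shared_host_becomes_polytomy_and_unmapped_pruned(self):
        host = parse_newick("(H1,(H2,H3));")
        m = TipHostMap({"v1": "H1", "v2": "H1", "v3": "H2"})
        assert write_newick(expand_host_tree(host, m)) == "((v1,v2),v3);"

    def test_all_on_one_host_star(self):
        host = parse_newick("(H1,(H2,H3));")
        m = TipHostMap({f"v{i}": "H1" for i in range(1, 5)})
        expanded = expand_host_tree(host, m)
        assert bipartitions(expanded) == set()
        assert sorted(expanded.tip_labels()) == ["v1", "v2", "v3", "v4"]

    def test_missing_host_errors(self):
        host = parse_newick("(H1,(H2,H3));")
        with pytest.raises(KeyError, match="H9"):
            expand_host_tree(host, TipHostMap({"v1": "H9"}))


class TestNPH85:
    def test_identical_topology_is_zero(self):
        host = yule_tree(8, seed=1, tip_prefix="H")
        virus = host.copy()
        for tip in virus.tips():
            tip.label = tip.label.replace("H", "v")
        m = TipHostMap({f"v{i}": f"H{i}" for i in range(1, 9)})
        assert nph85(virus, host, m).distance == 0.0

    def test_maximal_conflict_is_one(self):
        host = parse_newick("((A,B),(C,D));")
        virus = parse_newick("((a,c),(b,d));")
        m = TipHostMap({"a": "A", "b": "B", "c": "C", "d": "D"})
        assert nph85(virus, host, m).distance == 1.0

    @given(st.integers(0, 2_000))
    def test_matches_rf_oracle_on_resolved_pairs(self, seed):
        """Distance equals dendropy's RF symmetric difference / 2(n-3)."""
        rng = random.Random(seed)
        n = rng.randint(5, 10)
        host = yule_tree(n, seed=rng.randrange(10**6), tip_prefix="H")
        virus = yule_tree(n, seed=rng.randrange(10**6), tip_prefix="H")
        m = TipHostMap({f"H{i}": f"H{i}" for i in range(1, n + 1)})
        ours = nph85(virus, host, m).distance
        rf = dendropy_rf(write_newick(virus), write_newick(host))
        assert ours == pytest.approx(rf / (2 * (n - 3)))

    @given(st.integers(0, 1_000))
    def test_symmetric_and_bounded(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 9)
        a = yule_tree(n, seed=rng.randrange(10**6), tip_prefix="H")
        b = yule_tree(n, seed=rng.randrange(10**6), tip_prefix="H")
        ident = TipHostMap({f"H{i}": f"H{i}" for i in range(1, n + 1)})
        d_ab = nph85(a, b, ident).distance
        d_ba = nph85(b, a, ident).distance
        assert d_ab == pytest.approx(d_ba)
        assert 0 <= d_ab <= 1

    def test_resample_mode_zero_on_congruent_instance(self):
        host = yule_tree(6, seed=4, tip_prefix="H")
        virus = expand_host_tree(
            host, TipHostMap({f"v{i}": f"H{i}" for i in range(1, 7)})
        )
        m = TipHostMap({f"v{i}": f"H{i}" for i in range(1, 7)})
        res = nph85(virus, host, m, mode="resample-one-per-host",
                    resamples=10, seed=5)
        assert res.distance == 0.0
        assert len(res.replicate_distances) == 10

    def test_too_few_tips_errors(self):
        host = parse_newick("(A,(B,C));")
        virus = parse_newick("((a,b),c);")
        with pytest.raises(ValueError, match="4"):
            nph85(virus, host,
                  TipHostMap({"a": "A", "b": "B", "c": "C"}))


class TestReconcileMPR:
    def test_perfect_congruence_all_cospeciation(self):
        for n in (4, 7, 12):
            host = yule_tree(n, seed=n, tip_prefix="H")
            virus = host.copy()
            for tip in virus.tips():
                tip.label = "v" + tip.label
            m = TipHostMap({f"vH{i}": f"H{i}" for i in range(1, n + 1)})
            dp = reconcile_mpr(virus, host, m)
            assert dp.min_cost == 0
            assert dp.mpr_count == 1
            summ = event_likelihoods(dp, n_samples=5, seed=0)
            assert summ.event_proportions["cospeciation"] == 1.0
            assert summ.per_sample_counts[0]["cospeciation"] == n - 1

    def test_single_transfer_instance(self):
        host = parse_newick("((A:1,B:1):1,C:1);")
        virus = parse_newick("((a:1,c:1):1,b:1);")
        m = TipHostMap({"a": "A", "b": "B", "c": "C"})
        dp = reconcile_mpr(virus, host, m)
        assert dp.min_cost == 1.0

    def test_same_host_cherry_is_one_duplication(self):
        host = parse_newick("((A:1,B:1):1,C:1);")
        virus = parse_newick("(a1:1,a2:1);")
        dp = reconcile_mpr(virus, host, TipHostMap({"a1": "A", "a2": "A"}))
        assert dp.min_cost == 1.0
        summ = event_likelihoods(dp, n_samples=3, seed=0)
        assert summ.per_sample_counts[0] == {
            "cospeciation": 0, "transfer": 0, "duplication": 1, "loss": 0
        }

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_min_cost_and_mpr_count(self, seed):
        rng = random.Random(seed)
        virus, host, v2h = random_instance(rng)
        costs = EventCosts()
        dp = reconcile_mpr(virus, host, TipHostMap(v2h), costs)
        ocost, ocount, _ = enumerate_reconciliations(virus, host, v2h, costs)
        assert dp.min_cost == pytest.approx(ocost)
        assert dp.mpr_count == ocount

    @given(st.integers(0, 2_000))
    def test_matches_bruteforce_under_random_costs(self, seed):
        rng = random.Random(seed)
        virus, host, v2h = random_instance(rng, max_hosts=4, max_viruses=4)
        costs = EventCosts(
            cospeciation=rng.choice([0.0, 0.5]),
            transfer=rng.choice([1.0, 2.0]),
            duplication=rng.choice([1.0, 1.5]),
            loss=rng.choice([0.5, 1.0]),
        )
        dp = reconcile_mpr(virus, host, TipHostMap(v2h), costs)
        ocost, ocount, _ = enumerate_reconciliations(virus, host, v2h, costs)
        assert dp.min_cost == pytest.approx(ocost)
        assert dp.mpr_count == ocount

    def test_virus_polytomy_rejected(self):
        host = parse_newick("((A:1,B:1):1,C:1);")
        virus = parse_newick("(a:1,b:1,c:1);", rooted=True)
        with pytest.raises(ValueError, match="polytomy"):
            reconcile_mpr(virus, host,
                          TipHostMap({"a": "A", "b": "B", "c": "C"}))

    def test_unmapped_tip_rejected(self):
        host = parse_newick("((A:1,B:1):1,C:1);")
        virus = parse_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(KeyError, match="c"):
            reconcile_mpr(virus, host, TipHostMap({"a": "A", "b": "B"}))

    def test_host_polytomy_resolution_is_seeded_and_reported(self):
        host = parse_newick("(A:1,B:1,C:1,D:1);", rooted=True)
        virus = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = TipHostMap({"a": "A", "b": "B", "c": "C", "d": "D"})
        dp1 = reconcile_mpr(virus, host, m, host_resolution_seed=7)
        dp2 = reconcile_mpr(virus, host, m, host_resolution_seed=7)
        assert dp1.n_host_polytomies_resolved == 1
        assert write_newick(dp1.host_tree) == write_newick(dp2.host_tree)


# instance with exactly two equal-cost MPRs, found by exhaustive
# enumeration: one MPR has events {1 cospeciation, 2 transfers}, the other
# {2 cospeciations, 1 transfer, 1 loss}
TWO_MPR_HOST = (
    "(H1:1.3336,(H2:0.6203,(H3:0.6638,(H4:0.2855,H5:0.7447):0.7921)"
    ":0.5921):0.9123);"
)
TWO_MPR_VIRUS = (
    "((v1:1.0446,v3:1.0922):0.4373,(v2:1.1238,v4:1.0759):0.4161);"
)
TWO_MPR_MAP = {"v1": "H4", "v3": "H3", "v2": "H5", "v4": "H2"}


class TestMPRSampling:
    def test_two_mpr_instance_verified_by_oracle(self):
        virus = parse_newick(TWO_MPR_VIRUS)
        host = parse_newick(TWO_MPR_HOST)
        ocost, ocount, profiles = enumerate_reconciliations(
            virus, host, TWO_MPR_MAP, EventCosts()
        )
        assert ocount == 2
        dp = reconcile_mpr(virus, host, TipHostMap(TWO_MPR_MAP))
        assert dp.mpr_count == 2
        assert dp.min_cost == pytest.approx(ocost) == pytest.approx(2.0)
        assert sorted(p["loss"] for p in profiles) == [0, 1]

    def test_sampling_is_uniform_over_the_two_mprs(self):
        """Each of the 2 MPRs drawn with p=0.5 within 3 sigma at n=10,000."""
        virus = parse_newick(TWO_MPR_VIRUS)
        host = parse_newick(TWO_MPR_HOST)
        dp = reconcile_mpr(virus, host, TipHostMap(TWO_MPR_MAP))
        rng = random.Random(11)
        n = 10_000
        with_loss = sum(
            sample_reconciliation(dp, rng)["loss"] for _ in range(n)
        )
        sigma = math.sqrt(0.25 * n)
        assert abs(with_loss - n / 2) <= 3 * sigma

    @given(st.integers(0, 500))
    def test_event_proportions_sum_to_one(self, seed):
        rng = random.Random(seed)
        virus, host, v2h = random_instance(rng, max_hosts=6, max_viruses=6)
        dp = reconcile_mpr(virus, host, TipHostMap(v2h))
        summ = event_likelihoods(dp, n_samples=10, seed=seed)
        if virus.n_tips > 1:
            assert sum(summ.event_proportions.values()) == pytest.approx(1.0)
        for counts in summ.per_sample_counts:
            cost = (
                counts["transfer"] * 1.0
                + counts["duplication"] * 1.0
                + counts["loss"] * 1.0
            )
            assert cost == pytest.approx(dp.min_cost)

    def test_sampling_reproducible_given_seed(self):
        rng = random.Random(0)
        virus, host, v2h = random_instance(rng, max_hosts=6, max_viruses=6)
        dp = reconcile_mpr(virus, host, TipHostMap(v2h))
        a = event_likelihoods(dp, n_samples=30, seed=42)
        b = event_likelihoods(dp, n_samples=30, seed=42)
        assert a.per_sample_counts == b.per_sample_counts


def test_resolve_polytomies_counts_and_binarizes():
    tree = parse_newick("(A,B,C,(D,E,F));", rooted=True)
    resolved, n = resolve_polytomies(tree, seed=3)
    assert n == 2
    assert all(len(node.children) == 2
               for node in resolved.internal_nodes())
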