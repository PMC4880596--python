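"""Connectivity bookkeeping: deletion, formation, rewiring, conservation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from neuroplast.plasticity import (
    SynapseRule,
    SynapseStore,
    build_reports,
    check_conservation,
    commit_deletions,
    disconnect,
    form_synapses,
)

from helpers import make_elements


def ex_store():
    return SynapseStore([SynapseRule("ex_syn", "Axon_ex", "Den_ex", 1.0, delay=1.0)])


class TestBuildReports:
    def test_all_zero_deltas_give_empty_report(self):
        elems = make_elements({"Axon_ex": [(0, 1.0, 1)], "Den_ex": [(1, 1.0, 1)]})
        rep = build_reports(elems)
        assert rep.total_vacant() == 0 and rep.total_to_delete() == 0

    def test_vacancy_counts_are_totals(self):
        elems = make_elements({"Axon_ex": [(0, 3.7, 1)]})
        rep = build_reports(elems)
        assert rep.vacant["Axon_ex"].tolist() == [2]

    def test_no_netting_across_element_types(self):
        """One neuron may simultaneously delete type A and offer type B."""
        elems = make_elements({"Axon_ex": [(0, 1.5, 2)], "Den_ex": [(0, 2.0, 0)]})
        rep = build_reports(elems, {"Axon_ex": np.array([1]), "Den_ex": np.array([0])})
        assert rep.to_delete["Axon_ex"].tolist() == [1]
        assert rep.vacant["Den_ex"].tolist() == [2]

    def test_overreported_deletion_rejected(self):
        elems = make_elements({"Axon_ex": [(0, 1.0, 1)]})
        with pytest.raises(ValueError):
            build_reports(elems, {"Axon_ex": np.array([2])})


class TestCommitDeletions:
    def _wired(self, n_syn):
        elems = make_elements(
            {
                "Axon_ex": [(0, float(n_syn), n_syn)],
                "Den_ex": [(i, 1.0, 1) for i in range(1, n_syn + 1)],
            }
        )
        store = ex_store()
        store.add("ex_syn", np.zeros(n_syn, np.int64), np.arange(1, n_syn + 1))
        return elems, store

    def test_zero_deletions_leave_store_unchanged(self):
        elems, store = self._wired(3)
        rep = build_reports(elems)
        commit_deletions(store, rep, elems, np.random.default_rng(0))
        assert store.count("ex_syn") == 3

    def test_exhaustive_deletion_frees_all_partners(self):
        elems, store = self._wired(3)
        elems["Axon_ex"].z[0] = 0.0  # all three connected axonal elements lost
        rep = build_reports(elems, {"Axon_ex": np.array([3])})
        commit_deletions(store, rep, elems, np.random.default_rng(0))
        assert store.count("ex_syn") == 0
        assert elems["Den_ex"].connected.sum() == 0
        assert elems["Den_ex"].vacant.sum() == 3  # partners became vacant, z intact
        check_conservation(store, elems)

    def test_single_deletion_uniform_over_synapses(self):
        """Each of 5 synapses removed with frequency 1/5 (chi-square)."""
        counts = np.zeros(5)
        for seed in range(2000):
            elems, store = self._wired(5)
            elems["Axon_ex"].z[0] = 4.0
            rep = build_reports(elems, {"Axon_ex": np.array([1])})
            commit_deletions(store, rep, elems, np.random.default_rng(seed))
            (gone,) = set(range(1, 6)) - set(store.alive_edges("ex_syn")[1])
            counts[gone - 1] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_both_endpoints_scheduled_no_double_free(self):
        """A<->B edge with both sides losing their element: removed once."""
        elems = make_elements({"Axon_ex": [(0, 0.9, 1)], "Den_ex": [(1, 0.9, 1)]})
        store = ex_store()
        store.add("ex_syn", np.array([0]), np.array([1]))
        rep = build_reports(elems, {"Axon_ex": np.array([1]), "Den_ex": np.array([1])})
        commit_deletions(store, rep, elems, np.random.default_rng(0))
        assert store.count("ex_syn") == 0
        assert elems["Axon_ex"].connected[0] == 0
        assert elems["Den_ex"].connected[0] == 0
        check_conservation(store, elems)

    def test_bookkeeping_error_raises(self):
        elems, store = self._wired(2)
        elems["Axon_ex"].z[0] = 0.0
        elems["Axon_ex"].connected[0] = 3  # inconsistent with 2 stored edges
        rep = build_reports(elems, {"Axon_ex": np.array([3])})
        with pytest.raises(ValueError, match="bookkeeping"):
            commit_deletions(store, rep, elems, np.random.default_rng(0))


class TestFormSynapses:
    def test_no_pre_vacancy_no_synapses(self):
        elems = make_elements({"Axon_ex": [(0, 0.0, 0)], "Den_ex": [(1, 3.0, 0)]})
        store = ex_store()
        rep = build_reports(elems)
        added = form_synapses(store, rep.vacant, elems, np.random.default_rng(0))
        assert store.count("ex_syn") == 0 and len(added["ex_syn"][0]) == 0

    def test_forced_matching_two_pairs(self):
        """2 vacant axons on A, 2 vacant dendrites on B -> exactly 2 A->B edges."""
        elems = make_elements({"Axon_ex": [(0, 2.0, 0)], "Den_ex": [(1, 2.0, 0)]})
        store = ex_store()
        rep = build_reports(elems)
        form_synapses(store, rep.vacant, elems, np.random.default_rng(3))
        pre, post = store.alive_edges("ex_syn")
        assert pre.tolist() == [0, 0] and post.tolist() == [1, 1]
        assert elems["Axon_ex"].vacant[0] == 0 and elems["Den_ex"].vacant[0] == 0
        check_conservation(store, elems)

    def test_pairing_uniform_over_perfect_matchings(self):
        """3x3 one-vacant-element instance vs the enumerated matching oracle."""
        pre_ids, post_ids = [0, 1, 2], [3, 4, 5]
        matchings = list(itertools.permutations(post_ids))  # oracle: 6, uniform
        observed = {m: 0 for m in matchings}
        n_trials = 10000
        for seed in range(n_trials):
            elems = make_elements(
                {
                    "Axon_ex": [(i, 1.0, 0) for i in pre_ids],
                    "Den_ex": [(j, 1.0, 0) for j in post_ids],
                }
            )
            store = ex_store()
            rep = build_reports(elems)
            form_synapses(store, rep.vacant, elems, np.random.default_rng(seed))
            pre, post = store.alive_edges("ex_syn")
            assert len(pre) == 3
            observed[tuple(post[np.argsort(pre)])] += 1
        counts = np.array([observed[m] for m in matchings])
        assert stats.chisquare(counts).pvalue > 0.01

    def test_autapse_pairs_skipped_and_elements_stay_vacant(self):
        elems = make_elements({"Axon_ex": [(0, 1.0, 0)], "Den_ex": [(0, 1.0, 0)]})
        store = ex_store()
        rep = build_reports(elems)
        form_synapses(store, rep.vacant, elems, np.random.default_rng(0), allow_autapses=False)
        assert store.count("ex_syn") == 0
        assert elems["Axon_ex"].vacant[0] == 1 and elems["Den_ex"].vacant[0] == 1

    def test_autapses_allowed_when_configured(self):
        elems = make_elements({"Axon_ex": [(0, 1.0, 0)], "Den_ex": [(0, 1.0, 0)]})
        store = ex_store()
        rep = build_reports(elems)
        form_synapses(store, rep.vacant, elems, np.random.default_rng(0), allow_autapses=True)
        assert store.count("ex_syn") == 1

    def test_multapses_arise_from_repeated_pairs(self):
        elems = make_elements({"Axon_ex": [(0, 4.0, 0)], "Den_ex": [(1, 4.0, 0)]})
        store = ex_store()
        rep = build_reports(elems)
        form_synapses(store, rep.vacant, elems, np.random.default_rng(0))
        assert store.count("ex_syn") == 4  # four parallel edges

    def test_unknown_element_type_rejected(self):
        elems = make_elements({"Axon_ex": [(0, 1.0, 0)]})
        store = ex_store()  # rule references Den_ex which is absent
        with pytest.raises(KeyError):
            form_synapses(store, {"Axon_ex": np.array([1])}, elems, np.random.default_rng(0))


class TestRewiring:
    def test_manual_disconnect_leaves_two_vacant_counterparts(self):
        elems = make_elements({"Axon_ex": [(0, 1.0, 1)], "Den_ex": [(1, 1.0, 1)]})
        store = ex_store()
        store.add("ex_syn", np.array([0]), np.array([1]))
        disconnect(store, elems, "ex_syn", 0)
        assert store.count("ex_syn") == 0
        assert elems["Axon_ex"].vacant[0] == 1
        assert elems["Den_ex"].vacant[0] == 1
        check_conservation(store, elems)

    def test_freed_partner_can_rematch_next_interval(self):
        # interval 1: neuron 0 loses its axonal element; 1's dendrite is freed
        elems = make_elements(
            {"Axon_ex": [(0, 0.9, 1), (2, 1.0, 0)], "Den_ex": [(1, 1.0, 1)]}
        )
        store = ex_store()
        store.add("ex_syn", np.array([0]), np.array([1]))
        rep = build_reports(elems, {"Axon_ex": np.array([1, 0])})
        # formation pool (built before deletions) excludes the freed dendrite
        commit_deletions(store, rep, elems, np.random.default_rng(0))
        form_synapses(store, rep.vacant, elems, np.random.default_rng(0))
        assert store.count("ex_syn") == 0
        # interval 2: the freed dendrite is now in the pool and matches 2's axon
        rep2 = build_reports(elems)
        form_synapses(store, rep2.vacant, elems, np.random.default_rng(1))
        pre, post = store.alive_edges("ex_syn")
        assert pre.tolist() == [2] and post.tolist() == [1]
        check_conservation(store, elems)
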