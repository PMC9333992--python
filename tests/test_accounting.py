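"""Input accounting: composition, histograms, KS, pairing and connectivity filters."""

import itertools

import numpy as np
import pytest

from cohortwiring.input_accounting import (
    PER_EDGE_BINS,
    POOLED_BINS,
    HistogramSpec,
    TargetSet,
    class_composition,
    compose_by_source_type,
    highly_connected,
    inputs_onto,
    ks_compare,
    lr_pair_filter,
    sensory_breakdown,
    synapse_histogram,
)
from cohortwiring.model import Catalog, SynapseTable

from .conftest import lr_pair, record, table_of


class TestInputsOnto:
    def test_empty_table(self, two_targets):
        sub, summary = inputs_onto(table_of(), two_targets)
        assert summary.total_synapses == 0 and summary.distinct_sources == 0

    def test_single_edge(self, two_targets):
        sub, summary = inputs_onto(table_of(("a", "t_L", 7)), two_targets)
        assert summary.total_synapses == 7 and summary.distinct_sources == 1

    def test_unknown_target_rejected(self, two_target_catalog):
        ts = TargetSet(name="bad", members=["nope"])
        with pytest.raises(ValueError, match="absent"):
            inputs_onto(table_of(), ts, two_target_catalog)


class TestComposition:
    def test_counts_and_percentages(self, two_target_catalog):
        sub = table_of(("p_L", "t_L", 3), ("sens_L", "t_L", 1))
        comp = compose_by_source_type(sub, two_target_catalog)
        by_type = comp.set_index("source_type")
        assert by_type.loc["interneuron", "percentage"] == pytest.approx(75.0)
        assert by_type.loc["sensory", "percentage"] == pytest.approx(25.0)
        assert comp["percentage"].sum() == pytest.approx(100.0)
        assert comp["synapses"].sum() == sub.total_synapses

    def test_unknown_sources_are_fragments(self):
        sub = table_of(("mystery", "t", 4))
        comp = compose_by_source_type(sub, Catalog([]))
        assert comp.iloc[0]["source_type"] == "unknown_fragment"
        assert comp.iloc[0]["percentage"] == pytest.approx(100.0)

    def test_class_composition_single_class_is_100(self, two_target_catalog):
        sub = table_of(("mid", "t_L", 5), ("mid", "t_R", 2))
        comp = class_composition(sub, two_target_catalog)
        ladder = comp.set_index("morph_class").loc["Ladder"]
        assert ladder["neurons"] == 1
        assert ladder["percentage"] == pytest.approx(100.0)

    def test_class_composition_pools_unlisted_into_other(self, two_target_catalog):
        sub = table_of(("mid", "t_L", 3), ("p_L", "t_L", 1))
        comp = class_composition(sub, two_target_catalog, classes=["Ladder"])
        assert set(comp["morph_class"]) == {"Ladder", "other"}
        assert comp["percentage"].sum() == pytest.approx(100.0)


class TestSensoryBreakdown:
    def test_fraction_of_total_input(self, two_target_catalog, two_targets):
        sub = table_of(("sens_L", "t_L", 4), ("p_L", "t_L", 6))
        out = sensory_breakdown(sub, two_target_catalog, two_targets)
        row = out.set_index("target").loc["t_L"]
        assert row["chordotonal"] == pytest.approx(0.4)
        assert row["proprioceptive"] == 0.0

    def test_pure_sensory_input_is_one(self, two_target_catalog, two_targets):
        sub = table_of(("sens_L", "t_L", 3))
        row = sensory_breakdown(sub, two_target_catalog, two_targets).set_index("target").loc["t_L"]
        assert row["chordotonal"] == pytest.approx(1.0)

    def test_zero_input_target_flagged(self, two_target_catalog, two_targets):
        out = sensory_breakdown(table_of(), two_target_catalog, two_targets)
        assert out["no_input"].all()
        assert (out[["chordotonal", "proprioceptive", "other"]] == 0).all().all()


class TestHistogram:
    def test_unit_bins_and_open_top(self):
        sub = table_of(("a", "t", 1), ("b", "t", 1), ("c", "t", 10))
        out = synapse_histogram(sub, PER_EDGE_BINS, per="edge").set_index("bin")
        assert out.loc["1", "count"] == 2
        assert out.loc["10+", "count"] == 1
        assert out["count"].sum() == 3

    def test_empty_table_all_zero(self):
        out = synapse_histogram(table_of(), PER_EDGE_BINS)
        assert (out["count"] == 0).all()

    def test_source_pooled_uses_summed_counts(self):
        # one source with 3+4=7 synapses onto the set, one with 1
        sub = table_of(("a", "t1", 3), ("a", "t2", 4), ("b", "t1", 1))
        out = synapse_histogram(sub, POOLED_BINS, per="source_pooled").set_index("bin")
        assert out.loc["5-9", "count"] == 1
        assert out.loc["0-4", "count"] == 1

    def test_underflow_bucket(self):
        sub = table_of(("a", "t", 1))
        spec = HistogramSpec.unit_bins(2, 4)
        out = synapse_histogram(sub, spec).set_index("bin")
        assert out.loc["underflow", "count"] == 1

    def test_counts_sum_to_binned_items(self, sharp_system):
        ts = sharp_system.target_set()
        sub, _ = inputs_onto(sharp_system.table, ts)
        for per, expected in (
            ("edge", len(sub)),
            ("source_pooled", sub.df["pre_id"].nunique()),
        ):
            out = synapse_histogram(sub, PER_EDGE_BINS, per=per)
            assert out["count"].sum() == expected

    def test_malformed_specs_rejected(self):
        from cohortwiring.input_accounting import HistogramBin

        with pytest.raises(ValueError, match="open-ended"):
            HistogramSpec([HistogramBin("1", 1, 2)])
        with pytest.raises(ValueError, match="contiguous"):
            HistogramSpec([HistogramBin("1", 1, 1), HistogramBin("3+", 3, None)])


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_compare([1, 1, 1], [100, 100, 100])
        assert d == 1.0

    def test_hand_enumerated_cdf_gap(self):
        # CDFs of {1,2,3,4} and {2,3,4,5} differ by exactly 1/4 everywhere
        d, _ = ks_compare([1, 2, 3, 4], [2, 3, 4, 5])
        assert d == pytest.approx(0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_compare([], [1])


def pair_catalog():
    recs = lr_pair("t") + lr_pair("p") + lr_pair("q")
    recs.append(record("mid", side="M", homolog_id="mid", morph_class="Ladder"))
    recs.append(record("nohom", homolog_id=None))
    return Catalog(recs)


TARGETS = TargetSet(name="pair", members=["t_L", "t_R"],
                    homolog_pairs=[("t_L", "t_R")])


class TestLrPairFilter:
    @pytest.mark.parametrize("counts, retained", [
        ((4, 2), True),
        ((4, 1), False),
        ((3, 2), False),
        ((2, 4), True),  # high side may be either member
    ])
    def test_threshold_boundaries(self, counts, retained):
        hi, lo = counts
        sub = table_of(("p_L", "t_L", hi), ("p_R", "t_R", lo))
        res = lr_pair_filter(sub, pair_catalog(), TARGETS)
        assert (res.total_neurons == 2) is retained
        if retained:
            assert res.total_synapses == hi + lo

    def test_empty_input(self):
        res = lr_pair_filter(table_of(), pair_catalog(), TARGETS)
        assert res.total_neurons == 0 and res.total_synapses == 0

    def test_midline_neuron_evaluated_against_both_targets(self):
        res = lr_pair_filter(
            table_of(("mid", "t_L", 4), ("mid", "t_R", 2)), pair_catalog(), TARGETS
        )
        assert res.neuron_ids == {"mid"} and res.total_neurons == 1
        assert res.total_synapses == 6

    def test_same_side_counts_do_not_qualify(self):
        # both members contact only t_L: no homologous-target support
        sub = table_of(("p_L", "t_L", 9), ("p_R", "t_L", 9))
        assert lr_pair_filter(sub, pair_catalog(), TARGETS).total_neurons == 0

    def test_unpaired_candidate_skipped_and_logged(self):
        res = lr_pair_filter(
            table_of(("nohom", "t_L", 9), ("nohom", "t_R", 9)),
            pair_catalog(), TARGETS,
        )
        assert res.total_neurons == 0
        assert res.skipped_unpaired == ["nohom"]

    def test_row_order_and_global_side_swap_invariance(self):
        rows = [("p_L", "t_L", 5), ("p_R", "t_R", 3), ("q_L", "t_R", 4),
                ("q_R", "t_L", 1), ("mid", "t_L", 4), ("mid", "t_R", 2)]
        base = lr_pair_filter(table_of(*rows), pair_catalog(), TARGETS)
        for perm in itertools.islice(itertools.permutations(rows), 0, 24, 7):
            res = lr_pair_filter(table_of(*perm), pair_catalog(), TARGETS)
            assert res.neuron_ids == base.neuron_ids

        def swap(nid):
            return nid[:-2] + {"_L": "_R", "_R": "_L"}[nid[-2:]] if nid[-2:] in ("_L", "_R") else nid

        swapped = [(swap(a), swap(b), c) for a, b, c in rows]
        res = lr_pair_filter(table_of(*swapped), pair_catalog(), TARGETS)
        assert {swap(n) for n in res.neuron_ids} == base.neuron_ids

    def test_monotone_in_thresholds(self):
        rows = [("p_L", "t_L", 5), ("p_R", "t_R", 3), ("q_L", "t_L", 4),
                ("q_R", "t_R", 2), ("mid", "t_L", 6), ("mid", "t_R", 2)]
        sub = table_of(*rows)
        cat = pair_catalog()
        prev = None
        for hi in (4, 5, 6, 7):
            members = lr_pair_filter(sub, cat, TARGETS, thr_high=hi).neuron_ids
            if prev is not None:
                assert members <= prev
            prev = members


class TestHighlyConnected:
    @pytest.mark.parametrize("count, included", [(9, False), (10, True)])
    def test_boundary_on_summed_synapses(self, count, included):
        sub = table_of(("p_L", "t_L", count))
        res = highly_connected(sub, pair_catalog(), TARGETS)
        assert (("p_L" in res.members) is included)
        assert (("p_L" in res.qualifying_neurons) is included)

    def test_pair_expansion_includes_weak_member(self):
        sub = table_of(("p_L", "t_L", 12), ("p_R", "t_R", 2))
        res = highly_connected(sub, pair_catalog(), TARGETS)
        assert res.members == {"p_L", "p_R"}
        assert res.qualifying_neurons == {"p_L"}

    def test_summed_across_targets(self):
        sub = table_of(("mid", "t_L", 6), ("mid", "t_R", 5))
        res = highly_connected(sub, pair_catalog(), TARGETS)
        assert "mid" in res.members
        assert res.composition.set_index("morph_class").loc["Ladder", "synapses"] == 11

    def test_empty_input(self):
        res = highly_connected(table_of(), pair_catalog(), TARGETS)
        assert res.members == set()

    def test_monotone_in_min_syn(self, sharp_system):
        ts = sharp_system.target_set()
        sub, _ = inputs_onto(sharp_system.table, ts)
        prev = None
        for m in (5, 10, 15, 20):
            members = highly_connected(sub, sharp_system.catalog, ts, min_syn=m).members
            if prev is not None:
                assert members <= prev
            prev = members
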