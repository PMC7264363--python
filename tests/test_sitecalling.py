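"""Filtering semantics, support aggregation, control subtraction and
condition-set algebra."""

import pytest

from surftopo.core import (
    ExperimentCondition,
    PeptideObservation,
    PipelineConfig,
    ProteinEntry,
)
from surftopo.mapping import SiteEvidence
from surftopo.pipeline import run_pipeline
from surftopo.sites import (
    aggregate_sites,
    called_sets,
    compare_conditions,
    filter_observations,
    subtract_control,
    summarize_counts,
)
from surftopo.simulate import SimulationParams, simulate_study

COND = ExperimentCondition("trypsin", "15min")


def obs(score, mods, peptide="PEPTIDEK"):
    return PeptideObservation(peptide, tuple(mods), score, "s1", COND, obs_id=0)


def evidence(accession="P1", position=11, condition="trypsin:15min", obs_id=0,
             peptide="PEPTIDEK", context="lysine_sidechain", ambiguous=False):
    return SiteEvidence(
        accession=accession,
        position=position,
        context=context,
        mod_name="CAMthiopropanoyl",
        condition_key=condition,
        sample_id=condition,
        obs_id=obs_id,
        peptide=peptide,
        score=5.0,
        ambiguous=ambiguous,
    )


PROTEOME = [ProteinEntry("P1", "MAKPEPTIDEKR", "OOOOOOOOOOOO")]


class TestFilter:
    def test_subthreshold_score_dropped(self):
        kept, dropped = filter_observations(
            [obs(1.9, [(8, 145.0198)])], PipelineConfig()
        )
        assert not kept and dropped["low_score"] == 1

    def test_deamidation_only_dropped(self):
        kept, dropped = filter_observations([obs(3.0, [(5, 0.984)])], PipelineConfig())
        assert not kept and dropped["no_label_mod"] == 1

    def test_boundary_score_with_label_kept(self):
        kept, _ = filter_observations([obs(2.0, [(8, 145.0198)])], PipelineConfig())
        assert len(kept) == 1

    def test_both_label_forms_accepted(self):
        kept, _ = filter_observations(
            [obs(4.0, [(0, 87.9983)]), obs(4.0, [(8, 145.0198)])], PipelineConfig()
        )
        assert len(kept) == 2


class TestAggregation:
    def test_three_observations_call_a_site(self):
        config = PipelineConfig()
        ev = [evidence(obs_id=i) for i in range(3)]
        sites = aggregate_sites(ev, PROTEOME, config)
        assert sites[0].support == {"trypsin:15min": 3}
        assert called_sets(sites, config)["trypsin:15min"] == {("P1", 11)}

    def test_two_observations_do_not(self):
        config = PipelineConfig()
        sites = aggregate_sites([evidence(obs_id=i) for i in range(2)], PROTEOME, config)
        assert called_sets(sites, config)["trypsin:15min"] == set()

    def test_min_support_one_calls_everything(self):
        config = PipelineConfig(min_support=1)
        sites = aggregate_sites([evidence()], PROTEOME, config)
        assert called_sets(sites, config)["trypsin:15min"] == {("P1", 11)}

    def test_distinct_peptide_unit(self):
        config = PipelineConfig(support_unit="distinct_peptides")
        ev = [evidence(obs_id=i, peptide="PEPTIDEK") for i in range(3)]
        sites = aggregate_sites(ev, PROTEOME, config)
        assert sites[0].support["trypsin:15min"] == 1  # one peptide species

    def test_contexts_accumulate_on_one_site(self):
        config = PipelineConfig()
        ev = [
            evidence(obs_id=0, context="lysine_sidechain"),
            evidence(obs_id=1, context="peptide_nterm"),
        ]
        sites = aggregate_sites(ev, PROTEOME, config)
        assert len(sites) == 1
        assert sites[0].contexts == {"lysine_sidechain", "peptide_nterm"}

    def test_ambiguous_only_flag(self):
        config = PipelineConfig()
        sites = aggregate_sites([evidence(ambiguous=True)], PROTEOME, config)
        assert sites[0].ambiguous_only
        sites = aggregate_sites(
            [evidence(ambiguous=True), evidence(obs_id=1)], PROTEOME, config
        )
        assert not sites[0].ambiguous_only


class TestControlSubtraction:
    def make_sites(self):
        config = PipelineConfig()
        return aggregate_sites([evidence(obs_id=i) for i in range(3)], PROTEOME, config)

    def test_robust_control_site_removed(self):
        config = PipelineConfig()
        sites = self.make_sites()
        control = [
            evidence(obs_id=i, condition="none:unlabelled") for i in range(3)
        ]
        sites, removed = subtract_control(sites, control, config)
        assert removed == [("P1", 11)]
        assert called_sets(sites, config)["trypsin:15min"] == set()

    def test_sparse_control_is_identity(self):
        config = PipelineConfig()
        sites = self.make_sites()
        control = [evidence(obs_id=0, condition="none:unlabelled")]
        sites, removed = subtract_control(sites, control, config)
        assert removed == []
        assert called_sets(sites, config)["trypsin:15min"] == {("P1", 11)}

    def test_empty_control_is_identity(self):
        config = PipelineConfig()
        sites, removed = subtract_control(self.make_sites(), [], config)
        assert removed == []


class TestComparison:
    def test_partition_counts(self):
        called = {"c": {("P", 1), ("P", 2)}, "d": {("P", 2), ("P", 3)}}
        comp = compare_conditions(called, "c", ["d"])
        assert comp.counts == {"control_only": 1, "shared": 1, "digest_only": 1}
        assert sum(comp.counts.values()) == comp.union_size

    def test_identical_sets(self):
        called = {"c": {("P", 1)}, "d": {("P", 1)}}
        comp = compare_conditions(called, "c", ["d"])
        assert comp.counts == {"control_only": 0, "shared": 1, "digest_only": 0}

    def test_disjoint_sets(self):
        called = {"c": {("P", 1)}, "d": {("P", 2)}}
        comp = compare_conditions(called, "c", ["d"])
        assert comp.counts["shared"] == 0

    def test_merged_digest_union(self):
        called = {"c": set(), "d1": {("P", 1)}, "d2": {("P", 2)}}
        comp = compare_conditions(called, "c", ["d1", "d2"])
        assert comp.digest_only == {("P", 1), ("P", 2)}


class TestSummary:
    def test_tm_and_non_tm_split(self):
        proteome = [
            ProteinEntry("TM1", "MAKRG", "OOMMI"),
            ProteinEntry("SOL", "MAKRG", "UUUUU"),
        ]
        called = {"c": {("TM1", 1), ("TM1", 2), ("SOL", 3)}}
        frame = summarize_counts(called, proteome)
        row = frame.iloc[0]
        assert row["labelled_tmps"] == 1
        assert row["labelled_positions_tmps"] == 2
        assert row["labelled_non_tm_proteins"] == 1
        assert row["labelled_positions_non_tm"] == 1

    def test_empty_called_set_is_zero(self):
        frame = summarize_counts({"c": set()}, PROTEOME)
        assert frame.iloc[0]["labelled_tmps"] == 0


def test_min_support_monotonicity(small_study):
    """Raising the support threshold never enlarges a called set."""
    previous = None
    for threshold in range(1, 6):
        config = PipelineConfig(min_support=threshold)
        result = run_pipeline(
            small_study.proteins, small_study.observations, config
        )
        sizes = {k: len(v) for k, v in result.called.items()}
        counts = summarize_counts(result.called, small_study.proteins)
        if previous is not None:
            prev_sizes, prev_counts = previous
            for key in sizes:
                assert sizes[key] <= prev_sizes[key]
            assert (
                counts["labelled_positions_tmps"] <= prev_counts["labelled_positions_tmps"]
            ).all()
            assert (counts["labelled_tmps"] <= prev_counts["labelled_tmps"]).all()
        previous = (sizes, counts)


def test_sparse_support_drops_recall_keeps_precision():
    """With mean support 1 nothing reaches the >=3 threshold: recall falls
    below 1 while precision stays 1 (no false sites appear)."""
    params = SimulationParams(
        n_proteins=40, support_mean=1.0, label_efficiency=1.0, contamination_rate=0.0
    )
    study = simulate_study(params, seed=13)
    config = PipelineConfig()
    result = run_pipeline(study.proteins, study.observations, config)
    truth = {
        (s.accession, s.position)
        for s in study.ground_truth.sites
        if s.emitted
    }
    called = result.all_called_sites
    assert truth  # sites were emitted...
    assert called <= truth  # ...precision is perfect...
    assert len(called) < len(truth)  # ...but recall dropped
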