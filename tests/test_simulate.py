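"""The forward simulator: determinism, topology construction, labelling
chemistry and the containment guarantees that make recovery testable."""

import json
import re

import numpy as np
import pytest

from surftopo.core import ConfigError, ExperimentCondition
from surftopo.io import observations_to_frame, read_fasta, read_peptide_table
from surftopo.masses import DEFAULT_LABEL_MASSES
from surftopo.simulate import (
    CAUSE_CONTAMINANT,
    CAUSE_NEW_NTERM,
    CAUSE_UNCOVERED,
    GroundTruth,
    SimulationParams,
    default_conditions,
    emit_dataset,
    generate_proteome,
    simulate_study,
)

LABELLED_KEYS = [c.key for c in default_conditions() if c.labelled]


def has_label(obs):
    return bool(obs.label_mods(DEFAULT_LABEL_MASSES, 0.01))


def test_same_seed_reproduces_study():
    params = SimulationParams(n_proteins=15)
    a = simulate_study(params, seed=3)
    b = simulate_study(params, seed=3)
    assert [(p.accession, p.sequence, p.topology) for p in a.proteins] == [
        (p.accession, p.sequence, p.topology) for p in b.proteins
    ]
    assert observations_to_frame(a.observations).equals(
        observations_to_frame(b.observations)
    )
    assert a.ground_truth.sites == b.ground_truth.sites


def test_single_pass_topology_shape():
    params = SimulationParams(n_proteins=10, single_pass_fraction=1.0)
    proteins, _ = generate_proteome(params, seed=0)
    for protein in proteins:
        assert re.fullmatch(r"O+M+I+|I+M+O+", protein.topology)


def test_multi_pass_topology_has_multiple_membrane_blocks():
    params = SimulationParams(n_proteins=10, single_pass_fraction=0.0)
    proteins, _ = generate_proteome(params, seed=0)
    for protein in proteins:
        assert len(re.findall(r"M+", protein.topology)) >= 2


def test_clean_sites_are_extracellular(clean_study):
    """Membrane protection: without contamination every labelled amine sits
    at an extracellular residue (containment ground-truth invariant)."""
    topo = clean_study.ground_truth.topology
    for site in clean_study.ground_truth.sites:
        assert site.cause != CAUSE_CONTAMINANT
        assert topo[site.accession][site.position - 1] == "O"


def test_non_predigested_conditions_have_no_digestion_causes(clean_study):
    for site in clean_study.ground_truth.sites:
        enzyme, _, duration = site.condition.partition(":")
        if duration in {"NPT", "NPC"}:
            assert site.cause not in {CAUSE_NEW_NTERM, CAUSE_UNCOVERED}


def test_predigestion_creates_new_ntermini(clean_study):
    causes = {
        s.cause
        for s in clean_study.ground_truth.sites
        if s.condition.partition(":")[2] not in {"NPT", "NPC"}
    }
    assert CAUSE_NEW_NTERM in causes


def test_zero_label_efficiency_emits_no_label_evidence():
    params = SimulationParams(
        n_proteins=20, label_efficiency=0.0, contamination_rate=0.0
    )
    study = simulate_study(params, seed=5)
    labelled_obs = [o for o in study.observations if o.condition.labelled]
    assert all(not has_label(o) for o in labelled_obs)
    assert not study.ground_truth.sites


def test_alkylation_fraction_matches_rate(clean_study):
    """~93% of observed labels should be the alkylated (+145.020) form."""
    cam, total = 0, 0
    for obs in clean_study.observations:
        for _, delta in obs.label_mods(DEFAULT_LABEL_MASSES, 0.01):
            total += 1
            cam += abs(delta - 145.0198) <= 0.01
    assert total > 5000
    assert cam / total == pytest.approx(0.93, abs=0.02)


def test_observations_labelled_or_cysteine(clean_study):
    """Affinity-purification specificity: everything retained is either
    biotinylated or a piggyback cysteine peptide."""
    labelled_obs = [o for o in clean_study.observations if o.condition.labelled]
    ok = sum(1 for o in labelled_obs if has_label(o) or "C" in o.peptide)
    assert ok / len(labelled_obs) >= 0.97


def test_buried_lysines_need_predigestion():
    params = SimulationParams(
        n_proteins=40, k_buried_fraction=0.5, label_efficiency=1.0,
        contamination_rate=0.0,
    )
    study = simulate_study(params, seed=9)
    uncovered = [
        s for s in study.ground_truth.sites if s.cause == CAUSE_UNCOVERED
    ]
    assert uncovered  # the mechanism occurs
    for site in uncovered:
        assert site.condition.partition(":")[2] not in {"NPT", "NPC"}
    # a buried K never appears as a site in a non-pre-digested condition
    buried = study.ground_truth.buried
    for site in study.ground_truth.sites:
        if site.condition.partition(":")[2] in {"NPT", "NPC"}:
            assert site.position not in buried.get(site.accession, ())


def test_emitted_peptides_are_unique_and_long(clean_study):
    text = "|".join(p.sequence for p in clean_study.proteins)
    peptides = {
        o.peptide for o in clean_study.observations if o.condition.labelled and has_label(o)
    }
    params = SimulationParams()
    for peptide in peptides:
        assert len(peptide) >= params.min_peptide_length
        first = text.find(peptide)
        assert text.find(peptide, first + 1) == -1


def test_emit_dataset_round_trip(tmp_path, small_study):
    paths = emit_dataset(small_study, tmp_path / "d1")
    proteome = read_fasta(paths["fasta"])
    assert len(proteome) == len(small_study.proteins)
    total = 0
    for condition in small_study.conditions:
        key = f"peptides_{condition.key.replace(':', '_')}"
        total += len(read_peptide_table(paths[key]))
    assert total == len(small_study.observations)
    gt = GroundTruth.from_json(paths["ground_truth"])
    assert len(gt.sites) == len(small_study.ground_truth.sites)
    assert gt.topology == small_study.ground_truth.topology

    # identical seeds produce byte-identical files
    paths2 = emit_dataset(small_study, tmp_path / "d2")
    for name in paths:
        assert paths[name].read_bytes() == paths2[name].read_bytes(), name


def test_ground_truth_json_round_trip(tmp_path, small_study):
    path = tmp_path / "gt.json"
    small_study.ground_truth.to_json(path)
    gt = GroundTruth.from_json(path)
    with open(path) as handle:
        payload = json.load(handle)
    assert payload["seed"] == small_study.ground_truth.seed
    assert gt.abundance == small_study.ground_truth.abundance
    assert gt.expected_called().keys() == set(gt.conditions)


def test_invalid_probability_rejected():
    with pytest.raises(ConfigError, match="label_efficiency"):
        SimulationParams(label_efficiency=1.5)
    with pytest.raises(ConfigError, match="unknown simulation parameter"):
        SimulationParams.from_dict({"labelefficiency": 0.5})


def test_condition_validation():
    with pytest.raises(ValueError):
        ExperimentCondition("none", "NPT")
    assert not ExperimentCondition("trypsin", "NPT").predigested
    assert ExperimentCondition("trypsin", "15min").predigested


def test_abundance_distribution_mean():
    params = SimulationParams(n_proteins=400, support_mean=5.0)
    _, gt = generate_proteome(params, seed=2)
    values = np.array(list(gt.abundance.values()))
    assert values.min() >= 1
    assert values.mean() == pytest.approx(5.0, abs=0.35)
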