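"""Peptide location, modification localization and piggyback flagging."""

import numpy as np
import pytest

from surftopo.core import (
    LYSINE_SIDECHAIN,
    PEPTIDE_NTERM,
    PROTEIN_NTERM,
    ExperimentCondition,
    PeptideObservation,
    PipelineConfig,
    ProteinEntry,
)
from surftopo.mapping import (
    PeptideMatch,
    flag_piggyback,
    locate_peptide,
    localize_modifications,
    map_observations,
)

COND = ExperimentCondition("trypsin", "15min")


def obs(peptide, mods, score=5.0):
    return PeptideObservation(peptide, tuple(mods), score, "s1", COND, obs_id=0)


@pytest.fixture()
def proteome():
    return [
        ProteinEntry("P1", "MAKPEPTIDEKR"),
        ProteinEntry("P2", "MGGGSHAREDKRGG"),
        ProteinEntry("P3", "MSHAREDKRGGGG"),
    ]


def test_locate_exact_occurrence(proteome):
    matches = locate_peptide("PEPTIDEK", proteome)
    assert [(m.accession, m.start, m.end) for m in matches] == [("P1", 4, 11)]
    assert not matches[0].ambiguous


def test_locate_no_match(proteome):
    assert locate_peptide("WWWWW", proteome) == []


def test_locate_multi_locus_sets_ambiguous(proteome):
    matches = locate_peptide("SHAREDKR", proteome)
    assert {(m.accession, m.start) for m in matches} == {("P2", 5), ("P3", 2)}
    assert all(m.ambiguous for m in matches)


def test_short_peptide_warns(proteome):
    with pytest.warns(UserWarning, match="shorter"):
        locate_peptide("MAK", proteome)


def test_locate_agrees_with_all_offsets_scan():
    """Oracle: naive slice comparison at every offset of every protein."""
    rng = np.random.default_rng(4)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteome = [
        ProteinEntry(f"R{i}", "".join(rng.choice(letters, size=60)))
        for i in range(8)
    ]
    for _ in range(1000):
        if rng.random() < 0.5:  # peptide drawn from the proteome
            protein = proteome[rng.integers(len(proteome))]
            start = int(rng.integers(0, len(protein.sequence) - 5))
            length = int(rng.integers(5, min(12, len(protein.sequence) - start)))
            peptide = protein.sequence[start : start + length]
        else:
            peptide = "".join(rng.choice(letters, size=int(rng.integers(5, 10))))
        expected = [
            (p.accession, i + 1, i + len(peptide))
            for p in proteome
            for i in range(len(p.sequence) - len(peptide) + 1)
            if p.sequence[i : i + len(peptide)] == peptide
        ]
        got = [(m.accession, m.start, m.end) for m in locate_peptide(peptide, proteome)]
        assert got == expected


@pytest.mark.parametrize(
    ("match", "mods", "expected"),
    [
        # internal K: protein position = start + pep_pos - 1 = 4 + 8 - 1 = 11
        (("P1", 4, 11), [(8, 145.0198)], [(11, LYSINE_SIDECHAIN)]),
        # alpha-amine on an internal match -> peptide N-terminus
        (("P1", 4, 11), [(0, 87.9983)], [(4, PEPTIDE_NTERM)]),
        # alpha-amine at position 1 -> protein N-terminus
        (("P1", 1, 8), [(0, 145.0198)], [(1, PROTEIN_NTERM)]),
    ],
)
def test_localize_contexts(proteome, match, mods, expected):
    config = PipelineConfig()
    by_acc = {p.accession: p for p in proteome}
    accession, start, end = match
    peptide = by_acc[accession].sequence[start - 1 : end]
    evidence, invalid = localize_modifications(
        PeptideMatch(accession, start, end), obs(peptide, mods), by_acc, config
    )
    assert not invalid
    assert [(e.position, e.context) for e in evidence] == expected


def test_localize_flags_invalid_context(proteome):
    """A label mass on an internal non-lysine is invalid evidence, not lost."""
    config = PipelineConfig()
    by_acc = {p.accession: p for p in proteome}
    # P1[4..11] = PEPTIDEK; peptide position 3 is P (not K)
    evidence, invalid = localize_modifications(
        PeptideMatch("P1", 4, 11), obs("PEPTIDEK", [(3, 145.0198)]), by_acc, config
    )
    assert not evidence
    assert len(invalid) == 1
    assert invalid[0].residue == "P"
    assert invalid[0].position == 6


def test_localize_ignores_deamidation(proteome):
    config = PipelineConfig()
    by_acc = {p.accession: p for p in proteome}
    evidence, invalid = localize_modifications(
        PeptideMatch("P1", 4, 11), obs("PEPTIDEK", [(3, 0.984)]), by_acc, config
    )
    assert not evidence and not invalid


def test_initiator_methionine_rule():
    """A match at position 2 of a Met-initiated protein is the mature N-term."""
    proteome = {"P1": ProteinEntry("P1", "MAKPEPTIDEKR")}
    match = PeptideMatch("P1", 2, 11)
    observation = obs("AKPEPTIDEK", [(0, 145.0198)])
    evidence, _ = localize_modifications(
        match, observation, proteome, PipelineConfig()
    )
    assert evidence[0].context == PROTEIN_NTERM
    evidence, _ = localize_modifications(
        match, observation, proteome,
        PipelineConfig(initiator_met_as_protein_nterm=False),
    )
    assert evidence[0].context == PEPTIDE_NTERM


@pytest.mark.parametrize(
    ("peptide", "mods", "expected"),
    [
        ("ACDK", [], True),
        ("ACDK", [(4, 145.0198)], False),
        ("ADGK", [], False),
    ],
)
def test_flag_piggyback(peptide, mods, expected):
    assert flag_piggyback(obs(peptide, mods), PipelineConfig()) is expected


def test_mapping_recovers_ground_truth_exactly(clean_study):
    """On clean synthetic data, locate + localize recovers precisely the
    emitted (accession, position, context) triples — 100% site-level recall
    and precision at the mapping stage."""
    config = PipelineConfig()
    labelled = [o for o in clean_study.observations if o.condition.labelled]
    result = map_observations(labelled, clean_study.proteins, config)
    got = {(e.accession, e.position, e.context) for e in result.evidence}
    expected = {
        (s.accession, s.position, s.context)
        for s in clean_study.ground_truth.sites
        if s.emitted
    }
    assert got == expected
    assert not result.invalid
    assert not result.unmatched_peptides
    # evidence residue letters are consistent with their contexts
    by_acc = {p.accession: p for p in clean_study.proteins}
    for ev in result.evidence:
        if ev.context == LYSINE_SIDECHAIN:
            assert by_acc[ev.accession].sequence[ev.position - 1] == "K"
        if ev.context == PROTEIN_NTERM:
            # position 2 is the mature N-terminus after initiator-Met excision
            assert ev.position in (1, 2)
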