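"""Peptide-to-proteome mapping and modification-site localization.

Observed peptides are located by exact substring search against the proteome
(deterministic, exhaustively enumerable — the role a permissive short-read
BLAST plays in classic workflows), then each label-mass modification is
converted from peptide coordinates to a protein coordinate with a residue
context: protein N-terminus, peptide N-terminus (a pre-digestion product) or
lysine side chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (
    LABEL_MODS,
    LYSINE_SIDECHAIN,
    PEPTIDE_NTERM,
    PROTEIN_NTERM,
    PeptideObservation,
    PipelineConfig,
    ProteinEntry,
)


@dataclass(frozen=True)
class PeptideMatch:
    """One exact occurrence of a peptide in the proteome (1-based inclusive)."""

    accession: str
    start: int
    end: int
    ambiguous: bool = False


@dataclass(frozen=True)
class SiteEvidence:
    """One observation supporting a label at one protein position."""

    accession: str
    position: int
    context: str
    mod_name: str
    condition_key: str
    sample_id: str
    obs_id: int
    peptide: str
    score: float
    ambiguous: bool


@dataclass(frozen=True)
class InvalidEvidence:
    """A label mod whose residue context is impossible (e.g. internal glycine)."""

    accession: str
    position: int
    residue: str
    peptide: str
    obs_id: int
    reason: str


def locate_peptide(
    peptide: str,
    proteome: Sequence[ProteinEntry],
    min_len_warn: int = 5,
) -> list[PeptideMatch]:
    """All exact occurrences of ``peptide`` across the proteome.

    The ``ambiguous`` flag is set on every match when the total occurrence
    count exceeds one.  Peptides shorter than ``min_len_warn`` are still
    searched but trigger a warning (they are rarely informative).
    """
    if len(peptide) < min_len_warn:
        warnings.warn(
            f"peptide {peptide!r} is shorter than {min_len_warn} residues; "
            "matches are likely ambiguous",
            stacklevel=2,
        )
    matches: list[PeptideMatch] = []
    for protein in proteome:
        start = protein.sequence.find(peptide)
        while start >= 0:
            matches.append(
                PeptideMatch(protein.accession, start + 1, start + len(peptide))
            )
            start = protein.sequence.find(peptide, start + 1)
    if len(matches) > 1:
        matches = [
            PeptideMatch(m.accession, m.start, m.end, ambiguous=True) for m in matches
        ]
    return matches


def _nearest_label(delta: float, config: PipelineConfig) -> str | None:
    best_name, best_err = None, config.mass_tolerance
    for mod in LABEL_MODS:
        err = abs(delta - mod.delta_mass)
        if err <= best_err:
            best_name, best_err = mod.name, err
    if best_name is not None:
        return best_name
    # fall back to configured label masses without a named definition
    for mass in config.label_masses:
        if abs(delta - mass) <= config.mass_tolerance:
            return f"label@{mass:.4f}"
    return None


def localize_modifications(
    match: PeptideMatch,
    observation: PeptideObservation,
    proteome_by_accession: dict[str, ProteinEntry],
    config: PipelineConfig,
) -> tuple[list[SiteEvidence], list[InvalidEvidence]]:
    """Convert an observation's label mods into protein-coordinate evidence.

    A position-0 mod is the peptide's alpha-amine: classified protein
    N-terminus when the match starts the mature protein (position 1, or
    position 2 of a Met-initiated protein when initiator-Met trimming is
    assumed), otherwise peptide N-terminus.  Internal label mods are valid
    only on lysine; anything else is returned as invalid evidence rather
    than silently dropped.
    """
    protein = proteome_by_accession[match.accession]
    evidence: list[SiteEvidence] = []
    invalid: list[InvalidEvidence] = []
    for pep_pos, delta in observation.mods:
        mod_name = _nearest_label(delta, config)
        if mod_name is None:
            continue  # not a label mass (e.g. deamidation)
        if pep_pos == 0:
            position = match.start
            mature_nterm = match.start == 1 or (
                config.initiator_met_as_protein_nterm
                and match.start == 2
                and protein.sequence.startswith("M")
            )
            context = PROTEIN_NTERM if mature_nterm else PEPTIDE_NTERM
        else:
            position = match.start + pep_pos - 1
            residue = protein.sequence[position - 1]
            if residue != "K":
                invalid.append(
                    InvalidEvidence(
                        accession=match.accession,
                        position=position,
                        residue=residue,
                        peptide=observation.peptide,
                        obs_id=observation.obs_id,
                        reason=f"label mod on internal {residue}, expected K",
                    )
                )
                continue
            context = LYSINE_SIDECHAIN
        evidence.append(
            SiteEvidence(
                accession=match.accession,
                position=position,
                context=context,
                mod_name=mod_name,
                condition_key=observation.condition.key,
                sample_id=observation.sample_id,
                obs_id=observation.obs_id,
                peptide=observation.peptide,
                score=observation.score,
                ambiguous=match.ambiguous,
            )
        )
    return evidence, invalid


def flag_piggyback(observation: PeptideObservation, config: PipelineConfig) -> bool:
    """True for a cysteine-containing peptide with no label-mass modification.

    Such peptides co-purify on the affinity column through a disulphide bond
    with a labelled peptide; they are expected in the raw data but carry no
    site evidence.
    """
    if "C" not in observation.peptide:
        return False
    return not observation.label_mods(config.label_masses, config.mass_tolerance)


@dataclass
class MappingResult:
    evidence: list[SiteEvidence]
    invalid: list[InvalidEvidence]
    unmatched_peptides: list[str]
    piggyback_count: int
    ambiguous_peptides: int


def map_observations(
    observations: Iterable[PeptideObservation],
    proteome: Sequence[ProteinEntry],
    config: PipelineConfig,
) -> MappingResult:
    """Locate and localize every observation; collects diagnostics."""
    by_accession = {p.accession: p for p in proteome}
    evidence: list[SiteEvidence] = []
    invalid: list[InvalidEvidence] = []
    unmatched: list[str] = []
    piggyback = 0
    ambiguous_peptides: set[str] = set()
    match_cache: dict[str, list[PeptideMatch]] = {}
    for obs in observations:
        if flag_piggyback(obs, config):
            piggyback += 1
        matches = match_cache.get(obs.peptide)
        if matches is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                matches = locate_peptide(
                    obs.peptide, proteome, config.min_peptide_search_len
                )
            match_cache[obs.peptide] = matches
        if not matches:
            unmatched.append(obs.peptide)
            continue
        if matches[0].ambiguous:
            ambiguous_peptides.add(obs.peptide)
        for match in matches:
            ev, bad = localize_modifications(match, obs, by_accession, config)
            evidence.extend(ev)
            invalid.extend(bad)
    return MappingResult(
        evidence=evidence,
        invalid=invalid,
        unmatched_peptides=unmatched,
        piggyback_count=piggyback,
        ambiguous_peptides=len(ambiguous_peptides),
    )
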