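"""Score/mass filtering, >=3-support site aggregation and condition algebra.

The operative detection rule of the study design: an observation survives
when its confidence score passes the LogProb threshold *and* it carries at
least one label-mass modification; a position becomes a called site in a
condition when it is supported at least ``min_support`` times there.  The
unlabelled control preparation can veto sites (control subtraction), and
called sets are compared across conditions as a Venn partition per enzyme
series.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import PeptideObservation, PipelineConfig, ProteinEntry
from .mapping import SiteEvidence

SiteKey = tuple[str, int]


def filter_observations(
    observations: Iterable[PeptideObservation], config: PipelineConfig
) -> tuple[list[PeptideObservation], Counter]:
    """Keep confidently identified, label-carrying observations.

    Rows failing the score threshold or carrying no label-mass mod (this
    removes deamidation-only rows and piggyback peptides) are dropped; the
    returned counter logs removals by reason.
    """
    kept: list[PeptideObservation] = []
    dropped: Counter = Counter()
    for obs in observations:
        if obs.score < config.min_logprob:
            dropped["low_score"] += 1
            continue
        if not obs.label_mods(config.label_masses, config.mass_tolerance):
            dropped["no_label_mod"] += 1
            continue
        kept.append(obs)
    return kept, dropped


@dataclass
class LabelledSite:
    """A labelled protein position with per-condition support."""

    accession: str
    position: int
    residue: str
    contexts: set[str] = field(default_factory=set)
    mod_names: set[str] = field(default_factory=set)
    support: dict[str, int] = field(default_factory=dict)
    samples: set[str] = field(default_factory=set)
    ambiguous_only: bool = True
    removed_by_control: bool = False

    @property
    def key(self) -> SiteKey:
        return (self.accession, self.position)

    def called_in(self, condition_key: str, min_support: int) -> bool:
        return self.support.get(condition_key, 0) >= min_support


def aggregate_sites(
    evidence: Sequence[SiteEvidence],
    proteome: Sequence[ProteinEntry],
    config: PipelineConfig,
) -> list[LabelledSite]:
    """Group evidence by (accession, position) and count per-condition support.

    Support counts distinct observation rows by default (PSM-level), or
    distinct peptide sequences when ``config.support_unit`` says so.  One
    position may accumulate several contexts (a lysine side chain in one
    peptide, a peptide N-terminus in another); it stays a single site.
    """
    by_accession = {p.accession: p for p in proteome}
    grouped: dict[SiteKey, LabelledSite] = {}
    units: dict[tuple[SiteKey, str], set] = defaultdict(set)
    for ev in evidence:
        key = (ev.accession, ev.position)
        site = grouped.get(key)
        if site is None:
            sequence = by_accession[ev.accession].sequence
            site = LabelledSite(
                accession=ev.accession,
                position=ev.position,
                residue=sequence[ev.position - 1],
            )
            grouped[key] = site
        site.contexts.add(ev.context)
        site.mod_names.add(ev.mod_name)
        site.samples.add(ev.sample_id)
        if not ev.ambiguous:
            site.ambiguous_only = False
        unit = ev.obs_id if config.support_unit == "observations" else ev.peptide
        units[(key, ev.condition_key)].add(unit)
    for (key, condition_key), seen in units.items():
        grouped[key].support[condition_key] = len(seen)
    return sorted(grouped.values(), key=lambda s: s.key)


def called_sets(
    sites: Sequence[LabelledSite],
    config: PipelineConfig,
    condition_keys: Iterable[str] | None = None,
) -> dict[str, set[SiteKey]]:
    """Per-condition called-site sets under the min-support rule."""
    keys = set(condition_keys) if condition_keys is not None else {
        c for site in sites for c in site.support
    }
    out: dict[str, set[SiteKey]] = {key: set() for key in keys}
    for site in sites:
        if site.removed_by_control:
            continue
        for condition_key in keys:
            if site.called_in(condition_key, config.min_support):
                out[condition_key].add(site.key)
    return out


def subtract_control(
    sites: Sequence[LabelledSite],
    control_evidence: Sequence[SiteEvidence],
    config: PipelineConfig,
) -> tuple[list[LabelledSite], list[SiteKey]]:
    """Veto sites that the unlabelled control also 'identified' robustly.

    A site with at least ``control_min_support`` control observations is
    marked removed and excluded from called sets.  With a sparse control
    (the usual case) the output equals the input.
    """
    control_counts: dict[SiteKey, set] = defaultdict(set)
    for ev in control_evidence:
        unit = ev.obs_id if config.support_unit == "observations" else ev.peptide
        control_counts[(ev.accession, ev.position)].add(unit)
    removed: list[SiteKey] = []
    for site in sites:
        if len(control_counts.get(site.key, ())) >= config.control_min_support:
            site.removed_by_control = True
            removed.append(site.key)
    return list(sites), sorted(removed)


@dataclass
class ConditionComparison:
    """Venn partition of one enzyme series: control vs merged digests."""

    enzyme: str
    control_key: str
    digest_keys: tuple[str, ...]
    control_only: set[SiteKey]
    shared: set[SiteKey]
    digest_only: set[SiteKey]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "control_only": len(self.control_only),
            "shared": len(self.shared),
            "digest_only": len(self.digest_only),
        }

    @property
    def union_size(self) -> int:
        return len(self.control_only | self.shared | self.digest_only)

    @property
    def gained(self) -> set[SiteKey]:
        """Sites the pre-digestion step added."""
        return self.digest_only

    @property
    def lost(self) -> set[SiteKey]:
        """Sites lost to pre-digestion (control-only)."""
        return self.control_only


def compare_conditions(
    called: Mapping[str, set[SiteKey]],
    control_key: str,
    digest_keys: Sequence[str],
    enzyme: str = "",
) -> ConditionComparison:
    """Partition {control} vs the union of an enzyme's treated conditions."""
    if not digest_keys:
        raise ValueError("at least one digest condition is required")
    control = set(called.get(control_key, set()))
    digest: set[SiteKey] = set()
    for key in digest_keys:
        digest |= called.get(key, set())
    return ConditionComparison(
        enzyme=enzyme,
        control_key=control_key,
        digest_keys=tuple(digest_keys),
        control_only=control - digest,
        shared=control & digest,
        digest_only=digest - control,
    )


def summarize_counts(
    called: Mapping[str, set[SiteKey]],
    proteome: Sequence[ProteinEntry],
    condition_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-condition counts of labelled TM proteins and their positions.

    A protein counts as transmembrane when its annotation contains at least
    one ``M`` residue; sites on proteins without membrane segments are
    tallied separately.
    """
    tm = {p.accession for p in proteome if p.is_transmembrane}
    rows = []
    keys = condition_order if condition_order is not None else sorted(called)
    for key in keys:
        site_set = called.get(key, set())
        tm_sites = {s for s in site_set if s[0] in tm}
        non_tm_sites = site_set - tm_sites
        rows.append(
            {
                "condition": key,
                "labelled_tmps": len({acc for acc, _ in tm_sites}),
                "labelled_positions_tmps": len(tm_sites),
                "labelled_non_tm_proteins": len({acc for acc, _ in non_tm_sites}),
                "labelled_positions_non_tm": len(non_tm_sites),
            }
        )
    return pd.DataFrame(rows)


def sites_to_frame(
    sites: Sequence[LabelledSite],
    config: PipelineConfig,
    condition_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Called-site table: per-condition support and called flags."""
    keys = condition_order if condition_order is not None else sorted(
        {c for site in sites for c in site.support}
    )
    rows = []
    for site in sites:
        row = {
            "accession": site.accession,
            "position": site.position,
            "residue": site.residue,
            "contexts": ";".join(sorted(site.contexts)),
            "mods": ";".join(sorted(site.mod_names)),
            "ambiguous_only": site.ambiguous_only,
            "removed_by_control": site.removed_by_control,
        }
        for key in keys:
            row[f"support[{key}]"] = site.support.get(key, 0)
            row[f"called[{key}]"] = (
                not site.removed_by_control
                and site.called_in(key, config.min_support)
            )
        rows.append(row)
    return pd.DataFrame(rows)
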