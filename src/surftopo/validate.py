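"""Topology validation of called sites and mechanism statistics.

Each called site is classified against a reference annotation:
``Extracellular`` when the reference marks the residue extracellular,
``Intracellular`` when the reference places it anywhere not extracellular
(including membrane-embedded), and ``Unknown`` when no reference data exists.
Accuracy is the extracellular fraction among sites with a known class —
the quantity that certifies the labelling chemistry stayed outside intact
cells.  Called sites are also exported as extracellular ("O") constraints
for consensus topology predictors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import PEPTIDE_NTERM, PROTEIN_NTERM, ProteinEntry
from .mapping import SiteEvidence
from .sites import SiteKey

EXTRACELLULAR = "Extracellular"
INTRACELLULAR = "Intracellular"
UNKNOWN = "Unknown"
CLASSES = (EXTRACELLULAR, UNKNOWN, INTRACELLULAR)


@dataclass(frozen=True)
class ValidationRecord:
    accession: str
    position: int
    reference_class: str


def classify_site(
    site: SiteKey, proteome_by_accession: Mapping[str, ProteinEntry]
) -> ValidationRecord:
    """Classify one called site against the reference topology.

    ``O`` -> Extracellular; ``I`` or ``M`` -> Intracellular (i.e. "not
    extracellular"); ``U`` or missing annotation -> Unknown.  An
    out-of-range position is an error.
    """
    accession, position = site
    protein = proteome_by_accession.get(accession)
    if protein is None:
        return ValidationRecord(accession, position, UNKNOWN)
    if not 1 <= position <= len(protein):
        raise ValueError(
            f"position {position} outside {accession} (length {len(protein)})"
        )
    if protein.topology is None:
        return ValidationRecord(accession, position, UNKNOWN)
    label = protein.topology[position - 1]
    if label == "O":
        cls = EXTRACELLULAR
    elif label in "IM":
        cls = INTRACELLULAR
    else:
        cls = UNKNOWN
    return ValidationRecord(accession, position, cls)


@dataclass
class ValidationSummary:
    """Per-condition class counts plus merged-unique accuracy."""

    per_condition: dict[str, Counter] = field(default_factory=dict)
    merged_counts: Counter = field(default_factory=Counter)
    merged_unique_sites: int = 0
    accuracy: float | None = None  # None when no known-class site exists
    known_fraction: float | None = None
    membrane_calls: int = 0  # Intracellular calls sitting on M residues

    def table(self, condition_order: Sequence[str] | None = None) -> pd.DataFrame:
        keys = condition_order if condition_order is not None else sorted(
            self.per_condition
        )
        data = {
            key: [self.per_condition.get(key, Counter()).get(c, 0) for c in CLASSES]
            for key in keys
        }
        return pd.DataFrame(data, index=list(CLASSES))

    def to_dict(self) -> dict:
        return {
            "per_condition": {k: dict(v) for k, v in self.per_condition.items()},
            "merged_counts": dict(self.merged_counts),
            "merged_unique_sites": self.merged_unique_sites,
            "accuracy": self.accuracy,
            "accuracy_pct": None if self.accuracy is None else round(
                100.0 * self.accuracy, 1
            ),
            "known_fraction": self.known_fraction,
            "membrane_calls": self.membrane_calls,
        }


def summarize_validation(
    called: Mapping[str, set[SiteKey]],
    reference_proteome: Sequence[ProteinEntry],
) -> ValidationSummary:
    """Classify every called site per condition and over the merged unique set.

    Accuracy = Extracellular / (Extracellular + Intracellular) over the
    merged unique sites with a known class; reported as ``None`` when no
    known-class site exists.  Membrane-residue calls are counted separately
    so membrane-adjacent placements remain visible even though they score as
    "not extracellular".
    """
    by_accession = {p.accession: p for p in reference_proteome}
    summary = ValidationSummary()
    merged: dict[SiteKey, str] = {}
    membrane = 0
    for condition_key, site_set in called.items():
        counts: Counter = Counter()
        for site in sorted(site_set):
            record = classify_site(site, by_accession)
            counts[record.reference_class] += 1
            merged[site] = record.reference_class
            protein = by_accession.get(site[0])
            if (
                record.reference_class == INTRACELLULAR
                and protein is not None
                and protein.topology is not None
                and protein.topology[site[1] - 1] == "M"
            ):
                membrane += 1
        summary.per_condition[condition_key] = counts
    summary.merged_counts = Counter(merged.values())
    summary.merged_unique_sites = len(merged)
    known = summary.merged_counts[EXTRACELLULAR] + summary.merged_counts[INTRACELLULAR]
    if known > 0:
        summary.accuracy = summary.merged_counts[EXTRACELLULAR] / known
    if summary.merged_unique_sites > 0:
        summary.known_fraction = known / summary.merged_unique_sites
    summary.membrane_calls = membrane
    return summary


def mechanism_stats(
    evidence: Sequence[SiteEvidence],
    called: Mapping[str, set[SiteKey]],
    control_keys: Sequence[str],
    digest_keys: Sequence[str],
    ground_truth_causes: Mapping[SiteKey, set[str]] | None = None,
) -> dict:
    """How much of the signal did pre-digestion create?

    Reports (a) the fraction of N-terminally labelled peptides detected only
    in pre-digested conditions (new N-termini formation) and (b) the
    fraction of all called sites unique to pre-digested conditions
    (uncovering of inaccessible regions).  When simulation ground truth is
    available the digest-only sites are cross-tabulated with their
    generation cause.
    """
    import warnings as _warnings

    if not digest_keys:
        _warnings.warn("no pre-digested conditions supplied; fractions are 0")
        return {
            "nterm_peptides_digest_only_fraction": 0.0,
            "sites_digest_only_fraction": 0.0,
            "n_nterm_peptides": 0,
            "n_sites": 0,
            "digest_only_cause_counts": {},
        }
    digest_set = set(digest_keys)
    control_set = set(control_keys)

    nterm_conditions: dict[str, set[str]] = {}
    for ev in evidence:
        if ev.context in (PROTEIN_NTERM, PEPTIDE_NTERM):
            nterm_conditions.setdefault(ev.peptide, set()).add(ev.condition_key)
    n_nterm = len(nterm_conditions)
    nterm_digest_only = sum(
        1 for conds in nterm_conditions.values() if conds and conds <= digest_set
    )

    all_called: set[SiteKey] = set()
    digest_called: set[SiteKey] = set()
    control_called: set[SiteKey] = set()
    for key, site_set in called.items():
        all_called |= site_set
        if key in digest_set:
            digest_called |= site_set
        if key in control_set:
            control_called |= site_set
    digest_only_sites = digest_called - control_called

    cause_counts: Counter = Counter()
    if ground_truth_causes is not None:
        for site in digest_only_sites:
            for cause in ground_truth_causes.get(site, {"unknown"}):
                cause_counts[cause] += 1

    return {
        "nterm_peptides_digest_only_fraction": (
            nterm_digest_only / n_nterm if n_nterm else 0.0
        ),
        "sites_digest_only_fraction": (
            len(digest_only_sites) / len(all_called) if all_called else 0.0
        ),
        "n_nterm_peptides": n_nterm,
        "n_sites": len(all_called),
        "n_digest_only_sites": len(digest_only_sites),
        "digest_only_cause_counts": dict(cause_counts),
    }


def write_constraints(
    called_sites: set[SiteKey] | Sequence[SiteKey], path: str | Path
) -> None:
    """Export called sites as extracellular constraints for topology predictors.

    One tab-separated line per site: ``accession<TAB>position<TAB>O``,
    sorted by accession then position.  Only "O" constraints are ever
    emitted — this evidence type says nothing about intracellular residues.
    """
    with open(path, "w") as handle:
        for accession, position in sorted(set(called_sites)):
            handle.write(f"{accession}\t{position}\tO\n")


def read_constraints(path: str | Path) -> set[SiteKey]:
    sites: set[SiteKey] = set()
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            accession, position, label = line.split("\t")
            if label != "O":
                raise ValueError(f"unexpected constraint label {label!r}")
            sites.add((accession, int(position)))
    return sites


def plot_venn(
    comparison, path: str | Path, title: str | None = None
) -> None:
    """Two-set Venn diagram (control vs merged digests) drawn with circles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((-0.4, 0), 1.0, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.4, 0), 1.0, alpha=0.4, color="tab:orange"))
    counts = comparison.counts
    ax.text(-0.9, 0, str(counts["control_only"]), ha="center", va="center", fontsize=14)
    ax.text(0.0, 0, str(counts["shared"]), ha="center", va="center", fontsize=14)
    ax.text(0.9, 0, str(counts["digest_only"]), ha="center", va="center", fontsize=14)
    ax.text(-0.9, 1.15, comparison.control_key, ha="center", fontsize=10)
    ax.text(0.9, 1.15, f"{comparison.enzyme} digest (merged)", ha="center", fontsize=10)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.4, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
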