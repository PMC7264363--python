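"""End-to-end orchestration: filter -> map -> aggregate -> subtract control
-> compare -> validate -> export, with a reproducibility manifest."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .core import PeptideObservation, PipelineConfig, ProteinEntry
from .mapping import MappingResult, flag_piggyback, map_observations
from .sites import (
    ConditionComparison,
    LabelledSite,
    SiteKey,
    aggregate_sites,
    called_sets,
    compare_conditions,
    filter_observations,
    sites_to_frame,
    subtract_control,
    summarize_counts,
)
from .validate import (
    ValidationSummary,
    mechanism_stats,
    summarize_validation,
    write_constraints,
)

NO_PREDIGEST_LABELS = frozenset({"NPT", "NPC"})


@dataclass
class PipelineResult:
    config: PipelineConfig
    condition_keys: list[str]
    dropped: dict[str, int]
    mapping: MappingResult
    sites: list[LabelledSite]
    called: dict[str, set[SiteKey]]
    removed_by_control: list[SiteKey]
    comparisons: dict[str, ConditionComparison]
    validation: ValidationSummary
    mechanism: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def all_called_sites(self) -> set[SiteKey]:
        out: set[SiteKey] = set()
        for site_set in self.called.values():
            out |= site_set
        return out


def _series_structure(
    condition_keys: Sequence[str],
) -> tuple[dict[str, tuple[str, list[str]]], list[str], list[str]]:
    """Group labelled conditions into enzyme series (control, digests)."""
    series: dict[str, tuple[str | None, list[str]]] = {}
    controls: list[str] = []
    digests: list[str] = []
    for key in condition_keys:
        if key.endswith(":unlabelled"):
            continue
        enzyme, _, rest = key.partition(":")
        duration = rest
        control, members = series.get(enzyme, (None, []))
        if duration in NO_PREDIGEST_LABELS:
            control = key
            controls.append(key)
        else:
            members.append(key)
            digests.append(key)
        series[enzyme] = (control, members)
    complete = {
        enzyme: (control, members)
        for enzyme, (control, members) in series.items()
        if control is not None and members
    }
    return complete, controls, digests


def run_pipeline(
    proteome: Sequence[ProteinEntry],
    observations: Sequence[PeptideObservation],
    config: PipelineConfig,
    reference_proteome: Sequence[ProteinEntry] | None = None,
    ground_truth_causes: Mapping[SiteKey, set[str]] | None = None,
) -> PipelineResult:
    """Run the whole site-calling and validation pipeline in memory.

    ``proteome`` carries the (predicted) topology used for TM-protein
    bookkeeping; ``reference_proteome`` optionally carries the independent
    experimental annotation used for validation (defaults to ``proteome``).
    """
    warnings_log: list[str] = []
    labelled_obs = [o for o in observations if o.condition.labelled]
    control_obs = [o for o in observations if not o.condition.labelled]

    kept, dropped = filter_observations(labelled_obs, config)
    mapping = map_observations(kept, proteome, config)
    # piggybacks never pass the label filter; count them on the raw rows
    mapping.piggyback_count = sum(
        1 for o in labelled_obs if flag_piggyback(o, config)
    )

    control_kept, _ = filter_observations(control_obs, config)
    control_mapping = map_observations(control_kept, proteome, config)

    sites = aggregate_sites(mapping.evidence, proteome, config)
    sites, removed = subtract_control(sites, control_mapping.evidence, config)

    condition_keys = sorted({o.condition.key for o in labelled_obs})
    called = called_sets(sites, config, condition_keys)

    series, control_keys, digest_keys = _series_structure(condition_keys)
    comparisons = {
        enzyme: compare_conditions(called, control, members, enzyme=enzyme)
        for enzyme, (control, members) in series.items()
    }

    if reference_proteome is None:
        reference_proteome = proteome
    if all(p.topology is None for p in reference_proteome):
        warnings_log.append(
            "no topology available; validation classes are all Unknown"
        )
    validation = summarize_validation(called, reference_proteome)
    mechanism = mechanism_stats(
        mapping.evidence, called, control_keys, digest_keys, ground_truth_causes
    )
    if not called or not any(called.values()):
        warnings_log.append("no sites called; outputs are empty")

    return PipelineResult(
        config=config,
        condition_keys=condition_keys,
        dropped=dict(dropped),
        mapping=mapping,
        sites=sites,
        called=called,
        removed_by_control=removed,
        comparisons=comparisons,
        validation=validation,
        mechanism=mechanism,
        warnings=warnings_log,
    )


def write_results(
    result: PipelineResult,
    proteome: Sequence[ProteinEntry],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write called-site TSV, validation tables, comparisons, constraints."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["called_sites"] = out / "called_sites.tsv"
    sites_to_frame(result.sites, result.config, result.condition_keys).to_csv(
        paths["called_sites"], sep="\t", index=False
    )

    paths["summary_counts"] = out / "summary_counts.tsv"
    summarize_counts(result.called, proteome, result.condition_keys).to_csv(
        paths["summary_counts"], sep="\t", index=False
    )

    paths["validation_table"] = out / "validation_table.tsv"
    result.validation.table(result.condition_keys).to_csv(
        paths["validation_table"], sep="\t"
    )

    paths["validation"] = out / "validation.json"
    with open(paths["validation"], "w") as handle:
        json.dump(
            {
                "validation": result.validation.to_dict(),
                "mechanism": result.mechanism,
                "dropped_observations": result.dropped,
                "removed_by_control": [list(s) for s in result.removed_by_control],
                "piggyback_observations": result.mapping.piggyback_count,
                "ambiguous_peptides": result.mapping.ambiguous_peptides,
                "invalid_evidence": len(result.mapping.invalid),
                "warnings": result.warnings,
            },
            handle,
            indent=2,
        )

    paths["comparisons"] = out / "comparisons.json"
    with open(paths["comparisons"], "w") as handle:
        json.dump(
            {
                enzyme: {
                    "control": comp.control_key,
                    "digests": list(comp.digest_keys),
                    **comp.counts,
                    "union": comp.union_size,
                }
                for enzyme, comp in result.comparisons.items()
            },
            handle,
            indent=2,
        )

    paths["constraints"] = out / "constraints.tsv"
    write_constraints(result.all_called_sites, paths["constraints"])
    return paths


def write_manifest(
    out_dir: str | Path,
    config: PipelineConfig,
    inputs: Mapping[str, str],
    seed: int | None = None,
    timings: Mapping[str, float] | None = None,
) -> Path:
    """Reproducibility manifest: config snapshot, input digests, seed, version."""
    payload = {
        "tool": "surftopo",
        "version": __version__,
        "created_unix_time": int(time.time()),
        "seed": seed,
        "config": {
            **{k: getattr(config, k) for k in config.__dataclass_fields__},
            "label_masses": list(config.label_masses),
        },
        "input_sha256": dict(inputs),
        "stage_timings_s": dict(timings) if timings else {},
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
    return path
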