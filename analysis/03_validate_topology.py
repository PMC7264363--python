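#!/usr/bin/env python
"""Validate called sites against the reference topology.

Classifies every called site as Extracellular / Unknown / Intracellular
against the partial reference annotation, reports the accuracy over sites
with known class, the pre-digestion mechanism fractions (cross-tabulated
with the generative causes), writes the extracellular constraint file and
draws the per-enzyme Venn figures.
"""

import argparse
from pathlib import Path

from surftopo.core import PipelineConfig
from surftopo.io import read_fasta, read_peptide_tables, read_topology
from surftopo.pipeline import run_pipeline
from surftopo.simulate import GroundTruth
from surftopo.validate import plot_venn, read_constraints, write_constraints


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    proteome, _ = read_topology(
        args.dataset / "topology.tsv", read_fasta(args.dataset / "proteome.fasta")
    )
    reference, _ = read_topology(
        args.dataset / "topology_reference.tsv",
        read_fasta(args.dataset / "proteome.fasta"),
    )
    observations = read_peptide_tables(sorted(args.dataset.glob("peptides_*.csv")))
    gt = GroundTruth.from_json(args.dataset / "ground_truth.json")
    causes = {}
    for site in gt.sites:
        causes.setdefault((site.accession, site.position), set()).add(site.cause)

    config = PipelineConfig()
    result = run_pipeline(
        proteome,
        observations,
        config,
        reference_proteome=reference,
        ground_truth_causes=causes,
    )

    validation = result.validation
    print("validation classes per condition (reference annotation):")
    print(validation.table(result.condition_keys).to_string())
    print()
    acc = validation.accuracy
    print(f"merged unique sites: {validation.merged_unique_sites}")
    print(f"class counts (merged): {dict(validation.merged_counts)}")
    print(f"accuracy over known sites: {'N/A' if acc is None else f'{100 * acc:.1f}%'}")
    print(f"known fraction: {100 * validation.known_fraction:.1f}%")
    print()
    mech = result.mechanism
    print(
        "N-terminally labelled peptides seen only after pre-digestion: "
        f"{100 * mech['nterm_peptides_digest_only_fraction']:.1f}% "
        f"of {mech['n_nterm_peptides']}"
    )
    print(
        "called sites unique to pre-digested samples: "
        f"{100 * mech['sites_digest_only_fraction']:.1f}% of {mech['n_sites']}"
    )
    print(f"digest-only sites by generative cause: {mech['digest_only_cause_counts']}")

    constraints_path = args.out_dir / "constraints.tsv"
    write_constraints(result.all_called_sites, constraints_path)
    assert read_constraints(constraints_path) == result.all_called_sites
    print(f"\nextracellular constraints written: {constraints_path}")
    for enzyme, comparison in result.comparisons.items():
        figure = args.out_dir / f"venn_{enzyme}.png"
        plot_venn(comparison, figure, title=f"{enzyme} series")
        print(f"venn figure: {figure}")


if __name__ == "__main__":
    main()
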