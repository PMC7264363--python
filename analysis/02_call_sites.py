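#!/usr/bin/env python
"""Call labelled sites from the simulated dataset.

Runs filter -> map -> aggregate -> control subtraction on the files written
by 01_simulate.py, prints the per-condition labelled-TMP/position table and
the per-enzyme Venn partition (control vs merged pre-digested samples), and
writes the called-site tables under the run directory.
"""

import argparse
from pathlib import Path

from surftopo.core import PipelineConfig
from surftopo.io import read_fasta, read_peptide_tables, read_topology
from surftopo.pipeline import run_pipeline, write_results
from surftopo.sites import summarize_counts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    proteome, _ = read_topology(
        args.dataset / "topology.tsv", read_fasta(args.dataset / "proteome.fasta")
    )
    reference, _ = read_topology(
        args.dataset / "topology_reference.tsv",
        read_fasta(args.dataset / "proteome.fasta"),
    )
    observations = read_peptide_tables(sorted(args.dataset.glob("peptides_*.csv")))

    config = PipelineConfig()
    result = run_pipeline(proteome, observations, config, reference_proteome=reference)
    paths = write_results(result, proteome, args.out_dir)

    print(f"observations read: {len(observations)}")
    print(f"dropped by filter: {result.dropped}")
    print(f"piggyback (cysteine, unlabelled) observations: {result.mapping.piggyback_count}")
    print()
    print("labelled TMPs and positions per condition:")
    print(summarize_counts(result.called, proteome, result.condition_keys).to_string(index=False))
    print()
    for enzyme, comp in result.comparisons.items():
        counts = comp.counts
        print(
            f"{enzyme}: {comp.control_key} only {counts['control_only']}, "
            f"shared {counts['shared']}, digest only {counts['digest_only']} "
            f"(union {comp.union_size})"
        )
    print()
    print(f"outputs: {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
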