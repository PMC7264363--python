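"""File I/O: FASTA proteomes, topology TSVs and peptide observation tables.

Peptide observation tables are CSV/TSV with header columns
``sample_id, enzyme, duration, labelled, peptide, mods, score`` where ``mods``
is a semicolon-separated list of ``pos:delta`` pairs (empty for unmodified
peptides).  This emulates a flattened search-engine export.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExperimentCondition, PeptideObservation, ProteinEntry

PEPTIDE_TABLE_COLUMNS = [
    "sample_id",
    "enzyme",
    "duration",
    "labelled",
    "peptide",
    "mods",
    "score",
]


class ParseError(ValueError):
    """An input file violates the expected format."""


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a (multi-record) FASTA proteome.

    Sequences are uppercased, record order is preserved, and duplicate
    accessions raise a :class:`ParseError` naming the offending record.
    """
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if not accession:
            raise ParseError(f"{path}: FASTA record with empty header")
        if accession in seen:
            raise ParseError(f"{path}: duplicate accession {accession!r}")
        sequence = str(record.seq).upper()
        if not sequence:
            raise ParseError(f"{path}: record {accession!r} has an empty sequence")
        seen.add(accession)
        entries.append(ProteinEntry(accession, sequence))
    return entries


def write_fasta(proteome: Iterable[ProteinEntry], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="") for p in proteome
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_topology(
    path: str | Path, proteome: Sequence[ProteinEntry]
) -> tuple[list[ProteinEntry], list[str]]:
    """Attach per-residue topology strings from a 2-column TSV.

    Returns ``(proteome_with_topology, unmatched_accessions)``.  Proteins
    without a topology row receive an all-``U`` (no data) annotation; a
    topology whose length disagrees with the sequence raises
    :class:`ParseError` naming the accession.
    """
    table: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            table[parts[0]] = parts[1].upper()

    by_accession = {p.accession for p in proteome}
    unmatched = sorted(set(table) - by_accession)

    attached: list[ProteinEntry] = []
    for protein in proteome:
        if protein.accession in table:
            topology = table[protein.accession]
            try:
                attached.append(protein.with_topology(topology))
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
        else:
            attached.append(protein.with_topology("U" * len(protein)))
    return attached, unmatched


def write_topology(proteome: Iterable[ProteinEntry], path: str | Path) -> None:
    with open(path, "w") as handle:
        for protein in proteome:
            if protein.topology is not None:
                handle.write(f"{protein.accession}\t{protein.topology}\n")


def format_mods(mods: Iterable[tuple[int, float]]) -> str:
    return ";".join(f"{pos}:{delta:.4f}" for pos, delta in mods)


def parse_mods(text: str) -> tuple[tuple[int, float], ...]:
    if not text or (isinstance(text, float) and pd.isna(text)):
        return ()
    out = []
    for item in str(text).split(";"):
        pos_text, _, delta_text = item.partition(":")
        out.append((int(pos_text), float(delta_text)))
    return tuple(out)


def observations_to_frame(observations: Iterable[PeptideObservation]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": obs.sample_id,
            "enzyme": obs.condition.enzyme,
            "duration": obs.condition.duration_label,
            "labelled": obs.condition.labelled,
            "peptide": obs.peptide,
            "mods": format_mods(obs.mods),
            "score": obs.score,
        }
        for obs in observations
    ]
    return pd.DataFrame(rows, columns=PEPTIDE_TABLE_COLUMNS)


def frame_to_observations(frame: pd.DataFrame, start_id: int = 0) -> list[PeptideObservation]:
    missing = set(PEPTIDE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"peptide table missing columns: {sorted(missing)}")
    observations = []
    for offset, row in enumerate(frame.itertuples(index=False)):
        condition = ExperimentCondition(
            enzyme=str(row.enzyme),
            duration_label=str(row.duration),
            labelled=_parse_bool(row.labelled),
        )
        observations.append(
            PeptideObservation(
                peptide=str(row.peptide),
                mods=parse_mods(row.mods),
                score=float(row.score),
                sample_id=str(row.sample_id),
                condition=condition,
                obs_id=start_id + offset,
            )
        )
    return observations


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ParseError(f"cannot interpret {value!r} as a boolean")


def read_peptide_table(path: str | Path, start_id: int = 0) -> list[PeptideObservation]:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[])
    return frame_to_observations(frame, start_id=start_id)


def write_peptide_table(
    observations: Iterable[PeptideObservation], path: str | Path
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    observations_to_frame(observations).to_csv(path, sep=sep, index=False)


def read_peptide_tables(paths: Sequence[str | Path]) -> list[PeptideObservation]:
    """Read several per-condition tables, assigning globally unique obs ids."""
    observations: list[PeptideObservation] = []
    for path in paths:
        observations.extend(read_peptide_table(path, start_id=len(observations)))
    return observations


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
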