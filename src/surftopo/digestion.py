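"""Protease cleavage models.

Two regimes are needed: complete digestion of solubilized membrane
preparations (16 h proteomics-grade trypsin), and mild partial proteolysis of
the intact cell surface, modelled as independent Bernoulli cuts at eligible
sites.  Both share one site-eligibility rule: cleave C-terminal of the
enzyme's P1 residues, optionally suppressed before proline (Keil rule), and
never after a blocked residue — a labelled lysine side chain is invisible to
trypsin, which is the mechanism that forces missed cleavages around labelled
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import ProteinEntry


@dataclass(frozen=True)
class EnzymeRule:
    """P1 specificity of a protease."""

    name: str
    cleave_after: frozenset[str]
    block_before_proline: bool = True

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError(f"enzyme {self.name!r} has an empty residue set")


TRYPSIN = EnzymeRule("trypsin", frozenset("KR"))
#: Chymotrypsin with the five high-specificity P1 residues only.
CHYMOTRYPSIN = EnzymeRule("chymotrypsin", frozenset("FYWML"))

ENZYMES = {rule.name: rule for rule in (TRYPSIN, CHYMOTRYPSIN)}


@dataclass(frozen=True)
class Fragment:
    """A digestion product in 1-based inclusive protein coordinates."""

    accession: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("fragment start must be <= end")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("fragment sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(
    sequence: str,
    rule: EnzymeRule,
    blocked_positions: Iterable[int] = (),
    restrict_to: Iterable[int] | None = None,
) -> list[int]:
    """Eligible cut positions; a cut at ``p`` severs the bond after residue p.

    A position ``p`` (1-based) is a cut site iff residue p is in the enzyme's
    P1 set, p is not the final residue, p is not blocked (e.g. a labelled
    lysine), and — when the Keil rule is on — residue p+1 is not proline.
    ``restrict_to`` optionally limits candidates to a set of positions
    (e.g. extracellular residues for surface digestion).
    """
    blocked = set(blocked_positions)
    allowed = None if restrict_to is None else set(restrict_to)
    sites = []
    for p in range(1, len(sequence)):  # final residue can never be a cut
        if sequence[p - 1] not in rule.cleave_after:
            continue
        if p in blocked:
            continue
        if allowed is not None and p not in allowed:
            continue
        if rule.block_before_proline and sequence[p] == "P":
            continue
        sites.append(p)
    return sites


def fragments_between(protein: ProteinEntry, cuts: Sequence[int]) -> list[Fragment]:
    """Partition a protein at the given cut positions (sorted, deduplicated)."""
    bounds = [0, *sorted(set(cuts)), len(protein.sequence)]
    return [
        Fragment(
            protein.accession,
            start + 1,
            end,
            protein.sequence[start:end],
        )
        for start, end in zip(bounds, bounds[1:])
    ]


def digest_full(
    protein: ProteinEntry,
    rule: EnzymeRule,
    blocked_positions: Iterable[int] = (),
    max_missed_cleavages: int = 0,
) -> list[Fragment]:
    """Complete digestion.

    With 0 missed cleavages the fragments partition the sequence; with
    ``m > 0`` every concatenation of up to ``m + 1`` adjacent fragments is
    additionally emitted, ordered by start then end coordinate.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    cuts = cleavage_sites(protein.sequence, rule, blocked_positions)
    base = fragments_between(protein, cuts)
    if max_missed_cleavages == 0:
        return base
    out = []
    for i in range(len(base)):
        for j in range(i, min(i + max_missed_cleavages + 1, len(base))):
            start, end = base[i].start, base[j].end
            out.append(
                Fragment(
                    protein.accession,
                    start,
                    end,
                    protein.sequence[start - 1 : end],
                )
            )
    out.sort(key=lambda f: (f.start, f.end))
    return out


def digest_partial(
    protein: ProteinEntry,
    rule: EnzymeRule,
    p_cleave: float,
    rng: np.random.Generator | int,
    blocked_positions: Iterable[int] = (),
    restrict_to: Iterable[int] | None = None,
) -> list[Fragment]:
    """Mild digestion: each eligible site is cut independently with ``p_cleave``.

    The output fragments partition the sequence and are bit-reproducible for a
    given seed.  ``p_cleave`` maps monotonically to digestion time.
    """
    if not 0.0 <= p_cleave <= 1.0:
        raise ValueError("p_cleave must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sites = cleavage_sites(protein.sequence, rule, blocked_positions, restrict_to)
    if p_cleave == 0.0 or not sites:
        if sites:
            rng.random(len(sites))  # keep the stream position deterministic
        return fragments_between(protein, [])
    mask = rng.random(len(sites)) < p_cleave
    cuts = [p for p, keep in zip(sites, mask) if keep]
    return fragments_between(protein, cuts)


def fragments_to_tsv(fragments: Iterable[Fragment], path) -> None:
    """BED-like debugging dump: accession, start, end, sequence."""
    with open(path, "w") as handle:
        for frag in fragments:
            handle.write(f"{frag.accession}\t{frag.start}\t{frag.end}\t{frag.sequence}\n")
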