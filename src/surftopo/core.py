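"""Domain types shared by every pipeline stage.

Coordinates are 1-based inclusive throughout (UniProt convention).  A
modification position of 0 denotes the peptide N-terminal alpha-amine, as
distinct from residue 1's side chain.

Per-residue topology strings use the four-letter alphabet
``I`` (intracellular), ``M`` (membrane), ``O`` (extracellular) and
``U`` (unknown / no data).  Richer location vocabularies (e.g. TOPDB's)
collapse onto these four, anything extra-cytosolic mapping to ``O``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .masses import CAMTHIOPROPANOYL_MASS, DEFAULT_LABEL_MASSES, THIOACYL_MASS

TOPOLOGY_ALPHABET = frozenset("IMOU")

# Modification contexts: where a primary-amine label can sit.
PROTEIN_NTERM = "protein_nterm"
PEPTIDE_NTERM = "peptide_nterm"
LYSINE_SIDECHAIN = "lysine_sidechain"
CONTEXTS = frozenset({PROTEIN_NTERM, PEPTIDE_NTERM, LYSINE_SIDECHAIN})


class ConfigError(ValueError):
    """A pipeline or simulation configuration value is invalid."""


@dataclass
class ProteinEntry:
    """A proteome record: sequence plus optional per-residue topology."""

    accession: str
    sequence: str
    topology: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        if self.topology is not None:
            self._check_topology(self.topology)

    def _check_topology(self, topology: str) -> None:
        if len(topology) != len(self.sequence):
            raise ValueError(
                f"topology length {len(topology)} does not match sequence "
                f"length {len(self.sequence)} for {self.accession}"
            )
        bad = set(topology) - TOPOLOGY_ALPHABET
        if bad:
            raise ValueError(
                f"topology for {self.accession} contains letters outside "
                f"{{I,M,O,U}}: {sorted(bad)}"
            )

    def with_topology(self, topology: str) -> "ProteinEntry":
        self._check_topology(topology)
        return replace(self, topology=topology)

    @property
    def is_transmembrane(self) -> bool:
        """True when the annotation contains at least one membrane residue."""
        return self.topology is not None and "M" in self.topology

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModificationDef:
    """A named mass shift with its allowed residue contexts."""

    name: str
    delta_mass: float
    contexts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.contexts:
            raise ValueError(f"modification {self.name!r} has no contexts")
        bad = self.contexts - CONTEXTS
        if bad:
            raise ValueError(f"unknown contexts for {self.name!r}: {sorted(bad)}")
        if self.delta_mass <= 0:
            raise ValueError(f"label modification {self.name!r} must have delta_mass > 0")


#: The two covalent label remnants on extracellular primary amines.
THIOACYL = ModificationDef("Thioacyl", THIOACYL_MASS, CONTEXTS)
CAMTHIOPROPANOYL = ModificationDef("CAMthiopropanoyl", CAMTHIOPROPANOYL_MASS, CONTEXTS)
LABEL_MODS: tuple[ModificationDef, ...] = (THIOACYL, CAMTHIOPROPANOYL)


@dataclass(frozen=True)
class ExperimentCondition:
    """One experimental series member: pre-digestion enzyme x duration.

    ``duration_label`` is an opaque string ("15min", "NPT", ...); duration
    labels are never interpreted arithmetically.  ``NPT``/``NPC`` mark the
    non-pre-digested controls of the trypsin/chymotrypsin series.
    ``labelled=False`` marks the unlabelled control membrane preparation.
    """

    enzyme: str
    duration_label: str
    labelled: bool = True

    _NO_PREDIGEST = frozenset({"NPT", "NPC"})

    def __post_init__(self) -> None:
        if self.enzyme not in {"trypsin", "chymotrypsin", "none"}:
            raise ValueError(f"unknown pre-digestion enzyme {self.enzyme!r}")
        if self.enzyme == "none" and self.duration_label in self._NO_PREDIGEST:
            raise ValueError(
                "NPT/NPC are series controls and must carry their series enzyme"
            )

    @property
    def predigested(self) -> bool:
        """True when the cell surface was actually pre-digested."""
        return self.enzyme != "none" and self.duration_label not in self._NO_PREDIGEST

    @property
    def key(self) -> str:
        suffix = "" if self.labelled else ":unlabelled"
        return f"{self.enzyme}:{self.duration_label}{suffix}"


@dataclass(frozen=True)
class PeptideObservation:
    """One search-engine result row for a (possibly modified) peptide.

    ``mods`` holds ``(position, delta_mass)`` pairs with 1-based peptide
    positions; position 0 is the peptide N-terminal amine.  ``score`` is a
    LogProb-like confidence score.
    """

    peptide: str
    mods: tuple[tuple[int, float], ...]
    score: float
    sample_id: str
    condition: ExperimentCondition
    obs_id: int = -1

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("observation peptide must be non-empty")
        for pos, _delta in self.mods:
            if not 0 <= pos <= len(self.peptide):
                raise ValueError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.peptide)}"
                )

    def label_mods(
        self, label_masses: tuple[float, ...], tolerance: float
    ) -> tuple[tuple[int, float], ...]:
        """The subset of mods within ``tolerance`` of a label mass."""
        return tuple(
            (pos, delta)
            for pos, delta in self.mods
            if any(abs(delta - m) <= tolerance for m in label_masses)
        )


@dataclass
class PipelineConfig:
    """Operative thresholds of the site-calling pipeline.

    ``min_logprob`` is the search-engine confidence cut-off (the study design
    couples it to an FDR <= 1%; the FDR itself is not recomputed here).
    ``min_support`` is the "identified at least three times in the given
    treatment" rule.  ``support_unit`` selects whether support counts
    observation rows (PSM-level, the default) or distinct peptide sequences.
    """

    min_logprob: float = 2.0
    mass_tolerance: float = 0.01
    min_support: int = 3
    label_masses: tuple[float, ...] = DEFAULT_LABEL_MASSES
    control_min_support: int = 3
    block_before_proline: bool = True
    support_unit: str = "observations"
    initiator_met_as_protein_nterm: bool = True
    min_peptide_search_len: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if self.control_min_support < 1:
            raise ConfigError("control_min_support must be >= 1")
        if self.mass_tolerance <= 0:
            raise ConfigError("mass_tolerance must be > 0")
        if not self.label_masses:
            raise ConfigError("label_masses must be non-empty")
        if self.support_unit not in {"observations", "distinct_peptides"}:
            raise ConfigError(
                "support_unit must be 'observations' or 'distinct_peptides', "
                f"got {self.support_unit!r}"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown pipeline config keys: {sorted(bad)}")
        if "label_masses" in data:
            data = {**data, "label_masses": tuple(data["label_masses"])}
        return cls(**data)
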