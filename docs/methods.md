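# Methods

## The measurement being modelled

Intact cells are (optionally) pre-digested mildly with a serine protease —
trypsin (cleaves C-terminal of K and R) or chymotrypsin (C-terminal of F, Y,
W, M, L) — then surface primary amines are biotinylated with a
membrane-impermeable reagent. After lysis, membrane preparation and complete
tryptic digestion, labelled peptides are enriched on neutravidin, eluted
reductively and alkylated. Each labelled amine is observed as a +87.9983 Da
(thioacyl, C3H4OS) or +145.0198 Da (CAMthiopropanoyl, C5H7NO2S = thioacyl +
carbamidomethyl) mass shift on a lysine side chain, a protein N-terminus or
a peptide N-terminus. Because the label is applied while the membrane is
intact, a labelled residue is evidence of extracellular location; because
trypsin cannot cleave after a labelled lysine, labelling also forces missed
cleavages in the membrane-prep digest.

Coordinates are 1-based inclusive; modification position 0 denotes the
peptide N-terminal alpha-amine. Topology strings use
`I` (intracellular) / `M` (membrane) / `O` (extracellular) / `U` (no data);
richer annotation vocabularies collapse onto these four, with anything
extra-cytosolic mapping to `O`.

## Pipeline rules

* **Score filter.** Observations with a LogProb-like score below
  `min_logprob` (default 2, inclusive boundary) are dropped. The false
  discovery rate that this threshold implies in the original search-engine
  context is not recomputed — no decoy information is available at this
  stage, and the threshold is the operative rule.
* **Label filter.** An observation must carry at least one modification
  within `mass_tolerance` (default 0.01 Da, which absorbs the two printed
  precisions of the label masses) of a label mass. Deamidation (+0.984 Da,
  the O − N − H shift of N→D conversion) therefore never counts as label
  evidence; deamidation-only rows are removed.
* **Mapping.** Exact substring search of each peptide against the proteome.
  Exhaustive short-peptide lookup is the intent of permissive BLAST
  parameterizations in comparable workflows; exact matching is deterministic
  and directly checkable against an all-offsets scan. Multi-locus peptides
  contribute evidence to every matched protein but are flagged ambiguous,
  and sites supported *only* by ambiguous evidence are reported separately.
* **Context rules.** A position-0 mod at a match starting the protein is a
  protein N-terminus; a match starting at position 2 of a Met-initiated
  protein is treated as the mature N-terminus (initiator-Met excision,
  configurable via `initiator_met_as_protein_nterm`); any other position-0
  mod is a peptide N-terminus. Internal label mods are valid only on K;
  anything else becomes an explicit invalid-evidence record.
* **Support rule.** Sites are keyed by (accession, position); a site is
  *called* in a condition when supported by at least `min_support`
  (default 3) identifications there. Support counts observation rows
  (PSM-level) by default; `support_unit="distinct_peptides"` switches to
  distinct peptide sequences — the wording "identified at least three
  times" is ambiguous between the two readings. Support is counted per
  condition (enzyme × duration label); merged digest sets are unions of
  per-condition called sets, never re-pooled evidence. Duration labels are
  opaque strings and are never interpreted arithmetically.
* **Control subtraction.** Sites with `control_min_support` (default 3)
  supporting observations in the unlabelled control preparation are vetoed.
  Real unlabelled controls are nearly empty, so this is usually an identity.
* **Validation.** Called sites are classified against an independent
  reference annotation: `O` → Extracellular, `I`/`M` → Intracellular ("not
  extracellular"; membrane-residue calls are additionally counted in a
  diagnostic field so membrane-adjacent placements stay visible), `U` or
  missing → Unknown. Accuracy = Extracellular / (Extracellular +
  Intracellular) over the merged unique site set, reported as N/A when no
  known-class site exists. Constraint export writes one
  `accession<TAB>position<TAB>O` line per called site; this evidence type
  never justifies I or M constraints.

## The simulator

The generator's defaults are the study conditions: six labelled conditions
(trypsin NPT/15min/25min at surface cut probabilities 0/0.3/0.5;
chymotrypsin NPC/10min/20min at 0/0.3/0.5) plus an unlabelled control.
Proteins alternate I/M/O segments: 56/75 are single-pass (type I or II,
extracellular domain 80–250 residues), the rest multi-pass with 2–7
membrane blocks; membrane segments use a hydrophobic, K/R-free composition,
everything else approximate human proteome frequencies, and every sequence
starts with Met.

Per labelled condition, per protein:

1. surface cuts are drawn independently (Bernoulli) at eligible cleavage
   sites whose residue is `O` — the intact membrane shields `I`/`M` sites;
2. accessible amines are enumerated: the protein N-terminus when its residue
   is `O`, every surface-fragment N-terminus whose residue is `O`
   (regardless of amino-acid identity — a serine N-terminus is reactive),
   and extracellular lysines; each is labelled with probability
   `label_efficiency` (default 0.8). Each intracellular amine is wrongly
   labelled with probability `contamination_rate` (default 0.01),
   representing the residual membrane damage that grows with over-digestion;
3. the membrane-prep tryptic digest is computed with labelled lysines
   blocked and surface cuts already in place; label-carrying fragments are
   emitted as observation rows;
4. each observed label is the alkylated +145.0198 form with probability
   `alkylation_rate` (default 0.93) and the +87.9983 form otherwise; each
   asparagine deamidates per observation with probability
   `deamidation_rate` (0.05); each labelled observation drags in a
   piggyback cysteine peptide with probability `piggyback_rate` (0.15);
5. genuine observations draw scores from Normal(7, 1) truncated at 0,
   contaminant and piggyback observations from Normal(1, 1) truncated at 0,
   so the LogProb ≥ 2 filter separates them imperfectly but meaningfully.

**Support model.** Each protein draws an abundance 1 + Poisson(mean − 1)
(`support_mean`, default 5) once at proteome generation; every emitted
fragment of that protein is observed that many times in every condition.
PSM counts in real data are driven primarily by protein abundance, and
making support a protein property shared across conditions is what makes
the design's own contrasts exact: a site present in both the control and a
pre-digested condition is then called in both or neither, so sites unique
to pre-digested samples are genuinely digestion products rather than
counting noise.

**Detectability.** Labelled fragments shorter than `min_peptide_length`
(default 7, a standard search-engine minimum) or occurring more than once
in the proteome (non-proteotypic) are not emitted; ground truth records
them as unemitted with the reason. This gives the simulation a "lost
sites" mechanism (surface cuts can shorten a site's peptide below
detectability) and guarantees unambiguous mapping for emitted peptides.

**Accessibility.** By default every extracellular lysine is chemically
accessible. An optional burial model (`k_buried_fraction` > 0) makes a
fraction of extracellular lysines require a surface cut within
`uncover_window` residues before they can react ("uncovered lysine" sites).
It is off by default: with burial on, a newly labelled buried lysine blocks
a tryptic site and can merge a neighbouring short peptide into a detectable
one, so a pre-existing site can surface only after digestion — a real
phenomenon, but one that blurs the clean cause accounting the recovery
tests rely on.

**Ground truth.** Every labelled amine is recorded per condition with its
context, generation cause (pre-existing amine / new peptide N-terminus /
uncovered lysine / contaminant), emission outcome and per-observation
scores. The *detectable* set — emitted sites with ≥ `min_support`
observations at or above the score threshold — is recomputed directly from
these records, independently of the mapping/aggregation code path, and is
the oracle that the pipeline's called sets are required to equal exactly in
the clean regime (no contamination, complete labelling).

## What the simulator does not emulate

Retention time, intensities, and spectrum-level effects; glycosylation and
glycosite occupancy; inexact or isobaric peptide matches (mapping is exact
by construction); shared peptides between homologous proteins beyond chance
repeats; condition-to-condition abundance variation (support is fixed per
protein); kinetic digestion models (cut probability stands in for
enzyme-concentration × time, to which it maps monotonically). Passing the
recovery tests therefore certifies the pipeline's bookkeeping — mapping
arithmetic, context rules, thresholds, set algebra — not robustness to
search-engine idiosyncrasies of real data.

## Numerical and design choices

* Monoisotopic atomic masses are embedded constants (IUPAC values, ≥ 6
  decimals), so mass arithmetic is dependency-free; tests cross-check
  against an independent calculator.
* The Keil rule (no cleavage before proline) defaults to on for both
  enzymes and both digestion regimes, and is configurable
  (`block_before_proline`); chymotrypsin uses only its five
  high-specificity residues.
* Membrane-prep digestion emits the 0-missed-cleavage partition; labelled
  lysines are blocked unconditionally, which is the assay's built-in
  missed-cleavage mechanism. `digest_full` supports an explicit
  missed-cleavage cap for enumerating search-space peptide forms.
* Two topology inputs are distinguished: a full prediction-style annotation
  (used to decide which proteins count as TMPs, and as simulation truth)
  and a partial reference annotation (a TOPDB-like database extract; a
  32/75 fraction of simulated proteins carries no reference data, feeding
  the Unknown validation class).
* Tie-breaks and degenerate inputs: empty peptide tables and empty called
  sets are warnings, not failures; accuracy over zero known-class sites is
  N/A; duplicate FASTA accessions and sequence/topology length mismatches
  are hard errors naming the record.
* Problem sizes: tests and the acceptance script use 200-protein proteomes
  (≈ 35,000 observation rows across 7 conditions), 1,000 random sequences
  for the digestion oracle and 10,000 trials for the Bernoulli cut
  frequency — large enough for the statistics they check while keeping the
  default run in seconds.

## Known limitations

* `label_efficiency`, per-condition cut probabilities, the piggyback rate
  and the score distributions are free parameters; the experiment they
  emulate does not quantify them, so absolute simulated counts (e.g. the
  digest-only site fraction) are not calibrated to any particular dataset.
* With stochastic labelling (efficiency < 1) a pre-existing site can be
  labelled in one condition and not another, so a small number of
  digest-only sites with cause "pre-existing amine" appear in the noisy
  regime; the clean regime is free of them by construction.
* Ambiguity handling is all-or-nothing (exact multi-locus matches); one- or
  two-mismatch mapping is out of scope.
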