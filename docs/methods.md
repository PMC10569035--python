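# Methods

## Problem and scope

Metabolism and degradation literature describes transformation products
(TPs) in prose. Text-mining engines can recognize the chemical names in
such excerpts and link them to database identifiers, but a recognized
name is not a reaction: only a fraction of the names in a metabolism
excerpt actually denote a TP or parent of the compound the excerpt is
about. `tpcurate` is the headless machinery around that observation. It
parses markup-annotated excerpts into a candidate table, applies
curator verdicts to produce directed predecessor→successor reactions,
validates and deduplicates them against an existing transformations
library, exports the merged library as a TP suspect list, and uses that
list to label TPs among identified compounds, link parent–TP pairs and
compare their octanol–water partitioning (XlogP).

Name recognition itself is out of scope: the package consumes markup
(character-offset spans with linked CIDs) produced upstream, and never
produces it. Mass-spectral screening is likewise upstream/downstream:
matching here is identifier-based only.

## Annotation parsing

The supported input dialect mirrors the public PUG-View annotation
shape: a list of annotations, each carrying a source compound CID and
one or more excerpts as `StringWithMarkup` items
(`docs/annotation_schema.json`). Offsets are 0-based, length-counted,
and measured in Unicode code points. Each (annotation, excerpt) pair
becomes one record; the record's source identifier is the annotation's
`SourceID` suffixed with the excerpt ordinal (`hsdb/702/0`,
`hsdb/702/1`, ...). This suffix exists because the deterministic
candidate key is a hash of (input CID, source id, span start, matched
CID); without per-excerpt source ids, two spans at the same offset in
different excerpts of one annotation would collide. Overlapping and
nested spans are legal and each becomes its own candidate row; excerpts
with zero spans are retained because manually added entries cite them
as evidence. Unresolvable names (no CID, or a CID absent from the local
structure index) are flagged, never dropped and never encoded as empty
strings.

## Structure conventions

All structure identity flows through RDKit canonical SMILES and
InChIKeys computed on the canonical form. Descriptors (Hill formula,
monoisotopic mass) are computed on the *re-parsed* canonical SMILES so
that results are bitwise independent of input atom ordering — this is
what makes repeated runs byte-identical.

Three match levels are defined:

* `exact` — full 27-character InChIKey equality;
* `skeleton` — equality of the first 14-character block, which hashes
  connectivity without stereochemistry or protonation, so enantiomers
  and diastereomers of one skeleton compare equal;
* `desalted` — exact equality after salt stripping on both sides.

Salt stripping keeps the largest organic component (most heavy atoms
among carbon-containing components; ties broken by larger monoisotopic
mass, then lexicographically smallest canonical SMILES) and neutralizes
it, so sodium acetate desalts to acetic acid rather than to the
acetate anion; without neutralization a carboxylate salt would never
match its free acid even at the desalted level. Single-component inputs
pass through unchanged; a multi-component input with no organic part is
an error rather than a silent guess.

XlogP values are consumed from input tables (they are database-computed
values). A locally computed Crippen logP exists as `estimate_logp`, an
explicitly labeled fallback that no pipeline stage uses implicitly.

## Curation semantics

Curation is a declarative artifact: a decisions CSV mapping candidate
keys to verdicts (`product`, `parent`, `reject`) plus optional
biosystem/enzyme/transformation-type metadata copied verbatim onto the
reaction. `product` orients input→matched, `parent` matched→input; the
two verdicts produce exactly mirrored records. Every candidate ends up
in exactly one of {accepted, rejected, undecided}, so counts always
conserve. Undecided candidates block finalization unless explicitly
allowed — silent drops are the failure mode this guards against. If a
candidate receives several decisions, the last one in file order wins
and a warning is logged; this is a convention of this implementation,
not a rule inherited from any upstream tool.

Compounds the text mining missed enter through missing-entry records
(name + SMILES + direction). The structure is canonicalized before any
record is created and carries no CID, since it is by construction a
compound the identifier mapping did not know.

Validation reports issues from a closed vocabulary: `identical_sides`,
`stereo_only_difference` (skeleton-equal but not exact-equal sides),
`salt_component` (either side multi-component), `unresolved_cid`,
`missing_metadata` (none of biosystem/enzyme/type present). Validation
never mutates — whether to fix or drop a flagged reaction is itself a
curation decision.

## Library, deduplication, merging

A transformations library is a multiset of reactions keyed by structure
pair; the CID pair is used as the uniqueness key when both sides carry
one, with the InChIKey pair as fallback. Duplicate pairs are
deliberately allowed (the same transformation in different biosystems).

Dedup classifies each incoming reaction as `exact_duplicate` (structure
pair matched at exact level and the normalized biosystem/enzyme/type
triple matched), `metadata_variant` (pair matched, metadata differs) or
`novel`. Metadata normalization is case- and whitespace-folding only —
no synonym dictionary, so "liver" ≠ "hepatic" by design. Differences
confined to the evidence text count as exact duplicates: evidence is
provenance, not reaction identity. Merging adds novel entries (and
optionally variants) and never adds exact duplicates, which makes it
idempotent and order-insensitive on the unique-pair set.

Suspect-list export emits one row per distinct successor InChIKey with
all predecessor InChIKeys attached, sorted by InChIKey for byte-stable
output. The monoisotopic mass is recomputed from the structure rather
than trusted from the source table because downstream suspect screening
depends on mass accuracy.

## Screening stage

Labeling marks an identified compound as a TP iff its InChIKey matches
a suspect entry at the chosen level (`exact` or `skeleton`); nothing is
dropped. Linking pairs each labeled TP with every identified compound
matching one of its predecessor keys; a TP with k identified parents
yields k pairs, and one with none is an orphan — a real observation
(parent degraded, misidentified, or the "TP" entering the environment
directly). Self-pairs are excluded and logged.

The polarity comparison is a paired one-sided Wilcoxon signed-rank test
of the alternative "TP XlogP < parent XlogP" on linked pairs with both
values present (missing-value pairs are excluded and counted). Zero
differences are dropped; the exact null distribution is used for
n ≤ 25 usable pairs and the normal approximation with continuity
correction above that. The computation is delegated to
`scipy.stats.wilcoxon` with exactly these settings; the test suite
checks it against an independent enumeration of all 2^n sign
assignments. The two-sided p is reported alongside the directional one.
Density curves for plotting use a Gaussian kernel with Silverman
bandwidth. Zero usable pairs (including all-zero differences) is an
error, never a NaN summary.

## Synthetic fixtures

The fixture generators make every stage testable offline by planting
ground truth and returning a ledger that fully determines expected
outputs; tests compare pipeline results to the ledger, not to
hand-maintained constants.

The embedded catalog holds ~490 real structures: homologous series
(alkan-1-ols, alkanals, alkanoic and dioic acids, 1,2-diols,
ω-hydroxy acids, methyl esters, acylglycines, amines, nitriles,
chloroalkanes, methyl ethers, thiols, methyl ketones, alkylbenzenes
and their benzylic alcohols/acids up to C30), amino acids with D/L
pairs, N-acetyl amino acids, triazine herbicides with their hydroxy-
and desalkyl-TPs, a few pharmaceuticals with known TPs, and salt forms.
Reaction templates connect them with plausible transformation types
(oxidation, hydroxylation, hydrolysis, β-oxidation, conjugation,
dealkylation, dechlorination, acetylation, phosphorylation). Duplicate
structures arising from series crossings are unified by InChIKey at
catalog build time. The chemistry is simplistic on purpose: its role is
to exercise canonicalization, matching and mass code paths with valid
molecules, not to model metabolism.

Defaults mirror the observed study conditions this workflow operates
under: the annotation fixture plants 50 input compounds × 3 excerpts
with 400 spans of which 20% are true reactions (the rate observed when
curating real text-mined names), ~5% unresolvable names, the rest
distractors. The library fixture plants a 25-reaction curated set with
(novel, exact, variant) = (20, 3, 2) against a 200-entry library. The
screening fixture plants 436 identified compounds with 72 TPs, 36
linkable parent–TP pairs and 36 orphans; parent XlogP is drawn from
N(2.5, 1.2) — a typical spread for environmentally relevant organics —
and TP XlogP is the parent's minus a shift of 1.0 plus N(0, 0.5) noise,
so the planted polarity increase is detectable but noisy. All
randomness in a generator call flows from the single seed argument
through one RNG instance; equal seeds give byte-identical artifacts.

What the fixtures do *not* emulate: real metabolism prose (excerpts are
templated sentences), recognition errors inside spans (spans always
cover exactly one catalog name), chromatographic ambiguity, and the
skew of real libraries toward a few well-studied compounds. Passing
tests therefore demonstrate the correctness of the bookkeeping,
matching and statistics — not the quality of any particular curated
corpus.

## Numerical and design choices

* Candidate keys: SHA-1 over (input CID, source id, span start,
  matched CID), truncated to 16 hex characters; collisions raise.
* CSV is the format for every curation artifact (UTF-8, fixed column
  order, `csv`-module quoting, so embedded commas/quotes/newlines
  round-trip); JSON for the annotation input and summary reports.
* Exact-vs-approx switch for the signed-rank test at n = 25.
* The merged library never re-canonicalizes trusted entries; reading a
  library from CSV canonicalizes, so any non-canonical input SMILES is
  normalized at the boundary.
* Fixture problem sizes used by the test suite and acceptance script
  (20-seed sweeps, 1000/500-replicate calibration and power runs at
  n = 36) were chosen to make Monte-Carlo error small relative to the
  margins being checked while keeping the whole suite in the tens of
  seconds.

## Known limitations

* Reaction direction comes only from curator verdicts; no grammar-based
  direction inference, and no inference of transformation type from
  structure pairs.
* Multi-step chains in one excerpt are represented as independent
  pairwise reactions; there is no chain object.
* Metadata comparison has no synonym resolution; libraries curated with
  heterogeneous vocabularies will over-report metadata variants.
* The desalting neutralization uses a simple uncharger; exotic
  organometallics or zwitterion conventions may not desalt the way a
  specialist would choose.
* Skeleton-level matching collapses all stereoisomers; at that level a
  suspect hit cannot distinguish epimers.
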