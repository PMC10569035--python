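# tpcurate

A headless, scriptable toolkit for curating **transformation products
(TPs)** from text-mined chemical annotations. It turns markup-annotated
metabolism excerpts into validated, deduplicated predecessor→successor
reaction libraries, exports them as TP suspect lists, and uses those
lists to label TPs among identified compounds, link parent–TP pairs and
test whether TPs are more polar than their parents.

It is written for environmental chemists and cheminformaticians who
work with text-mined metabolism data and non-target screening results
and want the curation step to be reproducible: every curator decision
is a row in a CSV, every pipeline stage is a pure function, and two
runs on the same inputs produce byte-identical artifacts.

## What it computes

* **Extraction** — parse an annotation JSON document (per-compound text
  excerpts with character-offset markup spans linked to CIDs; schema in
  `docs/annotation_schema.json`) into a flat candidate table: one row
  per recognized chemical name, with structures resolved from a local
  CID→structure index.
* **Curation** — apply a declarative decisions CSV. Verdict `product`
  yields *input → matched*, `parent` yields *matched → input*, `reject`
  goes to the ledger. Compounds the text mining missed are added from a
  missing-entries CSV (name + SMILES + direction). Each reaction gets a
  canonical reaction SMILES `predecessor>>successor`.
* **Validation** — flag salts, stereo-only differences, degenerate and
  under-annotated reactions from a closed issue vocabulary.
* **Dedup & merge** — classify curated reactions against an existing
  transformations library as *novel* / *exact duplicate* / *metadata
  variant* (structure pair matched but biosystem/enzyme/type differ)
  and merge under an explicit policy. Identity is the (predecessor,
  successor) pair: CID pair when available, InChIKey pair otherwise.
* **Suspect list** — one entry per distinct successor structure with
  all known predecessor InChIKeys, mass recomputed from structure.
* **Screening linkage** — label identified compounds against the
  suspect list (exact or stereo-agnostic InChIKey-skeleton matching),
  link parent–TP pairs, and run a one-sided paired Wilcoxon signed-rank
  test of "TP XlogP < parent XlogP" (exact null for n ≤ 25, normal
  approximation with continuity correction above).

Deterministic fixture generators (`tpcurate.fixtures`) produce all
inputs with planted ground truth, so the complete pipeline runs and is
tested offline. See `docs/methods.md` for conventions and assumptions.

## Worked example

```sh
tpcurate make-fixtures --out-dir demo --seed 7
cd demo
tpcurate extract  --input annotation.json --index structure_index.csv --out candidates.csv
tpcurate curate   --candidates candidates.csv --decisions decisions.csv --out reactions.csv
tpcurate dedup    --reactions reactions.csv --library library.csv --out dedup.json
tpcurate merge    --reactions reactions.csv --library library.csv --out merged.csv
tpcurate suspects --library merged.csv --out suspects.csv
tpcurate label    --identified identified.csv --suspects suspects.csv --out labels.csv
tpcurate pairs    --identified identified.csv --suspects suspects.csv \
                  --out-pairs pairs.csv --out-orphans orphans.csv
tpcurate compare  --identified identified.csv --suspects suspects.csv --out comparison.json
```

which prints, step by step:

```
extracted 400 candidates from 150 records
curated 80 reactions (0 undecided)
{"novel": 41, "exact_duplicate": 1, "metadata_variant": 38}
merged: 200 + 41 new entries -> 241
exported 168 suspect entries
labeled 18 TPs among 100 compounds
linked 12 pairs, 6 orphan TPs
n_used=12 median parent XlogP=2.28 median TP XlogP=1.13 one-sided p=0.0002441
```

Reading: 400 text-mined names over 150 excerpts yielded 80 true
reactions under the shipped decision file (the planted 20% true rate);
41 of them were new to the 200-entry library, 38 were already listed
with different metadata. The merged library exports 168 distinct TP
structures as suspects; among 100 identified compounds 18 are TPs, 12
of which have an identified parent. The linked TPs are markedly more
polar than their parents (median XlogP 1.13 vs 2.28), and the paired
one-sided Wilcoxon test rejects at p ≈ 2.4 × 10⁻⁴.

Every command is a thin wrapper over library functions
(`tpcurate.annotations`, `.curation`, `.library`, `.screening`), so the
same pipeline can be driven from Python.

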