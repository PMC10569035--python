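"""Deterministic fixture generators with planted ground truth.

Every pipeline stage is testable offline against synthetic inputs whose
expected outputs are known exactly: the generators return, alongside the
artifacts, a :class:`FixtureLedger` recording what was planted (true
reactions, distractor and unresolved spans, dedup classes, linkable
pairs and orphans, the XlogP shift), so tests compare pipeline output to
the ledger rather than to hand-frozen numbers.

The chemistry is real: a small embedded catalog of simple homologous
series (alkanols, aldehydes, acids, amines, alkylbenzenes, ...), amino
acids, triazine herbicides and a few well-known pharmaceuticals, wired
into plausible transformation templates (oxidation, hydroxylation,
hydrolysis, conjugation, dealkylation, ...). This keeps the
canonicalization, InChIKey and mass code paths exercised with valid
structures — random SMILES strings are mostly invalid.

All randomness in one generator call flows from a single seed through
one RNG instance; the same seed reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen

from .annotations import candidate_id_for
from .chem import StructureIndex, StructureRef, canonicalize
from .curation import CompoundRef, DecisionRecord, ReactionRecord
from .errors import FixtureParameterError
from .library import SuspectEntry, TransformationsLibrary, export_suspect_list
from .screening import IdentifiedCompound

# ---------------------------------------------------------------------------
# Embedded structure catalog
# ---------------------------------------------------------------------------

_STEMS = [
    "meth", "eth", "prop", "but", "pent", "hex", "hept", "oct", "non", "dec",
    "undec", "dodec", "tridec", "tetradec", "pentadec", "hexadec", "heptadec",
    "octadec", "nonadec", "icos", "henicos", "docos", "tricos", "tetracos",
    "pentacos", "hexacos", "heptacos", "octacos", "nonacos", "triacont",
]

_N_MAX = 30

_BIOSYSTEMS = ["human", "rat", "soil", "activated sludge", "water/sediment"]
_ENZYMES = ["CYP3A4", "CYP2D6", "alcohol dehydrogenase", "esterase", None, None]

_FIRST_CID = 10001


@dataclass(frozen=True)
class CatalogMol:
    key: str
    name: str
    cid: int
    ref: StructureRef


@dataclass(frozen=True)
class ReactionTemplate:
    parent_key: str
    product_key: str
    transformation_type: str


def _stem(n: int) -> str:
    return _STEMS[n - 1]


def _series() -> list[tuple[str, str, str]]:
    """(key, name, smiles) for every catalog molecule, pre-dedup."""
    out: list[tuple[str, str, str]] = []

    def add(key, name, smiles):
        out.append((key, name, smiles))

    for n in range(1, _N_MAX + 1):
        add(f"alkanol:{n}", f"{_stem(n)}an-1-ol", "C" * n + "O")
    for n in range(2, _N_MAX + 1):
        add(f"aldehyde:{n}", f"{_stem(n)}anal", "C" * (n - 1) + "C=O")
        add(f"acid:{n}", f"{_stem(n)}anoic acid", "C" * (n - 1) + "C(=O)O")
        add(f"ester:{n}", f"methyl {_stem(n)}anoate", "C" * (n - 1) + "C(=O)OC")
        add(f"glyconj:{n}", f"{_stem(n)}anoylglycine", "C" * (n - 1) + "C(=O)NCC(=O)O")
        add(f"nitrile:{n}", f"{_stem(n)}anenitrile", "C" * (n - 1) + "C#N")
        add(f"diacid:{n}", f"{_stem(n)}anedioic acid", "OC(=O)" + "C" * (n - 2) + "C(=O)O")
        if n == 2:
            add("diol:2", "ethane-1,2-diol", "OCCO")
        else:
            add(f"diol:{n}", f"{_stem(n)}ane-1,2-diol", "OCC(O)" + "C" * (n - 2))
    for n in range(3, _N_MAX + 1):
        add(f"hydroxyacid:{n}", f"{n}-hydroxy{_stem(n)}anoic acid", "O" + "C" * (n - 1) + "C(=O)O")
        add(f"ketone:{n}", f"{_stem(n)}an-2-one", "C" * (n - 2) + "C(C)=O")
    for n in range(1, _N_MAX + 1):
        add(f"amine:{n}", f"{_stem(n)}an-1-amine", "C" * n + "N")
        add(f"chloro:{n}", f"1-chloro{_stem(n)}ane", "C" * n + "Cl")
        add(f"thiol:{n}", f"{_stem(n)}ane-1-thiol", "C" * n + "S")
        add(f"ether:{n}", f"1-methoxy{_stem(n)}ane", "C" * n + "OC")
    add("arene:0", "benzene", "c1ccccc1")
    for n in range(1, 16):
        add(f"arene:{n}", f"{_stem(n)}ylbenzene", "c1ccccc1" + "C" * n)
        add(
            f"phenylol:{n}",
            "phenylmethanol" if n == 1 else f"phenyl{_stem(n)}an-1-ol",
            "OC" + "C" * (n - 1) + "c1ccccc1",
        )
        add(
            f"phenylacid:{n}",
            "benzoic acid" if n == 1 else f"phenyl{_stem(n)}anoic acid",
            "OC(=O)" + "C" * (n - 1) + "c1ccccc1",
        )

    amino = [
        ("gly", "glycine", "NCC(=O)O"),
        ("l-ala", "L-alanine", "N[C@@H](C)C(=O)O"),
        ("d-ala", "D-alanine", "N[C@H](C)C(=O)O"),
        ("l-ser", "L-serine", "N[C@@H](CO)C(=O)O"),
        ("d-ser", "D-serine", "N[C@H](CO)C(=O)O"),
        ("l-val", "L-valine", "N[C@@H](C(C)C)C(=O)O"),
        ("d-val", "D-valine", "N[C@H](C(C)C)C(=O)O"),
        ("l-leu", "L-leucine", "N[C@@H](CC(C)C)C(=O)O"),
        ("l-phe", "L-phenylalanine", "N[C@@H](Cc1ccccc1)C(=O)O"),
        ("d-phe", "D-phenylalanine", "N[C@H](Cc1ccccc1)C(=O)O"),
        ("l-asp", "L-aspartic acid", "N[C@@H](CC(=O)O)C(=O)O"),
        ("l-glu", "L-glutamic acid", "N[C@@H](CCC(=O)O)C(=O)O"),
        ("l-met", "L-methionine", "N[C@@H](CCSC)C(=O)O"),
    ]
    for slug, name, smi in amino:
        add(f"aa:{slug}", name, smi)
    nacetyl = [
        ("gly", "N-acetylglycine", "CC(=O)NCC(=O)O"),
        ("l-ala", "N-acetyl-L-alanine", "CC(=O)N[C@@H](C)C(=O)O"),
        ("l-ser", "N-acetyl-L-serine", "CC(=O)N[C@@H](CO)C(=O)O"),
        ("l-val", "N-acetyl-L-valine", "CC(=O)N[C@@H](C(C)C)C(=O)O"),
        ("l-leu", "N-acetyl-L-leucine", "CC(=O)N[C@@H](CC(C)C)C(=O)O"),
        ("l-phe", "N-acetyl-L-phenylalanine", "CC(=O)N[C@@H](Cc1ccccc1)C(=O)O"),
        ("l-met", "N-acetyl-L-methionine", "CC(=O)N[C@@H](CCSC)C(=O)O"),
    ]
    for slug, name, smi in nacetyl:
        add(f"nacetyl:{slug}", name, smi)

    named = [
        ("atrazine", "atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1"),
        ("desethylatrazine", "desethylatrazine", "CC(C)Nc1nc(Cl)nc(N)n1"),
        ("atrazine-2-hydroxy", "atrazine-2-hydroxy", "CCNc1nc(O)nc(NC(C)C)n1"),
        ("simazine", "simazine", "CCNc1nc(Cl)nc(NCC)n1"),
        ("propazine", "propazine", "CC(C)Nc1nc(Cl)nc(NC(C)C)n1"),
        ("terbuthylazine", "terbuthylazine", "CCNc1nc(Cl)nc(NC(C)(C)C)n1"),
        ("terbuthylazine-2-hydroxy", "terbuthylazine-2-hydroxy", "CCNc1nc(O)nc(NC(C)(C)C)n1"),
        ("terbutryn", "terbutryn", "CCNc1nc(SC)nc(NC(C)(C)C)n1"),
        ("acyclovir", "acyclovir", "Nc1nc2c(c(=O)[nH]1)ncn2COCCO"),
        ("acyclovir-mp", "acyclovir monophosphate", "Nc1nc2c(c(=O)[nH]1)ncn2COCCOP(=O)(O)O"),
        ("acyclovir-dp", "acyclovir diphosphate", "Nc1nc2c(c(=O)[nH]1)ncn2COCCOP(=O)(O)OP(=O)(O)O"),
        ("diclofenac", "diclofenac", "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"),
        ("aceclofenac", "aceclofenac", "OC(=O)COC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"),
        ("diclofenac-4oh", "4'-hydroxydiclofenac", "OC(=O)Cc1ccccc1Nc1c(Cl)cc(O)cc1Cl"),
        ("benzidine", "benzidine", "Nc1ccc(-c2ccc(N)cc2)cc1"),
        ("n-acetylbenzidine", "N-acetylbenzidine", "CC(=O)Nc1ccc(-c2ccc(N)cc2)cc1"),
        ("diacetylbenzidine", "N,N'-diacetylbenzidine", "CC(=O)Nc1ccc(-c2ccc(NC(C)=O)cc2)cc1"),
    ]
    for slug, name, smi in named:
        add(f"named:{slug}", name, smi)

    salts = [
        ("sodium-acetate", "sodium acetate", "CC(=O)[O-].[Na+]"),
        ("ethylamine-hcl", "ethylamine hydrochloride", "CCN.Cl"),
        ("sodium-benzoate", "sodium benzoate", "[Na+].[O-]C(=O)c1ccccc1"),
    ]
    for slug, name, smi in salts:
        add(f"salt:{slug}", name, smi)
    return out


def _templates() -> list[ReactionTemplate]:
    t: list[ReactionTemplate] = []

    def add(p, q, ttype):
        t.append(ReactionTemplate(p, q, ttype))

    for n in range(2, _N_MAX + 1):
        add(f"alkanol:{n}", f"aldehyde:{n}", "oxidation")
        add(f"aldehyde:{n}", f"acid:{n}", "oxidation")
        add(f"alkanol:{n}", f"diol:{n}", "hydroxylation")
        add(f"ester:{n}", f"acid:{n}", "hydrolysis")
        add(f"acid:{n}", f"glyconj:{n}", "glycine conjugation")
        add(f"nitrile:{n}", f"acid:{n}", "hydrolysis")
        add(f"amine:{n}", f"aldehyde:{n}", "oxidative deamination")
    for n in range(3, _N_MAX + 1):
        add(f"acid:{n}", f"hydroxyacid:{n}", "hydroxylation")
        add(f"hydroxyacid:{n}", f"diacid:{n}", "oxidation")
    for n in range(4, _N_MAX + 1):
        add(f"acid:{n}", f"acid:{n - 2}", "beta-oxidation")
    for n in range(1, _N_MAX + 1):
        add(f"chloro:{n}", f"alkanol:{n}", "hydrolytic dechlorination")
        add(f"ether:{n}", f"alkanol:{n}", "O-demethylation")
    for n in range(1, 16):
        add(f"arene:{n}", f"phenylol:{n}", "hydroxylation")
        add(f"phenylol:{n}", f"phenylacid:{n}", "oxidation")
    for slug in ("gly", "l-ala", "l-ser", "l-val", "l-leu", "l-phe", "l-met"):
        add(f"aa:{slug}", f"nacetyl:{slug}", "acetylation")
    specials = [
        ("named:atrazine", "named:desethylatrazine", "dealkylation"),
        ("named:atrazine", "named:atrazine-2-hydroxy", "hydrolysis"),
        ("named:terbuthylazine", "named:terbuthylazine-2-hydroxy", "hydrolysis"),
        ("named:terbutryn", "named:terbuthylazine-2-hydroxy", "hydrolysis"),
        ("named:acyclovir", "named:acyclovir-mp", "phosphorylation"),
        ("named:acyclovir-mp", "named:acyclovir-dp", "phosphorylation"),
        ("named:aceclofenac", "named:diclofenac", "hydrolysis"),
        ("named:diclofenac", "named:diclofenac-4oh", "hydroxylation"),
        ("named:benzidine", "named:n-acetylbenzidine", "acetylation"),
        ("named:n-acetylbenzidine", "named:diacetylbenzidine", "acetylation"),
    ]
    for p, q, ttype in specials:
        add(p, q, ttype)
    return t


class Catalog:
    """The embedded, deduplicated molecule catalog plus reaction templates."""

    def __init__(self):
        self.mols: list[CatalogMol] = []
        self.by_key: dict[str, CatalogMol] = {}
        self.by_cid: dict[int, CatalogMol] = {}
        by_ik: dict[str, CatalogMol] = {}
        cid = _FIRST_CID
        for key, name, smiles in _series():
            ref = canonicalize(smiles)
            existing = by_ik.get(ref.inchikey)
            if existing is not None:
                # duplicate structure under another key: alias, keep first
                self.by_key[key] = existing
                continue
            xlogp = round(float(Crippen.MolLogP(Chem.MolFromSmiles(ref.smiles))), 2)
            mol = CatalogMol(key=key, name=name, cid=cid, ref=ref.with_xlogp(xlogp))
            cid += 1
            self.mols.append(mol)
            self.by_key[key] = mol
            self.by_cid[mol.cid] = mol
            by_ik[ref.inchikey] = mol
        self.templates: list[ReactionTemplate] = [
            t
            for t in _templates()
            if self.by_key[t.parent_key].ref.inchikey != self.by_key[t.product_key].ref.inchikey
        ]
        # adjacency: input key -> [(template, input_role)]
        self.adjacency: dict[str, list[tuple[ReactionTemplate, str]]] = {}
        for t in self.templates:
            pk = self.by_key[t.parent_key].key
            qk = self.by_key[t.product_key].key
            self.adjacency.setdefault(pk, []).append((t, "product"))
            self.adjacency.setdefault(qk, []).append((t, "parent"))

    def compound_ref(self, key: str) -> CompoundRef:
        # reaction records carry no per-structure logP annotation; that
        # lives in the structure index only
        m = self.by_key[key]
        return CompoundRef(name=m.name, cid=m.cid, structure=m.ref.with_xlogp(None))

    def reaction(
        self,
        template: ReactionTemplate,
        biosystem: str | None = None,
        enzyme: str | None = None,
        evidence: str = "",
        source_name: str = "fixture",
        source_id: str = "",
    ) -> ReactionRecord:
        return ReactionRecord(
            predecessor=self.compound_ref(template.parent_key),
            successor=self.compound_ref(template.product_key),
            biosystem=biosystem,
            enzyme=enzyme,
            transformation_type=template.transformation_type,
            evidence_excerpt=evidence,
            source_name=source_name,
            source_id=source_id,
        )


@lru_cache(maxsize=1)
def catalog() -> Catalog:
    return Catalog()


def structure_index(cat: Catalog | None = None) -> StructureIndex:
    """A structure index covering the whole catalog (the local stand-in for
    a database identifier mapping)."""
    cat = cat or catalog()
    idx = StructureIndex()
    for m in cat.mols:
        idx.add(m.cid, m.name, m.ref)
    return idx


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedReaction:
    predecessor_inchikey: str
    successor_inchikey: str
    biosystem: str | None
    enzyme: str | None
    transformation_type: str | None

    @property
    def recovery_key(self) -> tuple[str, str, str]:
        return (
            self.predecessor_inchikey,
            self.successor_inchikey,
            (self.biosystem or "").strip().casefold(),
        )


@dataclass
class FixtureLedger:
    """What a generator planted; fully determines expected pipeline output."""

    seed: int
    planted_reactions: list[PlantedReaction] = field(default_factory=list)
    n_records: int = 0
    n_spans: int = 0
    n_true_spans: int = 0
    distractor_spans: int = 0
    unresolved_spans: int = 0
    planted_dedup_classes: dict[str, int] = field(default_factory=dict)
    planted_tp: int = 0
    planted_pairs: int = 0
    planted_orphans: int = 0
    xlogp_shift: float = 0.0
    xlogp_noise_sd: float = 0.0

    @property
    def recovery_keys(self) -> set[tuple[str, str, str]]:
        return {p.recovery_key for p in self.planted_reactions}


# ---------------------------------------------------------------------------
# Annotation fixture
# ---------------------------------------------------------------------------


def gen_annotation_fixture(
    seed: int,
    n_compounds: int = 50,
    true_fraction: float = 0.2,
    distractor_rate: float = 0.75,
    unresolved_rate: float = 0.05,
    n_excerpts_per_compound: int = 3,
    spans_per_compound: int = 8,
) -> tuple[dict, StructureIndex, list[DecisionRecord], FixtureLedger]:
    """Generate an annotation document with planted true reactions.

    Each of ``n_compounds`` input compounds gets ``n_excerpts_per_compound``
    templated excerpts; ``n_compounds * spans_per_compound`` markup spans
    are distributed over them. A span is, with the given rates, a true
    transformation mention (its ground-truth verdict orients a planted
    reaction), a distractor chemical name (verdict reject), or an
    unresolved name whose CID is absent from the structure index (verdict
    reject). The three rates must sum to 1. The returned decisions are
    the ground truth: applying them to the flattened candidates recovers
    exactly the planted reaction set.
    """
    if n_compounds < 1 or n_excerpts_per_compound < 1 or spans_per_compound < 1:
        raise FixtureParameterError("fixture sizes must be positive")
    if min(true_fraction, distractor_rate, unresolved_rate) < 0 or abs(
        true_fraction + distractor_rate + unresolved_rate - 1.0
    ) > 1e-9:
        raise FixtureParameterError(
            "true_fraction + distractor_rate + unresolved_rate must equal 1"
        )
    cat = catalog()
    eligible = [m for m in cat.mols if cat.adjacency.get(m.key)]
    if n_compounds > len(eligible):
        raise FixtureParameterError(
            f"n_compounds={n_compounds} exceeds the {len(eligible)} catalog "
            "compounds with reaction templates"
        )
    rng = random.Random(seed)
    inputs = rng.sample(eligible, n_compounds)

    n_spans = n_compounds * spans_per_compound
    n_true = round(n_spans * true_fraction)
    n_unresolved = round(n_spans * unresolved_rate)
    n_distractor = n_spans - n_true - n_unresolved
    slot_types = ["true"] * n_true + ["distractor"] * n_distractor + ["unresolved"] * n_unresolved
    rng.shuffle(slot_types)

    n_excerpts = n_compounds * n_excerpts_per_compound
    # slots per excerpt, exactly n_spans in total
    per_excerpt = [0] * n_excerpts
    for _ in range(n_spans):
        per_excerpt[rng.randrange(n_excerpts)] += 1

    index = structure_index(cat)
    decisions: list[DecisionRecord] = []
    planted: list[PlantedReaction] = []
    annotations = []
    slot_iter = iter(slot_types)
    unresolved_counter = 0

    for ci, mol in enumerate(inputs):
        data = []
        for j in range(n_excerpts_per_compound):
            excerpt_ordinal = ci * n_excerpts_per_compound + j
            n_here = per_excerpt[excerpt_ordinal]
            text = f"{mol.name} has been studied extensively."
            markup = []
            record_source_id = f"hsdb/{mol.cid}/{j}"
            for _ in range(n_here):
                slot = next(slot_iter)
                if slot == "true":
                    template, role = rng.choice(cat.adjacency[mol.key])
                    other_key = (
                        template.product_key if role == "product" else template.parent_key
                    )
                    other = cat.by_key[other_key]
                    biosystem = rng.choice(_BIOSYSTEMS)
                    enzyme = rng.choice(_ENZYMES)
                    if role == "product":
                        sentence = f" In {biosystem}, it is converted to "
                        tail = "."
                        pred_ik = mol.ref.inchikey
                        succ_ik = other.ref.inchikey
                    else:
                        sentence = f" It is formed in {biosystem} from "
                        tail = "."
                        pred_ik = other.ref.inchikey
                        succ_ik = mol.ref.inchikey
                    start = len(text) + len(sentence)
                    text = text + sentence + other.name + tail
                    markup.append(
                        {"Start": start, "Length": len(other.name), "Extra": f"CID-{other.cid}"}
                    )
                    decisions.append(
                        DecisionRecord(
                            candidate_id=candidate_id_for(
                                mol.cid, record_source_id, start, other.cid
                            ),
                            verdict=role,
                            biosystem=biosystem,
                            enzyme=enzyme,
                            transformation_type=template.transformation_type,
                            note="planted true reaction",
                        )
                    )
                    planted.append(
                        PlantedReaction(
                            predecessor_inchikey=pred_ik,
                            successor_inchikey=succ_ik,
                            biosystem=biosystem,
                            enzyme=enzyme,
                            transformation_type=template.transformation_type,
                        )
                    )
                elif slot == "distractor":
                    other = rng.choice(cat.mols)
                    while other.ref.inchikey == mol.ref.inchikey:
                        other = rng.choice(cat.mols)
                    sentence = " It is often determined alongside "
                    start = len(text) + len(sentence)
                    text = text + sentence + other.name + " in monitoring studies."
                    markup.append(
                        {"Start": start, "Length": len(other.name), "Extra": f"CID-{other.cid}"}
                    )
                    decisions.append(
                        DecisionRecord(
                            candidate_id=candidate_id_for(
                                mol.cid, record_source_id, start, other.cid
                            ),
                            verdict="reject",
                            note="distractor name, no transformation",
                        )
                    )
                else:  # unresolved
                    unresolved_counter += 1
                    fake_name = f"uncharacterized metabolite U{unresolved_counter}"
                    fake_cid = 900000 + unresolved_counter
                    sentence = " Trace amounts of "
                    start = len(text) + len(sentence)
                    text = text + sentence + fake_name + " were also reported."
                    markup.append(
                        {"Start": start, "Length": len(fake_name), "Extra": f"CID-{fake_cid}"}
                    )
                    decisions.append(
                        DecisionRecord(
                            candidate_id=candidate_id_for(
                                mol.cid, record_source_id, start, fake_cid
                            ),
                            verdict="reject",
                            note="structure not resolvable",
                        )
                    )
            data.append({"Value": {"StringWithMarkup": [{"String": text, "Markup": markup}]}})
        annotations.append(
            {
                "SourceName": "HSDB",
                "SourceID": f"hsdb/{mol.cid}",
                "Name": mol.name,
                "LinkedRecords": {"CID": [mol.cid]},
                "Data": data,
            }
        )

    document = {"Annotations": annotations}
    ledger = FixtureLedger(
        seed=seed,
        planted_reactions=planted,
        n_records=n_excerpts,
        n_spans=n_spans,
        n_true_spans=n_true,
        distractor_spans=n_distractor,
        unresolved_spans=n_unresolved,
    )
    return document, index, decisions, ledger


# ---------------------------------------------------------------------------
# Library fixture
# ---------------------------------------------------------------------------


def _distinct_templates(cat: Catalog, rng: random.Random, n: int) -> list[ReactionTemplate]:
    """Sample n templates with pairwise-distinct structure pairs."""
    pool = list(cat.templates)
    rng.shuffle(pool)
    seen: set[tuple[str, str]] = set()
    out = []
    for t in pool:
        pair = (cat.by_key[t.parent_key].ref.inchikey, cat.by_key[t.product_key].ref.inchikey)
        if pair in seen:
            continue
        seen.add(pair)
        out.append(t)
        if len(out) == n:
            return out
    raise FixtureParameterError(
        f"cannot sample {n} distinct reaction pairs from the {len(pool)}-template catalog"
    )


def gen_library_fixture(
    seed: int,
    n_entries: int = 200,
    n_overlap_exact: int = 3,
    n_overlap_variant: int = 2,
    n_candidates: int = 25,
    candidate_reactions: list[ReactionRecord] | None = None,
) -> tuple[TransformationsLibrary, list[ReactionRecord], FixtureLedger]:
    """Generate a library and a curated candidate set with known overlap.

    Of the candidate reactions, ``n_overlap_exact`` are present in the
    library with identical structure pair and metadata, ``n_overlap_variant``
    with the same pair but an altered biosystem, and the rest are absent,
    so ``dedup_classify(candidates, library)`` must report exactly
    ``(novel, exact, variant) = (n_candidates - both overlaps,
    n_overlap_exact, n_overlap_variant)``. Pass ``candidate_reactions`` to
    reuse an externally curated set (e.g. the annotation fixture's planted
    reactions) instead of sampling a fresh one.
    """
    rng = random.Random(seed)
    cat = catalog()
    if candidate_reactions is None:
        templates = _distinct_templates(cat, rng, n_candidates)
        candidates = [
            cat.reaction(
                t,
                biosystem=rng.choice(_BIOSYSTEMS),
                enzyme=rng.choice(_ENZYMES),
                evidence=f"fixture evidence {i}",
                source_id=f"fixture/cand/{i}",
            )
            for i, t in enumerate(templates)
        ]
    else:
        candidates = list(candidate_reactions)
        n_candidates = len(candidates)
    if n_overlap_exact + n_overlap_variant > n_candidates:
        raise FixtureParameterError("overlap counts exceed candidate set size")
    if n_overlap_exact + n_overlap_variant > n_entries:
        raise FixtureParameterError("overlap counts exceed library size")

    # distinct pairs among candidates are required for exact planted counts
    cand_pairs = [r.structure_pair() for r in candidates]
    if len(set(cand_pairs)) != len(cand_pairs):
        raise FixtureParameterError("candidate reactions must have distinct structure pairs")

    overlap_idx = rng.sample(range(n_candidates), n_overlap_exact + n_overlap_variant)
    exact_idx = set(overlap_idx[:n_overlap_exact])
    variant_idx = set(overlap_idx[n_overlap_exact:])

    entries: list[ReactionRecord] = []
    for i in sorted(exact_idx):
        r = candidates[i]
        entries.append(
            ReactionRecord(
                predecessor=r.predecessor,
                successor=r.successor,
                biosystem=r.biosystem,
                enzyme=r.enzyme,
                transformation_type=r.transformation_type,
                evidence_excerpt="library copy",
                source_name="library",
                source_id=f"lib/exact/{i}",
            )
        )
    for i in sorted(variant_idx):
        r = candidates[i]
        other_bio = rng.choice([b for b in _BIOSYSTEMS if b != (r.biosystem or "")])
        entries.append(
            ReactionRecord(
                predecessor=r.predecessor,
                successor=r.successor,
                biosystem=other_bio,
                enzyme=r.enzyme,
                transformation_type=r.transformation_type,
                evidence_excerpt="library copy, different biosystem",
                source_name="library",
                source_id=f"lib/variant/{i}",
            )
        )

    # background entries: distinct pairs disjoint from every candidate pair
    n_background = n_entries - len(entries)
    cand_pair_set = set(cand_pairs)
    background = []
    for t in _distinct_templates(cat, rng, len(cat.templates)):
        pair = (cat.by_key[t.parent_key].ref.inchikey, cat.by_key[t.product_key].ref.inchikey)
        if pair in cand_pair_set:
            continue
        background.append(t)
        if len(background) == n_background:
            break
    if len(background) < n_background:
        raise FixtureParameterError(
            f"catalog cannot supply {n_background} background library entries"
        )
    for i, t in enumerate(background):
        entries.append(
            cat.reaction(
                t,
                biosystem=rng.choice(_BIOSYSTEMS),
                enzyme=rng.choice(_ENZYMES),
                evidence=f"library background {i}",
                source_name="library",
                source_id=f"lib/bg/{i}",
            )
        )
    rng.shuffle(entries)
    lib = TransformationsLibrary(entries=entries, version=f"fixture-{seed}")
    ledger = FixtureLedger(
        seed=seed,
        planted_dedup_classes={
            "novel": n_candidates - n_overlap_exact - n_overlap_variant,
            "exact_duplicate": n_overlap_exact,
            "metadata_variant": n_overlap_variant,
        },
    )
    return lib, candidates, ledger


# ---------------------------------------------------------------------------
# Screening fixture
# ---------------------------------------------------------------------------


def gen_screening_fixture(
    seed: int,
    n_compounds: int = 436,
    n_tp: int = 72,
    n_linkable_pairs: int = 36,
    n_orphans: int = 36,
    shift: float = 1.0,
    noise_sd: float = 0.5,
    reactions: list[ReactionRecord] | None = None,
) -> tuple[list[IdentifiedCompound], list[SuspectEntry], FixtureLedger]:
    """Generate an identified-compounds table plus a matching suspect list.

    Plants ``n_tp`` identified TP structures (``n_tp == n_linkable_pairs +
    n_orphans`` is enforced): for the linkable ones, the parent compound
    is also in the identified list; orphan TPs have their parent withheld.
    The remaining rows are decoys matching no suspect. Parent XlogP is
    drawn from a normal distribution centred at 2.5 (sd 1.2, the typical
    spread of environmentally relevant organics); each TP's XlogP is its
    parent's minus ``shift`` plus Gaussian noise of sd ``noise_sd``, so a
    positive shift plants the polarity increase the screening comparison
    is meant to detect.

    When ``reactions`` is given, linkable/orphan reactions are drawn from
    that list (e.g. a merged library) instead of the template catalog.
    """
    if n_tp != n_linkable_pairs + n_orphans:
        raise FixtureParameterError(
            f"n_tp ({n_tp}) must equal n_linkable_pairs + n_orphans "
            f"({n_linkable_pairs} + {n_orphans})"
        )
    if n_compounds < n_tp + n_linkable_pairs:
        raise FixtureParameterError("n_compounds too small for the planted TPs and parents")
    rng = np.random.default_rng(seed)
    cat = catalog()

    if reactions is None:
        pool = list(cat.templates)
        order = rng.permutation(len(pool))
        candidates = [cat.reaction(pool[i], biosystem="human") for i in order]
        # the suspect list will hold exactly the picked reactions, so the
        # only constraint is that predecessor/successor keys don't collide
        used_iks: set[str] = set()
        picked: list[ReactionRecord] = []
        for r in candidates:
            if len(picked) == n_tp:
                break
            pik, sik = r.structure_pair()
            if pik == sik or pik in used_iks or sik in used_iks:
                continue
            picked.append(r)
            used_iks.update((pik, sik))
        if len(picked) < n_tp:
            raise FixtureParameterError(
                f"could not plant {n_tp} disjoint reactions (got {len(picked)})"
            )
        linkable = picked[:n_linkable_pairs]
        orphaned = picked[n_linkable_pairs:]
        suspects = export_suspect_list(
            TransformationsLibrary(entries=picked, version=f"screening-{seed}")
        )
        avoid_iks = used_iks
    else:
        # the suspect list is the one the pipeline will export from the
        # provided library, so planting exact counts means no identified
        # compound may collide with any successor, and no identified
        # compound other than a designated parent may match a linking
        # predecessor of a planted TP's suspect entry
        suspects = export_suspect_list(
            TransformationsLibrary(entries=list(reactions), version=f"screening-{seed}")
        )
        entry_by_ik = {s.inchikey: s for s in suspects}
        succ_all = set(entry_by_ik)
        order = rng.permutation(len(reactions))
        candidates = [reactions[i] for i in order]
        identified_iks: set[str] = set()
        linked_preds: set[str] = set()  # predecessors of planted suspect entries
        linkable = []
        orphaned = []
        for r in candidates:
            pik, sik = r.structure_pair()
            entry = entry_by_ik[sik]
            preds = set(entry.predecessor_inchikeys)
            if sik in identified_iks or sik in linked_preds:
                continue
            if preds & identified_iks:
                continue
            need_parent = len(linkable) < n_linkable_pairs
            if need_parent:
                if pik == sik or pik in succ_all or pik in linked_preds:
                    continue
                linkable.append(r)
                identified_iks.update((pik, sik))
            else:
                if len(orphaned) == n_orphans:
                    break
                orphaned.append(r)
                identified_iks.add(sik)
            linked_preds |= preds
        picked = linkable + orphaned
        if len(picked) < n_tp:
            raise FixtureParameterError(
                f"could not plant {n_tp} disjoint reactions from the provided "
                f"library (got {len(picked)})"
            )
        avoid_iks = succ_all | linked_preds | identified_iks

    identified: list[IdentifiedCompound] = []
    for r in linkable:
        parent_xlogp = float(rng.normal(2.5, 1.2))
        tp_xlogp = parent_xlogp - shift + float(rng.normal(0.0, noise_sd))
        identified.append(
            IdentifiedCompound(
                name=r.predecessor.name,
                cid=r.predecessor.cid,
                inchikey=r.predecessor.structure.inchikey,
                xlogp=round(parent_xlogp, 3),
            )
        )
        identified.append(
            IdentifiedCompound(
                name=r.successor.name,
                cid=r.successor.cid,
                inchikey=r.successor.structure.inchikey,
                xlogp=round(tp_xlogp, 3),
            )
        )
    for r in orphaned:
        parent_xlogp = float(rng.normal(2.5, 1.2))
        tp_xlogp = parent_xlogp - shift + float(rng.normal(0.0, noise_sd))
        identified.append(
            IdentifiedCompound(
                name=r.successor.name,
                cid=r.successor.cid,
                inchikey=r.successor.structure.inchikey,
                xlogp=round(tp_xlogp, 3),
            )
        )

    n_decoys = n_compounds - len(identified)
    decoy_pool = [m for m in cat.mols if m.ref.inchikey not in avoid_iks]
    if n_decoys > len(decoy_pool):
        raise FixtureParameterError(
            f"need {n_decoys} decoy compounds but only {len(decoy_pool)} unused "
            "catalog structures remain"
        )
    decoy_idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
    for i in decoy_idx:
        m = decoy_pool[int(i)]
        identified.append(
            IdentifiedCompound(
                name=m.name,
                cid=m.cid,
                inchikey=m.ref.inchikey,
                xlogp=round(float(rng.normal(2.0, 1.5)), 3),
            )
        )
    perm = rng.permutation(len(identified))
    identified = [identified[int(i)] for i in perm]

    ledger = FixtureLedger(
        seed=seed,
        planted_reactions=[
            PlantedReaction(
                predecessor_inchikey=r.predecessor.structure.inchikey,
                successor_inchikey=r.successor.structure.inchikey,
                biosystem=r.biosystem,
                enzyme=r.enzyme,
                transformation_type=r.transformation_type,
            )
            for r in picked
        ],
        planted_tp=n_tp,
        planted_pairs=n_linkable_pairs,
        planted_orphans=n_orphans,
        xlogp_shift=shift,
        xlogp_noise_sd=noise_sd,
    )
    return identified, suspects, ledger
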