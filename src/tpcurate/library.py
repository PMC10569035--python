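"""Transformations-library handling: I/O, uniqueness, dedup, merge, export.

A transformations library is a flat list of directed reactions with
provenance, mirroring the public predecessor/successor reaction tables
used as TP suspect sources. Identity of a reaction is its structure pair
(predecessor InChIKey, successor InChIKey); the CID pair is an equivalent
shortcut when both identifiers are present. Duplicate pairs are allowed
in a library — the same transformation reported in different biosystems
is two entries — which is exactly what the metadata-variant class in
deduplication captures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .chem import canonicalize
from .curation import CompoundRef, ReactionRecord, make_reaction_smiles
from .errors import MergePolicyError, SchemaError

LIBRARY_COLUMNS = [
    "predecessor_name",
    "predecessor_cid",
    "predecessor_smiles",
    "successor_name",
    "successor_cid",
    "successor_smiles",
    "biosystem",
    "enzyme",
    "transformation_type",
    "evidence",
    "source_name",
    "source_id",
    "reaction_smiles",
]

MERGE_POLICIES = ("novel_only", "novel_plus_variants")


def normalize_metadata(value: str | None) -> str:
    """Whitespace/case normalization used for metadata comparison.

    Deliberately nothing more: no synonym resolution ('liver' != 'hepatic').
    """
    return (value or "").strip().casefold()


def metadata_key(r: ReactionRecord) -> tuple[str, str, str]:
    return (
        normalize_metadata(r.biosystem),
        normalize_metadata(r.enzyme),
        normalize_metadata(r.transformation_type),
    )


def pair_key(r: ReactionRecord) -> tuple:
    """Uniqueness key: CID pair when both sides carry one, else the
    InChIKey pair. The two kinds never collide (tagged tuples)."""
    if r.predecessor.cid is not None and r.successor.cid is not None:
        return ("cid", r.predecessor.cid, r.successor.cid)
    return ("ik", *r.structure_pair())


class TransformationsLibrary:
    """A keyed multiset of reactions with a version tag.

    ``index`` maps each entry's :func:`pair_key` to the entry positions
    holding it (duplicate pairs map to several positions).
    """

    def __init__(self, entries: list[ReactionRecord] | None = None, version: str = "0.1"):
        if not version:
            raise ValueError("library version tag must be non-empty")
        self.entries: list[ReactionRecord] = list(entries or [])
        self.version = version
        self._index: dict[tuple, list[int]] | None = None
        self._ik_index: dict[tuple[str, str], list[int]] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def index(self) -> dict[tuple, list[int]]:
        if self._index is None:
            idx: dict[tuple, list[int]] = {}
            for pos, r in enumerate(self.entries):
                idx.setdefault(pair_key(r), []).append(pos)
            self._index = idx
        return self._index

    @property
    def inchikey_index(self) -> dict[tuple[str, str], list[int]]:
        """Structure-pair index; defined for every entry regardless of CIDs."""
        if self._ik_index is None:
            idx: dict[tuple[str, str], list[int]] = {}
            for pos, r in enumerate(self.entries):
                idx.setdefault(r.structure_pair(), []).append(pos)
            self._ik_index = idx
        return self._ik_index

    def _invalidate(self) -> None:
        self._index = None
        self._ik_index = None

    def extend(self, reactions: list[ReactionRecord]) -> None:
        self.entries.extend(reactions)
        self._invalidate()


def count_unique_by_cid(lib: TransformationsLibrary) -> int:
    """Number of distinct reaction pairs (CID pairs, with CID-less entries
    counted by their InChIKey pair)."""
    return len({pair_key(r) for r in lib.entries})


@dataclass
class DedupReport:
    """Partition of a curated reaction set against an existing library."""

    novel: list[ReactionRecord] = field(default_factory=list)
    exact_duplicate: list[ReactionRecord] = field(default_factory=list)
    metadata_variant: list[ReactionRecord] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "novel": len(self.novel),
            "exact_duplicate": len(self.exact_duplicate),
            "metadata_variant": len(self.metadata_variant),
        }

    @property
    def total(self) -> int:
        return len(self.novel) + len(self.exact_duplicate) + len(self.metadata_variant)


def dedup_classify(
    new_reactions: list[ReactionRecord], lib: TransformationsLibrary
) -> DedupReport:
    """Classify each curated reaction against a library.

    ``exact_duplicate``: some library entry matches the structure pair
    (exact InChIKey level on both sides) AND the normalized (biosystem,
    enzyme, transformation type) triple. ``metadata_variant``: the
    structure pair is listed but only with different metadata. ``novel``:
    the pair is not in the library at all. The three classes partition
    the input.
    """
    report = DedupReport()
    ik_index = lib.inchikey_index
    for r in new_reactions:
        positions = ik_index.get(r.structure_pair(), [])
        if not positions:
            report.novel.append(r)
        elif any(metadata_key(lib.entries[p]) == metadata_key(r) for p in positions):
            report.exact_duplicate.append(r)
        else:
            report.metadata_variant.append(r)
    return report


def merge_reactions(
    lib: TransformationsLibrary,
    new_reactions: list[ReactionRecord],
    policy: str = "novel_only",
    report: DedupReport | None = None,
    version: str | None = None,
) -> TransformationsLibrary:
    """Merge curated reactions into a library under an explicit policy.

    ``novel_only`` adds only reactions whose pair is new; metadata
    variants are skipped (and available in the report). ``novel_plus_variants``
    also adds the variants. Exact duplicates are never added, which makes
    merging idempotent. Returns a new library; the input is unchanged.
    """
    if policy not in MERGE_POLICIES:
        raise MergePolicyError(f"unknown merge policy {policy!r}; expected one of {MERGE_POLICIES}")
    if report is None:
        report = dedup_classify(new_reactions, lib)
    added = list(report.novel)
    if policy == "novel_plus_variants":
        added += report.metadata_variant
    merged = TransformationsLibrary(
        entries=lib.entries + added, version=version or lib.version
    )
    return merged


# ---------------------------------------------------------------------------
# Suspect-list export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuspectEntry:
    """One suspect-list row: a distinct TP structure with its known parents."""

    name: str
    smiles: str
    inchikey: str
    formula: str
    monoisotopic_mass: float
    predecessor_inchikeys: tuple[str, ...]

    @property
    def skeleton(self) -> str:
        return self.inchikey[:14]


def export_suspect_list(lib: TransformationsLibrary) -> list[SuspectEntry]:
    """One entry per distinct successor structure (unique InChIKey).

    A structure reached from several parents yields a single entry listing
    every predecessor InChIKey. The monoisotopic mass is recomputed from
    the structure rather than trusted from the source table, since suspect
    screening hinges on mass accuracy. Output is sorted by InChIKey for
    byte-stable files.
    """
    by_ik: dict[str, dict] = {}
    for r in lib.entries:
        succ = r.successor
        ik = succ.structure.inchikey
        slot = by_ik.setdefault(
            ik, {"name": succ.name, "structure": succ.structure, "preds": set()}
        )
        slot["preds"].add(r.predecessor.structure.inchikey)
    out = []
    for ik in sorted(by_ik):
        slot = by_ik[ik]
        ref = canonicalize(slot["structure"].smiles)
        out.append(
            SuspectEntry(
                name=slot["name"],
                smiles=ref.smiles,
                inchikey=ref.inchikey,
                formula=ref.formula,
                monoisotopic_mass=ref.monoisotopic_mass,
                predecessor_inchikeys=tuple(sorted(slot["preds"])),
            )
        )
    return out


SUSPECT_COLUMNS = [
    "Name",
    "SMILES",
    "InChIKey",
    "Molecular_Formula",
    "Monoisotopic_Mass",
    "Predecessor_InChIKeys",
]


def write_suspects_csv(suspects: list[SuspectEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SUSPECT_COLUMNS)
        for s in suspects:
            w.writerow(
                [
                    s.name,
                    s.smiles,
                    s.inchikey,
                    s.formula,
                    f"{s.monoisotopic_mass:.6f}",
                    ";".join(s.predecessor_inchikeys),
                ]
            )


def read_suspects_csv(path: str | Path) -> list[SuspectEntry]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != SUSPECT_COLUMNS:
            missing = [c for c in SUSPECT_COLUMNS if c not in (header or [])]
            unknown = [c for c in (header or []) if c not in SUSPECT_COLUMNS]
            raise SchemaError(
                f"suspect list {path}: missing={missing} unknown={unknown}",
                missing=missing,
                unknown=unknown,
            )
        out = []
        for rec in reader:
            name, smiles, ik, formula, mass, preds = rec
            out.append(
                SuspectEntry(
                    name=name,
                    smiles=smiles,
                    inchikey=ik,
                    formula=formula,
                    monoisotopic_mass=float(mass),
                    predecessor_inchikeys=tuple(p for p in preds.split(";") if p),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Reaction-table I/O (shared by curated outputs and libraries)
# ---------------------------------------------------------------------------


def write_reactions_csv(reactions: list[ReactionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LIBRARY_COLUMNS)
        for r in reactions:
            w.writerow(
                [
                    r.predecessor.name,
                    "" if r.predecessor.cid is None else r.predecessor.cid,
                    r.predecessor.structure.smiles,
                    r.successor.name,
                    "" if r.successor.cid is None else r.successor.cid,
                    r.successor.structure.smiles,
                    r.biosystem or "",
                    r.enzyme or "",
                    r.transformation_type or "",
                    r.evidence_excerpt,
                    r.source_name,
                    r.source_id,
                    make_reaction_smiles(r),
                ]
            )


def read_reactions_csv(path: str | Path) -> list[ReactionRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != LIBRARY_COLUMNS:
            missing = [c for c in LIBRARY_COLUMNS if c not in (header or [])]
            unknown = [c for c in (header or []) if c not in LIBRARY_COLUMNS]
            raise SchemaError(
                f"reaction table {path}: missing={missing} unknown={unknown}",
                missing=missing,
                unknown=unknown,
            )
        out = []
        for rec in reader:
            (p_name, p_cid, p_smiles, s_name, s_cid, s_smiles, biosystem,
             enzyme, ttype, evidence, src_name, src_id, _rxn) = rec
            out.append(
                ReactionRecord(
                    predecessor=CompoundRef(p_name, int(p_cid) if p_cid else None, canonicalize(p_smiles)),
                    successor=CompoundRef(s_name, int(s_cid) if s_cid else None, canonicalize(s_smiles)),
                    biosystem=biosystem or None,
                    enzyme=enzyme or None,
                    transformation_type=ttype or None,
                    evidence_excerpt=evidence,
                    source_name=src_name,
                    source_id=src_id,
                )
            )
    return out


def write_library(lib: TransformationsLibrary, path: str | Path) -> None:
    """Library file = reaction table; the version tag travels separately
    (a ``<path>.version`` sidecar is deliberately avoided — callers pass
    the tag explicitly)."""
    write_reactions_csv(lib.entries, path)


def read_library(path: str | Path, version: str = "0.1") -> TransformationsLibrary:
    return TransformationsLibrary(entries=read_reactions_csv(path), version=version)
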