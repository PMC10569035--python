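"""Turning candidate rows plus curator decisions into directed reactions.

A curator's work is captured as a declarative decisions CSV: one verdict
per candidate key (``product`` — the matched name is a transformation
product of the input compound; ``parent`` — the matched name is the
input's precursor; ``reject`` — the name is unrelated to a transformation).
Applying the decisions to a candidate table is pure and reproducible, so
a curation session can be replayed, diffed and reviewed.

Compounds missed by the upstream text mining enter through
:class:`MissingEntry` records carrying a hand-supplied name and SMILES.

Reaction validation reports issues (salt components, stereo-only
differences, degenerate or under-annotated records) without mutating
anything; what to do about an issue is itself a curation decision.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .annotations import CandidateRow
from .chem import StructureIndex, StructureRef, canonicalize, structures_match
from .errors import CurationError, SchemaError, UndecidedError

logger = logging.getLogger(__name__)

VERDICTS = ("product", "parent", "reject")
DIRECTIONS = ("product", "parent")

# closed vocabulary reported by validate_reaction
ISSUE_IDENTICAL = "identical_sides"
ISSUE_STEREO = "stereo_only_difference"
ISSUE_SALT = "salt_component"
ISSUE_UNRESOLVED = "unresolved_cid"
ISSUE_METADATA = "missing_metadata"


@dataclass(frozen=True)
class DecisionRecord:
    """One curator verdict on one candidate row."""

    candidate_id: str
    verdict: str
    biosystem: str | None = None
    enzyme: str | None = None
    transformation_type: str | None = None
    note: str = ""

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise CurationError(
                f"verdict {self.verdict!r} for candidate {self.candidate_id}: "
                f"must be one of {VERDICTS}"
            )


@dataclass(frozen=True)
class MissingEntry:
    """A hand-curated compound the text mining missed, with its reaction
    direction relative to the input compound."""

    input_cid: int
    new_name: str
    new_smiles: str
    direction: str
    biosystem: str | None = None
    enzyme: str | None = None
    transformation_type: str | None = None
    evidence_excerpt: str = ""

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise CurationError(
                f"direction {self.direction!r} must be one of {DIRECTIONS}"
            )
        if not self.new_name:
            raise CurationError("missing entry requires a non-empty new_name")


@dataclass(frozen=True)
class CompoundRef:
    """One side of a reaction: a name, an optional CID, and a structure."""

    name: str
    cid: int | None
    structure: StructureRef


@dataclass(frozen=True)
class ReactionRecord:
    """A directed predecessor -> successor transformation with metadata."""

    predecessor: CompoundRef
    successor: CompoundRef
    biosystem: str | None = None
    enzyme: str | None = None
    transformation_type: str | None = None
    evidence_excerpt: str = ""
    source_name: str = ""
    source_id: str = ""

    @property
    def reaction_smiles(self) -> str:
        return make_reaction_smiles(self)

    def structure_pair(self) -> tuple[str, str]:
        """(predecessor inchikey, successor inchikey) — the identity used
        for set comparisons and CID-less indexing."""
        return (self.predecessor.structure.inchikey, self.successor.structure.inchikey)


def make_reaction_smiles(r: ReactionRecord) -> str:
    """``predecessor>>successor`` over the stored canonical SMILES."""
    return f"{r.predecessor.structure.smiles}>>{r.successor.structure.smiles}"


@dataclass(frozen=True)
class LedgerEntry:
    candidate_id: str
    status: str  # accepted_product | accepted_parent | rejected | undecided
    note: str = ""


def apply_decisions(
    candidates: list[CandidateRow], decisions: list[DecisionRecord]
) -> tuple[list[ReactionRecord], list[LedgerEntry]]:
    """Apply curator verdicts to a candidate table.

    Returns the accepted reactions (in candidate-table order) and a full
    ledger: every candidate appears exactly once as accepted, rejected or
    undecided, so ``len(reactions) + rejections + undecided ==
    len(candidates)`` always holds.

    Orientation: verdict ``product`` yields input -> matched; verdict
    ``parent`` yields matched -> input. Metadata (biosystem, enzyme,
    transformation type) is copied verbatim from the decision.

    If one candidate has several decisions the last one in file order
    wins and a warning is logged.

    Raises
    ------
    CurationError
        For a decision on an unknown candidate key, or an accepting
        verdict on a candidate whose structures are unresolved (those must
        go through the missing-entry path).
    """
    by_id = {c.candidate_id: c for c in candidates}
    chosen: dict[str, DecisionRecord] = {}
    for d in decisions:
        if d.candidate_id not in by_id:
            raise CurationError(f"decision references unknown candidate_id {d.candidate_id!r}")
        if d.candidate_id in chosen:
            logger.warning(
                "duplicate decision for candidate %s: keeping the later verdict %r",
                d.candidate_id,
                d.verdict,
            )
        chosen[d.candidate_id] = d

    reactions: list[ReactionRecord] = []
    ledger: list[LedgerEntry] = []
    for cand in candidates:
        d = chosen.get(cand.candidate_id)
        if d is None:
            ledger.append(LedgerEntry(cand.candidate_id, "undecided"))
            continue
        if d.verdict == "reject":
            ledger.append(LedgerEntry(cand.candidate_id, "rejected", d.note))
            continue
        if not cand.resolved or cand.matched_smiles is None:
            raise CurationError(
                f"candidate {cand.candidate_id} ({cand.matched_name!r}) has no resolved "
                "structure; accepting it requires the missing-entry path"
            )
        if cand.input_smiles is None:
            raise CurationError(
                f"candidate {cand.candidate_id}: input compound CID {cand.input_cid} "
                "has no structure in the index"
            )
        input_ref = CompoundRef(cand.input_name, cand.input_cid, canonicalize(cand.input_smiles))
        matched_ref = CompoundRef(cand.matched_name, cand.matched_cid, canonicalize(cand.matched_smiles))
        if d.verdict == "product":
            pred, succ = input_ref, matched_ref
        else:
            pred, succ = matched_ref, input_ref
        reactions.append(
            ReactionRecord(
                predecessor=pred,
                successor=succ,
                biosystem=d.biosystem,
                enzyme=d.enzyme,
                transformation_type=d.transformation_type,
                evidence_excerpt=cand.excerpt,
                source_name=cand.source_name,
                source_id=cand.source_id,
            )
        )
        ledger.append(LedgerEntry(cand.candidate_id, f"accepted_{d.verdict}", d.note))
    return reactions, ledger


def undecided_ids(ledger: list[LedgerEntry]) -> list[str]:
    return [e.candidate_id for e in ledger if e.status == "undecided"]


def assert_all_decided(ledger: list[LedgerEntry], allow_undecided: bool = False) -> None:
    """Finalization gate: undecided candidates block unless explicitly allowed."""
    pending = undecided_ids(ledger)
    if pending and not allow_undecided:
        raise UndecidedError(pending)


def add_missing_entry(entry: MissingEntry, input_index: StructureIndex) -> ReactionRecord:
    """Build a reaction from a hand-supplied compound.

    The new compound's SMILES is canonicalized on entry (an unparseable
    structure fails before any record exists) and carries no CID — it is,
    by construction, a compound the identifier mapping did not know.
    """
    input_entry = input_index.get(entry.input_cid)
    if input_entry is None:
        raise CurationError(f"input CID {entry.input_cid} not present in the structure index")
    new_ref = CompoundRef(entry.new_name, None, canonicalize(entry.new_smiles))
    input_ref = CompoundRef(input_entry.name, input_entry.cid, input_entry.structure)
    if entry.direction == "product":
        pred, succ = input_ref, new_ref
    else:
        pred, succ = new_ref, input_ref
    return ReactionRecord(
        predecessor=pred,
        successor=succ,
        biosystem=entry.biosystem,
        enzyme=entry.enzyme,
        transformation_type=entry.transformation_type,
        evidence_excerpt=entry.evidence_excerpt,
        source_name="manual",
        source_id=f"manual/{entry.input_cid}",
    )


def validate_reaction(r: ReactionRecord) -> list[str]:
    """Report curation issues for one reaction; never mutates.

    Issues come from a closed vocabulary: ``identical_sides`` (degenerate
    reaction), ``stereo_only_difference`` (the two sides share an InChIKey
    skeleton but differ in stereochemistry), ``salt_component`` (either
    side is multi-component), ``unresolved_cid`` (either side lacks an
    identifier), ``missing_metadata`` (no biosystem, enzyme or
    transformation type at all). An empty list means clean.
    """
    issues: list[str] = []
    a, b = r.predecessor.structure, r.successor.structure
    if structures_match(a, b, "exact"):
        issues.append(ISSUE_IDENTICAL)
    elif structures_match(a, b, "skeleton"):
        issues.append(ISSUE_STEREO)
    if "." in a.smiles or "." in b.smiles:
        issues.append(ISSUE_SALT)
    if r.predecessor.cid is None or r.successor.cid is None:
        issues.append(ISSUE_UNRESOLVED)
    if not any(
        (v or "").strip() for v in (r.biosystem, r.enzyme, r.transformation_type)
    ):
        issues.append(ISSUE_METADATA)
    return issues


# ---------------------------------------------------------------------------
# CSV artifacts
# ---------------------------------------------------------------------------

DECISION_COLUMNS = ["candidate_id", "verdict", "biosystem", "enzyme", "transformation_type", "note"]
MISSING_COLUMNS = [
    "input_cid",
    "new_name",
    "new_smiles",
    "direction",
    "biosystem",
    "enzyme",
    "transformation_type",
    "evidence_excerpt",
]


def _check_header(header, expected, path):
    if header != expected:
        missing = [c for c in expected if c not in (header or [])]
        unknown = [c for c in (header or []) if c not in expected]
        raise SchemaError(
            f"{path}: missing={missing} unknown={unknown}", missing=missing, unknown=unknown
        )


def write_decisions_csv(decisions: list[DecisionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DECISION_COLUMNS)
        for d in decisions:
            w.writerow(
                [
                    d.candidate_id,
                    d.verdict,
                    d.biosystem or "",
                    d.enzyme or "",
                    d.transformation_type or "",
                    d.note,
                ]
            )


def read_decisions_csv(path: str | Path) -> list[DecisionRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), DECISION_COLUMNS, str(path))
        out = []
        for rec in reader:
            cand_id, verdict, biosystem, enzyme, ttype, note = rec
            out.append(
                DecisionRecord(
                    candidate_id=cand_id,
                    verdict=verdict,
                    biosystem=biosystem or None,
                    enzyme=enzyme or None,
                    transformation_type=ttype or None,
                    note=note,
                )
            )
    return out


def write_missing_entries_csv(entries: list[MissingEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MISSING_COLUMNS)
        for e in entries:
            w.writerow(
                [
                    e.input_cid,
                    e.new_name,
                    e.new_smiles,
                    e.direction,
                    e.biosystem or "",
                    e.enzyme or "",
                    e.transformation_type or "",
                    e.evidence_excerpt,
                ]
            )


def read_missing_entries_csv(path: str | Path) -> list[MissingEntry]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), MISSING_COLUMNS, str(path))
        out = []
        for rec in reader:
            cid, name, smiles, direction, biosystem, enzyme, ttype, evidence = rec
            out.append(
                MissingEntry(
                    input_cid=int(cid),
                    new_name=name,
                    new_smiles=smiles,
                    direction=direction,
                    biosystem=biosystem or None,
                    enzyme=enzyme or None,
                    transformation_type=ttype or None,
                    evidence_excerpt=evidence,
                )
            )
    return out
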