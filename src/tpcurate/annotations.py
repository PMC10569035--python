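"""Parsing of markup-annotated text excerpts into candidate-reaction tables.

The input is an annotation JSON document in a PUG-View-like dialect: each
annotation carries a source compound (CID), source descriptors, and one or
more text excerpts; each excerpt is a string plus a markup array of
character spans, each span optionally linked to the CID of the chemical
name it covers. A machine-readable schema for the dialect ships in
``docs/annotation_schema.json``.

Offsets are 0-based, length-counted, in Unicode code points.

Each (annotation, excerpt) pair becomes one :class:`AnnotationRecord`;
each markup span becomes one :class:`CandidateRow` once flattened against
a local CID -> structure index. Excerpts with zero spans are retained —
they are the raw material for manually added entries downstream.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

from .chem import StructureIndex
from .errors import AnnotationParseError, SchemaError, SpanValidationError


@dataclass(frozen=True)
class MarkupSpan:
    """One recognized chemical name inside an excerpt.

    ``matched_text`` always equals ``excerpt[start : start + length]``;
    this is asserted at parse time. ``linked_cid`` is None when the
    text-mining engine recognized a name without resolving an identifier.
    """

    start: int
    length: int
    matched_text: str
    linked_cid: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class AnnotationRecord:
    """One compound's excerpt with its markup spans (sorted by start)."""

    input_cid: int
    input_name: str
    source_name: str
    source_id: str
    excerpt: str
    spans: tuple[MarkupSpan, ...]


@dataclass(frozen=True)
class CandidateRow:
    """One flattened (excerpt, span) pair — the unit a curator decides on.

    ``resolved`` is True iff the matched name's structure was found in the
    index; an unresolved candidate can only be accepted through the
    missing-entry path. Absent values are None in memory and empty cells
    on disk, with ``resolved`` carrying the flag explicitly.
    """

    candidate_id: str
    input_cid: int
    input_name: str
    input_smiles: str | None
    matched_name: str
    matched_cid: int | None
    matched_smiles: str | None
    resolved: bool
    excerpt: str
    source_name: str
    source_id: str


CANDIDATE_COLUMNS = [
    "candidate_id",
    "input_cid",
    "input_name",
    "input_smiles",
    "matched_name",
    "matched_cid",
    "matched_smiles",
    "resolved_flag",
    "excerpt",
    "source_name",
    "source_id",
]


def candidate_id_for(input_cid: int, source_id: str, start: int, matched_cid: int | None) -> str:
    """Deterministic candidate key: SHA-1 over the identifying 4-tuple."""
    raw = f"{input_cid}|{source_id}|{start}|{'' if matched_cid is None else matched_cid}"
    return hashlib.sha1(raw.encode("utf-8")).hexdigest()[:16]


def _require(obj, key, typ, path):
    if not isinstance(obj, dict):
        raise AnnotationParseError(f"expected object, got {type(obj).__name__}", path)
    if key not in obj:
        raise AnnotationParseError(f"missing required field {key!r}", path)
    value = obj[key]
    if typ is int and isinstance(value, bool):
        raise AnnotationParseError(f"field {key!r} must be an integer", path)
    if not isinstance(value, typ):
        raise AnnotationParseError(
            f"field {key!r} must be {typ.__name__}, got {type(value).__name__}", path
        )
    return value


def _parse_markup(item, excerpt: str, path: str) -> MarkupSpan:
    start = _require(item, "Start", int, path)
    length = _require(item, "Length", int, path)
    if start < 0 or length < 1:
        raise AnnotationParseError(f"span offsets out of range (Start={start}, Length={length})", path)
    if start + length > len(excerpt):
        raise SpanValidationError(
            f"{path}: span [{start}, {start + length}) exceeds excerpt length {len(excerpt)}"
        )
    matched = excerpt[start : start + length]
    if "Text" in item and item["Text"] != matched:
        raise SpanValidationError(
            f"{path}: markup Text {item['Text']!r} does not equal excerpt "
            f"slice {matched!r} at [{start}, {start + length})"
        )
    cid = None
    extra = item.get("Extra")
    if extra is not None:
        if not (isinstance(extra, str) and extra.startswith("CID-") and extra[4:].isdigit()):
            raise AnnotationParseError(f"Extra must look like 'CID-<n>', got {extra!r}", path)
        cid = int(extra[4:])
    return MarkupSpan(start=start, length=length, matched_text=matched, linked_cid=cid)


def parse_annotation_json(document: dict) -> list[AnnotationRecord]:
    """Parse an annotation document into per-excerpt records.

    One record is produced per (annotation, excerpt) pair; the record's
    ``source_id`` is the annotation's SourceID suffixed with ``/<k>`` where
    ``k`` is the 0-based excerpt ordinal, so that records (and therefore
    candidate keys) stay unique when one annotation carries several
    excerpts. Spans are validated against the excerpt text and sorted by
    start offset. Excerpts with no markup yield records with zero spans.

    Raises
    ------
    AnnotationParseError
        On structural problems, naming the offending record path.
    SpanValidationError
        When a markup span disagrees with its excerpt text.
    """
    annotations = _require(document, "Annotations", list, "$")
    records: list[AnnotationRecord] = []
    for i, ann in enumerate(annotations):
        apath = f"$.Annotations[{i}]"
        source_name = _require(ann, "SourceName", str, apath)
        source_id = _require(ann, "SourceID", str, apath)
        name = _require(ann, "Name", str, apath)
        linked = _require(ann, "LinkedRecords", dict, apath)
        cids = _require(linked, "CID", list, apath + ".LinkedRecords")
        if len(cids) != 1 or not isinstance(cids[0], int) or isinstance(cids[0], bool) or cids[0] <= 0:
            raise AnnotationParseError(
                "LinkedRecords.CID must hold exactly one positive integer", apath
            )
        input_cid = cids[0]
        data = _require(ann, "Data", list, apath)
        excerpt_idx = 0
        for j, datum in enumerate(data):
            value = _require(datum, "Value", dict, f"{apath}.Data[{j}]")
            swm = _require(value, "StringWithMarkup", list, f"{apath}.Data[{j}].Value")
            for k, item in enumerate(swm):
                path = f"{apath}.Data[{j}].Value.StringWithMarkup[{k}]"
                excerpt = _require(item, "String", str, path)
                if not excerpt:
                    raise AnnotationParseError("excerpt string is empty", path)
                markup = item.get("Markup", [])
                if not isinstance(markup, list):
                    raise AnnotationParseError("Markup must be a list", path)
                spans = sorted(
                    (
                        _parse_markup(m, excerpt, f"{path}.Markup[{s}]")
                        for s, m in enumerate(markup)
                    ),
                    key=lambda sp: (sp.start, sp.length),
                )
                records.append(
                    AnnotationRecord(
                        input_cid=input_cid,
                        input_name=name,
                        source_name=source_name,
                        source_id=f"{source_id}/{excerpt_idx}",
                        excerpt=excerpt,
                        spans=tuple(spans),
                    )
                )
                excerpt_idx += 1
    return records


def flatten_candidates(
    records: list[AnnotationRecord], structure_index: StructureIndex
) -> list[CandidateRow]:
    """One :class:`CandidateRow` per span, with structures resolved locally.

    Missing CIDs are tolerated: the row is flagged unresolved, never
    dropped. Candidate keys are deterministic (:func:`candidate_id_for`);
    a key collision indicates two indistinguishable spans and raises.
    """
    rows: list[CandidateRow] = []
    seen: dict[str, str] = {}
    for rec in records:
        input_entry = structure_index.get(rec.input_cid)
        input_smiles = input_entry.structure.smiles if input_entry else None
        for span in rec.spans:
            matched_smiles = None
            if span.linked_cid is not None:
                entry = structure_index.get(span.linked_cid)
                if entry is not None:
                    matched_smiles = entry.structure.smiles
            cid = candidate_id_for(rec.input_cid, rec.source_id, span.start, span.linked_cid)
            if cid in seen:
                raise SpanValidationError(
                    f"candidate key collision: span {span.matched_text!r} in record "
                    f"{rec.source_id} duplicates {seen[cid]!r}"
                )
            seen[cid] = span.matched_text
            rows.append(
                CandidateRow(
                    candidate_id=cid,
                    input_cid=rec.input_cid,
                    input_name=rec.input_name,
                    input_smiles=input_smiles,
                    matched_name=span.matched_text,
                    matched_cid=span.linked_cid,
                    matched_smiles=matched_smiles,
                    resolved=matched_smiles is not None,
                    excerpt=rec.excerpt,
                    source_name=rec.source_name,
                    source_id=rec.source_id,
                )
            )
    return rows


def write_candidates_csv(rows: list[CandidateRow], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANDIDATE_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.candidate_id,
                    r.input_cid,
                    r.input_name,
                    "" if r.input_smiles is None else r.input_smiles,
                    r.matched_name,
                    "" if r.matched_cid is None else r.matched_cid,
                    "" if r.matched_smiles is None else r.matched_smiles,
                    "true" if r.resolved else "false",
                    r.excerpt,
                    r.source_name,
                    r.source_id,
                ]
            )


def read_candidates_csv(path: str | Path) -> list[CandidateRow]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CANDIDATE_COLUMNS:
            missing = [c for c in CANDIDATE_COLUMNS if c not in (header or [])]
            unknown = [c for c in (header or []) if c not in CANDIDATE_COLUMNS]
            raise SchemaError(
                f"candidates table {path}: missing={missing} unknown={unknown}",
                missing=missing,
                unknown=unknown,
            )
        rows = []
        for rec in reader:
            (cand_id, input_cid, input_name, input_smiles, matched_name,
             matched_cid, matched_smiles, resolved_flag, excerpt,
             source_name, source_id) = rec
            rows.append(
                CandidateRow(
                    candidate_id=cand_id,
                    input_cid=int(input_cid),
                    input_name=input_name,
                    input_smiles=input_smiles or None,
                    matched_name=matched_name,
                    matched_cid=int(matched_cid) if matched_cid else None,
                    matched_smiles=matched_smiles or None,
                    resolved=resolved_flag == "true",
                    excerpt=excerpt,
                    source_name=source_name,
                    source_id=source_id,
                )
            )
    return rows
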