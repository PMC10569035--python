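"""Canonical structure handling.

All structure comparisons in the pipeline go through this module: SMILES
canonicalization, InChIKey-based match semantics, desalting, and the
descriptors (Hill formula, monoisotopic mass) that suspect screening
depends on. RDKit does the chemistry; this module fixes the conventions.

Match levels
------------
``exact``
    Full 27-character InChIKey equality (connectivity + stereo + protonation).
``skeleton``
    Equality of the first InChIKey block (14 characters), i.e. the
    stereo-agnostic skeleton. Used to detect stereoisomer-only mismatches.
``desalted``
    Exact equality after stripping counter-ions / minor components and
    neutralizing the retained fragment on both sides.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import SaltStripError, SchemaError, StructureError

# RDKit logs every failed parse to stderr; failures are reported through
# StructureError instead.
RDLogger.DisableLog("rdApp.*")

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

MATCH_LEVELS = ("exact", "skeleton", "desalted")


@dataclass(frozen=True)
class StructureRef:
    """A canonicalized structure with the descriptors the pipeline needs.

    ``xlogp`` is the octanol-water partition coefficient as provided by the
    input table (a computed database value); it is never silently replaced
    by a local estimate — see :func:`estimate_logp`.
    """

    smiles: str
    inchikey: str
    formula: str
    monoisotopic_mass: float
    xlogp: float | None = None

    @property
    def skeleton(self) -> str:
        """First InChIKey block: the stereo-agnostic connectivity hash."""
        return self.inchikey[:14]

    def with_xlogp(self, xlogp: float | None) -> "StructureRef":
        return replace(self, xlogp=xlogp)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise StructureError("empty structure string", offending=smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}", offending=smiles)
    return mol


def canonicalize(smiles_in: str, xlogp: float | None = None) -> StructureRef:
    """Parse a SMILES string and return its canonical :class:`StructureRef`.

    Idempotent: ``canonicalize(canonicalize(x).smiles) == canonicalize(x)``
    up to the ``xlogp`` annotation, which is carried through unchanged.

    Raises
    ------
    StructureError
        If the input does not parse.
    """
    mol = _mol_from_smiles(smiles_in)
    smiles = Chem.MolToSmiles(mol)
    # descriptors are computed on the re-parsed canonical form so that the
    # result is bitwise independent of the input atom ordering
    mol = _mol_from_smiles(smiles)
    return StructureRef(
        smiles=smiles,
        inchikey=Chem.MolToInchiKey(mol),
        formula=rdMolDescriptors.CalcMolFormula(mol),
        monoisotopic_mass=Descriptors.ExactMolWt(mol),
        xlogp=xlogp,
    )


def estimate_logp(ref: StructureRef) -> float:
    """Crippen logP estimate, an explicitly-labeled fallback.

    Pipeline tables carry database-computed XlogP values; this local
    estimate exists only for callers that knowingly want a substitute and
    is never used implicitly.
    """
    return float(Crippen.MolLogP(_mol_from_smiles(ref.smiles)))


def _is_organic(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


_UNCHARGER = rdMolStandardize.Uncharger()


def strip_salt(ref: StructureRef) -> tuple[StructureRef, bool]:
    """Retain the largest organic component of a multi-component structure.

    Returns ``(stripped, flag)`` where ``flag`` is True iff components were
    removed. Single-component inputs come back unchanged (flag False).
    The retained fragment is neutralized (e.g. a carboxylate from a sodium
    salt becomes the free acid) so that desalted matching pairs a salt with
    its free form.

    Largest organic component: most heavy atoms among carbon-containing
    components; ties broken by larger monoisotopic mass, then by
    lexicographically smallest canonical SMILES.

    Raises
    ------
    SaltStripError
        If a multi-component input has no organic component.
    """
    mol = _mol_from_smiles(ref.smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return ref, False
    organic = [f for f in frags if _is_organic(f)]
    if not organic:
        raise SaltStripError(
            f"no organic component to retain in {ref.smiles!r}",
            offending=ref.smiles,
        )
    best = min(
        organic,
        key=lambda f: (
            -f.GetNumHeavyAtoms(),
            -Descriptors.ExactMolWt(f),
            Chem.MolToSmiles(f),
        ),
    )
    neutral = _UNCHARGER.uncharge(best)
    return canonicalize(Chem.MolToSmiles(neutral), xlogp=ref.xlogp), True


def structures_match(a: StructureRef, b: StructureRef, level: str = "exact") -> bool:
    """Compare two structures at the given match level.

    ``exact`` implies ``skeleton`` for every valid pair.
    """
    if level == "exact":
        return a.inchikey == b.inchikey
    if level == "skeleton":
        return a.skeleton == b.skeleton
    if level == "desalted":
        sa, _ = strip_salt(a)
        sb, _ = strip_salt(b)
        return sa.inchikey == sb.inchikey
    raise ValueError(f"unknown match level {level!r}; expected one of {MATCH_LEVELS}")


# ---------------------------------------------------------------------------
# Structure index: local CID -> structure lookup
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ["cid", "name", "smiles", "inchikey", "formula", "monoisotopic_mass", "xlogp"]


@dataclass(frozen=True)
class IndexEntry:
    cid: int
    name: str
    structure: StructureRef


class StructureIndex:
    """A local CID -> structure lookup table (replaces any live service).

    Backed by a plain CSV with columns ``cid, name, smiles, inchikey,
    formula, monoisotopic_mass, xlogp``. SMILES are re-canonicalized on
    load so the index always holds canonical forms; the stored inchikey,
    when present, is cross-checked.
    """

    def __init__(self, entries: dict[int, IndexEntry] | None = None):
        self._entries: dict[int, IndexEntry] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, cid: int) -> bool:
        return cid in self._entries

    def get(self, cid: int) -> IndexEntry | None:
        return self._entries.get(cid)

    def add(self, cid: int, name: str, structure: StructureRef) -> None:
        self._entries[cid] = IndexEntry(cid=cid, name=name, structure=structure)

    def cids(self) -> list[int]:
        return sorted(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StructureIndex":
        entries: dict[int, IndexEntry] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in INDEX_COLUMNS if c not in header]
            unknown = [c for c in header if c not in INDEX_COLUMNS]
            if missing or unknown:
                raise SchemaError(
                    f"structure index {path}: missing={missing} unknown={unknown}",
                    missing=missing,
                    unknown=unknown,
                )
            for row in reader:
                cid = int(row["cid"])
                xlogp = float(row["xlogp"]) if row["xlogp"] != "" else None
                ref = canonicalize(row["smiles"], xlogp=xlogp)
                if row["inchikey"] and row["inchikey"] != ref.inchikey:
                    raise StructureError(
                        f"structure index {path}: cid {cid} inchikey mismatch "
                        f"(stored {row['inchikey']}, computed {ref.inchikey})",
                        offending=row["smiles"],
                    )
                entries[cid] = IndexEntry(cid=cid, name=row["name"], structure=ref)
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(INDEX_COLUMNS)
            for cid in self.cids():
                e = self._entries[cid]
                s = e.structure
                writer.writerow(
                    [
                        e.cid,
                        e.name,
                        s.smiles,
                        s.inchikey,
                        s.formula,
                        f"{s.monoisotopic_mass:.6f}",
                        "" if s.xlogp is None else f"{s.xlogp:.2f}",
                    ]
                )
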