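"""Decision application, missing entries, reaction SMILES and validation."""

import logging

import pytest

from tpcurate.annotations import CandidateRow
from tpcurate.chem import StructureIndex, canonicalize
from tpcurate.curation import (
    DecisionRecord,
    MissingEntry,
    add_missing_entry,
    apply_decisions,
    assert_all_decided,
    make_reaction_smiles,
    read_decisions_csv,
    validate_reaction,
    write_decisions_csv,
)
from tpcurate.errors import CurationError, StructureError, UndecidedError

ACYCLOVIR = "Nc1nc2c(c(=O)[nH]1)ncn2COCCO"
ACYCLOVIR_MP = "Nc1nc2c(c(=O)[nH]1)ncn2COCCOP(=O)(O)O"
DICLOFENAC = "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"
ACECLOFENAC = "OC(=O)COC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"


def _candidate(cid="c1", input_smiles=ACYCLOVIR, matched_smiles=ACYCLOVIR_MP,
               input_name="acyclovir", matched_name="acyclovir monophosphate"):
    return CandidateRow(
        candidate_id=cid,
        input_cid=101,
        input_name=input_name,
        input_smiles=input_smiles,
        matched_name=matched_name,
        matched_cid=202 if matched_smiles else None,
        matched_smiles=matched_smiles,
        resolved=matched_smiles is not None,
        excerpt="Acyclovir is converted to acyclovir monophosphate",
        source_name="HSDB",
        source_id="hsdb/101/0",
    )


def test_product_verdict_orients_input_to_matched():
    cand = _candidate()
    reactions, ledger = apply_decisions(
        [cand], [DecisionRecord("c1", "product", biosystem="human")]
    )
    (r,) = reactions
    assert r.predecessor.name == "acyclovir"
    assert r.successor.name == "acyclovir monophosphate"
    assert r.biosystem == "human"
    assert ledger[0].status == "accepted_product"


def test_parent_verdict_reverses_orientation():
    cand = _candidate(
        input_smiles=DICLOFENAC, matched_smiles=ACECLOFENAC,
        input_name="diclofenac", matched_name="aceclofenac",
    )
    reactions, _ = apply_decisions([cand], [DecisionRecord("c1", "parent")])
    (r,) = reactions
    assert r.predecessor.name == "aceclofenac"
    assert r.successor.name == "diclofenac"


def test_reversing_a_verdict_exactly_swaps_the_sides():
    cand = _candidate()
    (as_product,), _ = apply_decisions([cand], [DecisionRecord("c1", "product", biosystem="rat")])
    (as_parent,), _ = apply_decisions([cand], [DecisionRecord("c1", "parent", biosystem="rat")])
    assert as_product.predecessor == as_parent.successor
    assert as_product.successor == as_parent.predecessor
    assert as_product.biosystem == as_parent.biosystem
    assert as_product.evidence_excerpt == as_parent.evidence_excerpt


def test_ledger_partitions_candidates():
    cands = [_candidate(cid=f"c{i}") for i in range(5)]
    decisions = [
        DecisionRecord("c0", "product"),
        DecisionRecord("c1", "parent"),
        DecisionRecord("c2", "reject"),
    ]
    reactions, ledger = apply_decisions(cands, decisions)
    statuses = [e.status for e in ledger]
    assert len(reactions) == 2
    assert statuses.count("rejected") == 1
    assert statuses.count("undecided") == 2
    assert len(reactions) + statuses.count("rejected") + statuses.count("undecided") == len(cands)


def test_fixture_decision_mixture_conserves_counts(annotation_fixture):
    from tpcurate.annotations import flatten_candidates, parse_annotation_json

    document, index, decisions, ledger = annotation_fixture
    candidates = flatten_candidates(parse_annotation_json(document), index)
    reactions, dec_ledger = apply_decisions(candidates, decisions)
    n_rej = sum(e.status == "rejected" for e in dec_ledger)
    n_und = sum(e.status == "undecided" for e in dec_ledger)
    assert len(reactions) == ledger.n_true_spans
    assert n_rej == ledger.distractor_spans + ledger.unresolved_spans
    assert n_und == 0
    assert len(reactions) + n_rej + n_und == len(candidates)


def test_unknown_candidate_id_raises():
    with pytest.raises(CurationError, match="unknown candidate_id"):
        apply_decisions([_candidate()], [DecisionRecord("nope", "product")])


def test_accepting_unresolved_candidate_points_to_missing_entry_path():
    cand = _candidate(matched_smiles=None)
    with pytest.raises(CurationError, match="missing-entry"):
        apply_decisions([cand], [DecisionRecord("c1", "product")])


def test_rejecting_unresolved_candidate_is_fine():
    cand = _candidate(matched_smiles=None)
    reactions, ledger = apply_decisions([cand], [DecisionRecord("c1", "reject")])
    assert reactions == []
    assert ledger[0].status == "rejected"


def test_duplicate_decisions_last_wins_with_warning(caplog):
    cand = _candidate()
    with caplog.at_level(logging.WARNING):
        reactions, _ = apply_decisions(
            [cand],
            [DecisionRecord("c1", "reject"), DecisionRecord("c1", "product")],
        )
    assert len(reactions) == 1
    assert "duplicate decision" in caplog.text


def test_undecided_blocks_finalize_unless_allowed():
    _, ledger = apply_decisions([_candidate()], [])
    with pytest.raises(UndecidedError) as exc:
        assert_all_decided(ledger)
    assert exc.value.undecided_ids == ["c1"]
    assert_all_decided(ledger, allow_undecided=True)


def _index():
    index = StructureIndex()
    index.add(101, "acyclovir", canonicalize(ACYCLOVIR))
    return index


def test_missing_entry_product_direction():
    entry = MissingEntry(
        input_cid=101,
        new_name="acyclovir diphosphate",
        new_smiles="Nc1nc2c(c(=O)[nH]1)ncn2COCCOP(=O)(O)OP(=O)(O)O",
        direction="product",
        biosystem="human",
    )
    r = add_missing_entry(entry, _index())
    assert r.predecessor.name == "acyclovir"
    assert r.successor.name == "acyclovir diphosphate"
    assert r.successor.cid is None  # new compound: no identifier yet
    assert r.predecessor.cid == 101


def test_missing_entry_parent_direction_is_symmetric():
    kwargs = dict(input_cid=101, new_name="x", new_smiles="CCO")
    prod = add_missing_entry(MissingEntry(direction="product", **kwargs), _index())
    par = add_missing_entry(MissingEntry(direction="parent", **kwargs), _index())
    assert prod.predecessor.structure == par.successor.structure
    assert prod.successor.structure == par.predecessor.structure


def test_missing_entry_invalid_structure_fails_before_record():
    entry = MissingEntry(input_cid=101, new_name="bad", new_smiles="xx$$", direction="product")
    with pytest.raises(StructureError):
        add_missing_entry(entry, _index())


def test_reaction_smiles_uses_canonical_forms():
    cand = _candidate(input_smiles="OCC", matched_smiles="OC(=O)C",
                      input_name="ethanol", matched_name="acetic acid")
    (r,), _ = apply_decisions([cand], [DecisionRecord("c1", "product")])
    assert make_reaction_smiles(r) == "CCO>>CC(=O)O"
    pred, succ = make_reaction_smiles(r).split(">>")
    assert pred == r.predecessor.structure.smiles
    assert succ == r.successor.structure.smiles


def _reaction(pred_smiles, succ_smiles, **meta):
    cand = _candidate(input_smiles=pred_smiles, matched_smiles=succ_smiles)
    (r,), _ = apply_decisions(
        [cand],
        [DecisionRecord("c1", "product", **meta)],
    )
    return r


def test_validation_flags_stereo_only_difference():
    r = _reaction("N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O", biosystem="human")
    assert validate_reaction(r) == ["stereo_only_difference"]


def test_validation_flags_identical_sides():
    r = _reaction("CCO", "OCC", biosystem="human")
    assert validate_reaction(r) == ["identical_sides"]


def test_validation_flags_salt_component():
    r = _reaction("CC(=O)[O-].[Na+]", "CCO", biosystem="human")
    assert validate_reaction(r) == ["salt_component"]


def test_validation_flags_missing_metadata():
    r = _reaction("CCO", "CC(=O)O")
    assert validate_reaction(r) == ["missing_metadata"]


def test_clean_reaction_has_no_issues():
    r = _reaction("CCO", "CC(=O)O", biosystem="human", transformation_type="oxidation")
    assert validate_reaction(r) == []


def test_decisions_csv_round_trip(tmp_path):
    decisions = [
        DecisionRecord("c1", "product", biosystem="human", enzyme="CYP3A4",
                       transformation_type="hydroxylation", note="ok"),
        DecisionRecord("c2", "reject", note="not a TP"),
    ]
    path = tmp_path / "decisions.csv"
    write_decisions_csv(decisions, path)
    assert read_decisions_csv(path) == decisions


def test_invalid_verdict_rejected():
    with pytest.raises(CurationError):
        DecisionRecord("c1", "maybe")
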