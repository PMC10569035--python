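"""Library I/O, pair uniqueness, dedup classification, merging, suspects."""

import random

import pytest

from tpcurate.chem import canonicalize
from tpcurate.curation import CompoundRef, ReactionRecord
from tpcurate.errors import MergePolicyError, SchemaError
from tpcurate.library import (
    LIBRARY_COLUMNS,
    TransformationsLibrary,
    count_unique_by_cid,
    dedup_classify,
    export_suspect_list,
    merge_reactions,
    pair_key,
    read_library,
    read_suspects_csv,
    write_library,
    write_suspects_csv,
)
from tpcurate import fixtures as fx


def _rxn(pred, succ, pred_cid=None, succ_cid=None, biosystem="human", enzyme=None,
         ttype="oxidation", source_id=""):
    return ReactionRecord(
        predecessor=CompoundRef("p", pred_cid, canonicalize(pred)),
        successor=CompoundRef("s", succ_cid, canonicalize(succ)),
        biosystem=biosystem,
        enzyme=enzyme,
        transformation_type=ttype,
        source_id=source_id,
    )


def test_library_round_trip(tmp_path, library_fixture):
    lib, _, _ = library_fixture
    path = tmp_path / "library.csv"
    write_library(lib, path)
    back = read_library(path)
    assert back.entries == lib.entries
    assert back.index == lib.index


def test_duplicate_pairs_both_retained_and_indexed():
    a = _rxn("CCO", "CC(=O)O", 1, 2, biosystem="human")
    b = _rxn("CCO", "CC(=O)O", 1, 2, biosystem="rat")
    lib = TransformationsLibrary([a, b])
    assert len(lib) == 2
    assert lib.index[pair_key(a)] == [0, 1]


def test_empty_library_file_round_trips(tmp_path):
    path = tmp_path / "empty.csv"
    write_library(TransformationsLibrary([]), path)
    assert len(read_library(path)) == 0


def test_schema_mismatch_lists_columns(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(",".join(LIBRARY_COLUMNS[:-1]) + ",bogus\n", encoding="utf-8")
    with pytest.raises(SchemaError) as exc:
        read_library(path)
    assert "reaction_smiles" in exc.value.missing
    assert "bogus" in exc.value.unknown


def test_count_unique_by_cid_against_bruteforce():
    rng = random.Random(3)
    smiles = ["CCO", "CC(=O)O", "CCCO", "CCC(=O)O", "CCN"]
    entries = []
    for _ in range(10):
        i, j = rng.sample(range(5), 2)
        entries.append(_rxn(smiles[i], smiles[j], pred_cid=i + 1, succ_cid=j + 1))
    lib = TransformationsLibrary(entries)
    brute = len({(r.predecessor.cid, r.successor.cid) for r in entries})
    assert count_unique_by_cid(lib) == brute


def test_cidless_entries_counted_by_inchikey_pair():
    with_cid = _rxn("CCO", "CC(=O)O", 1, 2)
    without_cid = _rxn("CCO", "CC(=O)O")
    lib = TransformationsLibrary([with_cid, without_cid])
    # same structures, but one is CID-keyed and one InChIKey-keyed
    assert count_unique_by_cid(lib) == 2
    assert count_unique_by_cid(TransformationsLibrary([without_cid, without_cid])) == 1


def test_empty_library_counts_zero():
    assert count_unique_by_cid(TransformationsLibrary([])) == 0


def test_dedup_against_empty_library_is_all_novel(library_fixture):
    _, candidates, _ = library_fixture
    report = dedup_classify(candidates, TransformationsLibrary([]))
    assert report.counts == {
        "novel": len(candidates),
        "exact_duplicate": 0,
        "metadata_variant": 0,
    }


def test_dedup_of_library_against_itself_has_no_novel(library_fixture):
    lib, _, _ = library_fixture
    report = dedup_classify(lib.entries, lib)
    assert report.counts["novel"] == 0
    assert report.counts["metadata_variant"] == 0
    assert report.counts["exact_duplicate"] == len(lib)


def test_dedup_recovers_planted_classes(library_fixture):
    lib, candidates, ledger = library_fixture
    report = dedup_classify(candidates, lib)
    assert report.counts == ledger.planted_dedup_classes == {
        "novel": 20,
        "exact_duplicate": 3,
        "metadata_variant": 2,
    }
    assert report.total == len(candidates)


def test_metadata_comparison_normalizes_case_and_whitespace():
    in_lib = _rxn("CCO", "CC(=O)O", biosystem="  Human ", ttype="Oxidation")
    incoming = _rxn("CCO", "CC(=O)O", biosystem="human", ttype="oxidation")
    report = dedup_classify([incoming], TransformationsLibrary([in_lib]))
    assert report.counts["exact_duplicate"] == 1


def test_evidence_only_difference_is_exact_duplicate():
    in_lib = _rxn("CCO", "CC(=O)O", source_id="a")
    incoming = ReactionRecord(
        predecessor=in_lib.predecessor,
        successor=in_lib.successor,
        biosystem=in_lib.biosystem,
        enzyme=in_lib.enzyme,
        transformation_type=in_lib.transformation_type,
        evidence_excerpt="a different excerpt entirely",
        source_id="b",
    )
    report = dedup_classify([incoming], TransformationsLibrary([in_lib]))
    assert report.counts["exact_duplicate"] == 1


def test_merge_adds_only_novel_pairs(library_fixture):
    lib, candidates, _ = library_fixture
    before = count_unique_by_cid(lib)
    merged = merge_reactions(lib, candidates, policy="novel_only")
    report = dedup_classify(candidates, lib)
    assert len(merged) == len(lib) + len(report.novel)
    novel_pairs = {pair_key(r) for r in report.novel} - set(lib.index)
    assert count_unique_by_cid(merged) == before + len(novel_pairs)


def test_merge_is_idempotent(library_fixture):
    lib, candidates, _ = library_fixture
    once = merge_reactions(lib, candidates, policy="novel_plus_variants")
    twice = merge_reactions(once, candidates, policy="novel_plus_variants")
    assert twice.entries == once.entries


def test_merge_order_insensitive_on_unique_pairs():
    cat = fx.catalog()
    rng = random.Random(9)
    templates = rng.sample(cat.templates, 30)
    set_a = [cat.reaction(t, biosystem="human") for t in templates[:15]]
    set_b = [cat.reaction(t, biosystem="soil") for t in templates[15:]]
    base = TransformationsLibrary([])
    ab = merge_reactions(merge_reactions(base, set_a), set_b)
    ba = merge_reactions(merge_reactions(base, set_b), set_a)
    assert set(ab.index) == set(ba.index)


def test_unknown_merge_policy_errors(library_fixture):
    lib, candidates, _ = library_fixture
    with pytest.raises(MergePolicyError):
        merge_reactions(lib, candidates, policy="everything")


def test_suspect_entry_merges_parents_of_shared_tp():
    cat = fx.catalog()
    terb = cat.by_key["named:terbuthylazine"]
    terbutryn = cat.by_key["named:terbutryn"]
    tp = cat.by_key["named:terbuthylazine-2-hydroxy"]
    lib = TransformationsLibrary(
        [
            _rxn(terb.ref.smiles, tp.ref.smiles, terb.cid, tp.cid),
            _rxn(terbutryn.ref.smiles, tp.ref.smiles, terbutryn.cid, tp.cid),
        ]
    )
    suspects = export_suspect_list(lib)
    assert len(suspects) == 1
    assert set(suspects[0].predecessor_inchikeys) == {
        terb.ref.inchikey,
        terbutryn.ref.inchikey,
    }


def test_suspect_list_unique_and_sorted(library_fixture):
    lib, _, _ = library_fixture
    suspects = export_suspect_list(lib)
    keys = [s.inchikey for s in suspects]
    assert len(keys) == len(set(keys))
    assert keys == sorted(keys)
    brute_distinct = {r.successor.structure.inchikey for r in lib.entries}
    assert len(suspects) == len(brute_distinct)


def test_suspect_mass_recomputed_from_structure():
    lib = TransformationsLibrary([_rxn("CCO", "NCC(=O)O", 1, 2)])
    (entry,) = export_suspect_list(lib)
    assert entry.monoisotopic_mass == pytest.approx(75.0320, abs=1e-3)


def test_export_empty_library_is_empty():
    assert export_suspect_list(TransformationsLibrary([])) == []


def test_suspects_csv_round_trip(tmp_path, library_fixture):
    lib, _, _ = library_fixture
    suspects = export_suspect_list(lib)
    path = tmp_path / "suspects.csv"
    write_suspects_csv(suspects, path)
    back = read_suspects_csv(path)
    assert [s.inchikey for s in back] == [s.inchikey for s in suspects]
    assert [s.predecessor_inchikeys for s in back] == [
        s.predecessor_inchikeys for s in suspects
    ]
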