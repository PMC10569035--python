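"""TP labeling, parent-TP linkage, and the paired XlogP comparison."""

from itertools import product as iproduct

import numpy as np
import pytest

from tpcurate.errors import ScreeningError
from tpcurate.library import SuspectEntry
from tpcurate.screening import (
    IdentifiedCompound,
    ParentTPPair,
    label_tps,
    link_parent_pairs,
    xlogp_compare,
)
from tpcurate import fixtures as fx

IK_A = "AAAAAAAAAAAAAA-AAAAAAAAAA-N"
IK_B = "BBBBBBBBBBBBBB-BBBBBBBBBB-N"


def _suspect(inchikey, preds=(), name="tp"):
    return SuspectEntry(
        name=name,
        smiles="CCO",
        inchikey=inchikey,
        formula="C2H6O",
        monoisotopic_mass=46.0419,
        predecessor_inchikeys=tuple(preds),
    )


def _compound(inchikey, name="c", xlogp=None):
    return IdentifiedCompound(name=name, inchikey=inchikey, xlogp=xlogp)


def test_empty_suspect_list_labels_nothing():
    labeled = label_tps([_compound(IK_A)], [])
    assert [lc.is_tp for lc in labeled] == [False]


def test_label_conservation_and_fixture_counts(screening_fixture):
    identified, suspects, ledger = screening_fixture
    labeled = label_tps(identified, suspects, level="exact")
    assert len(labeled) == len(identified)  # nothing dropped
    assert sum(lc.is_tp for lc in labeled) == ledger.planted_tp == 72


def test_stereoisomer_matches_only_at_skeleton_level():
    suspect = _suspect("QNAYBMKLOCPYGJ-REOHCLBHSA-N")  # L-alanine
    d_ala = _compound("QNAYBMKLOCPYGJ-UWTATZPHSA-N")  # D-alanine
    assert not label_tps([d_ala], [suspect], level="exact")[0].is_tp
    assert label_tps([d_ala], [suspect], level="skeleton")[0].is_tp


def test_tp_with_two_identified_parents_yields_two_pairs():
    cat = fx.catalog()
    terb = cat.by_key["named:terbuthylazine"].ref
    terbutryn = cat.by_key["named:terbutryn"].ref
    tp = cat.by_key["named:terbuthylazine-2-hydroxy"].ref
    suspect = _suspect(tp.inchikey, preds=[terb.inchikey, terbutryn.inchikey])
    compounds = [
        _compound(terb.inchikey, "terbuthylazine", 3.2),
        _compound(terbutryn.inchikey, "terbutryn", 3.7),
        _compound(tp.inchikey, "terbuthylazine-2-hydroxy", 2.1),
    ]
    labeled = label_tps(compounds, [suspect])
    pairs, orphans = link_parent_pairs(labeled)
    assert len(pairs) == 2
    assert {p.parent.name for p in pairs} == {"terbuthylazine", "terbutryn"}
    assert orphans == []


def test_tp_without_identified_parent_is_orphan():
    suspect = _suspect(IK_A, preds=[IK_B])
    labeled = label_tps([_compound(IK_A, "lonely tp")], [suspect])
    pairs, orphans = link_parent_pairs(labeled)
    assert pairs == []
    assert [o.name for o in orphans] == ["lonely tp"]


def test_self_pairs_are_excluded():
    # the TP's suspect entry lists the TP itself as a predecessor
    suspect = _suspect(IK_A, preds=[IK_A])
    labeled = label_tps([_compound(IK_A)], [suspect])
    pairs, orphans = link_parent_pairs(labeled)
    assert pairs == []
    assert len(orphans) == 1


def test_fixture_pairs_and_orphans_recovered(screening_fixture):
    identified, suspects, ledger = screening_fixture
    labeled = label_tps(identified, suspects)
    pairs, orphans = link_parent_pairs(labeled)
    assert len(pairs) == ledger.planted_pairs == 36
    assert len(orphans) == ledger.planted_orphans == 36
    # every TP label lands in exactly one of {a pair's tp slot, orphans}
    tp_iks = {lc.compound.inchikey for lc in labeled if lc.is_tp}
    pair_tp_iks = {p.tp.inchikey for p in pairs}
    orphan_iks = {o.inchikey for o in orphans}
    assert pair_tp_iks | orphan_iks == tp_iks
    assert pair_tp_iks & orphan_iks == set()


def _pairs_from_xlogp(parent_vals, tp_vals):
    out = []
    for i, (pv, tv) in enumerate(zip(parent_vals, tp_vals)):
        out.append(
            ParentTPPair(
                parent=_compound(IK_A, f"p{i}", pv),
                tp=_compound(IK_B, f"t{i}", tv),
                via=(IK_A,),
            )
        )
    return out


def brute_force_signed_rank_p(diffs):
    """Exact one-sided p by enumerating all 2^n sign assignments.

    Independent oracle for the Wilcoxon signed-rank null: every sign
    pattern of |d| is equally likely under H0; p = P(W+ <= observed).
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    # midranks for ties
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 0
    for signs in iproduct((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if w <= w_obs:
            count += 1
    return count / total


def test_exact_p_for_five_uniform_sign_pairs():
    parent = [1.0, 2.0, 3.0, 4.0, 5.0]
    tp = [0.5, 1.0, 1.5, 2.0, 2.5]  # every TP strictly below its parent
    comp = xlogp_compare(_pairs_from_xlogp(parent, tp), density_points=0)
    oracle = brute_force_signed_rank_p(np.array(tp) - np.array(parent))
    assert oracle == pytest.approx(1 / 32)
    assert comp.p_one_sided == pytest.approx(1 / 32)
    assert comp.method == "exact"


def test_exact_p_matches_enumeration_with_mixed_signs():
    rng = np.random.default_rng(4)
    parent = rng.normal(2.5, 1.0, size=9)
    tp = parent - 0.4 + rng.normal(0, 0.8, size=9)
    comp = xlogp_compare(_pairs_from_xlogp(parent, tp), density_points=0)
    oracle = brute_force_signed_rank_p(tp - parent)
    assert comp.p_one_sided == pytest.approx(oracle, rel=1e-9)


def test_all_zero_differences_is_an_error():
    pairs = _pairs_from_xlogp([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ScreeningError):
        xlogp_compare(pairs)


def test_no_usable_pairs_is_an_error():
    pairs = _pairs_from_xlogp([None, None], [1.0, None])
    with pytest.raises(ScreeningError):
        xlogp_compare(pairs)


def test_pairs_missing_xlogp_are_excluded_and_counted():
    pairs = _pairs_from_xlogp([1.0, 2.0, None, 3.0], [0.5, 1.0, 1.0, None])
    comp = xlogp_compare(pairs, density_points=0)
    assert comp.n_pairs == 4
    assert comp.n_excluded_missing == 2
    assert comp.n_used == 2


def test_planted_shift_detected_on_fixture(screening_fixture):
    identified, suspects, _ = screening_fixture
    labeled = label_tps(identified, suspects)
    pairs, _ = link_parent_pairs(labeled)
    comp = xlogp_compare(pairs)
    assert comp.n_used > 30
    assert comp.p_one_sided < 0.05
    assert comp.median_tp_xlogp < comp.median_parent_xlogp
    assert comp.method == "approx"
    assert len(comp.density_grid) == len(comp.parent_density) == len(comp.tp_density) > 0


def test_malformed_inchikey_rejected():
    with pytest.raises(ValueError):
        IdentifiedCompound(name="x", inchikey="not-a-key")
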