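"""Consensus ATC classification: per-method ranking, the consensus rule and
the leave-one-out evaluation harness."""

import pytest

from chempred.atc_classifier import (
    ConsensusConfig,
    MethodRanking,
    ReferenceLibrary,
    classify,
    consensus_from_rankings,
    evaluate_prediction_rate,
    rank_by_method,
    truncate_atc,
)


def _ranking(method, cls, top, second_cls="X99XX99"):
    return MethodRanking(
        method=method,
        ranked=[("id_top", top), ("id_2", top * 0.5)],
        predicted_class=cls,
        top_score=top,
    )


@pytest.fixture(scope="module")
def tiny_library(atc_fixture):
    # 2 series x 3 members, with conformers, for end-to-end classify calls
    labeled = atc_fixture.labeled[:3] + atc_fixture.labeled[10:13]
    cfg = ConsensusConfig(max_conformers=3, atc_level=1)
    return ReferenceLibrary.build(labeled, config=cfg)


def test_library_validates_codes_and_duplicates(mk_compound):
    comp = mk_compound("c1ccccc1")
    with pytest.raises(ValueError, match="invalid ATC"):
        ReferenceLibrary.build([(comp, ["NOPE"])], with_conformers=False)
    with pytest.raises(ValueError, match="no ATC code"):
        ReferenceLibrary.build([(comp, [])], with_conformers=False)
    with pytest.raises(ValueError, match="duplicate"):
        ReferenceLibrary.build(
            [(comp, ["N02AA01"]), (mk_compound("c1ccccc1", "x"), ["C01AA01"])],
            with_conformers=False,
        )


def test_atc_truncation_levels():
    assert truncate_atc("N02BE01", 1) == "N"
    assert truncate_atc("N02BE01", 2) == "N02"
    assert truncate_atc("N02BE01", 5) == "N02BE01"


def test_query_identical_to_library_drug_tops_every_method(tiny_library):
    query = tiny_library.entries[0].compound
    for method in ("2d", "fragment", "3d"):
        ranking = rank_by_method(query, tiny_library, method)
        assert ranking.ranked[0][0] == query.canonical_id
        assert ranking.top_score == pytest.approx(1.0)


def test_empty_library_is_an_error(mk_compound):
    lib = ReferenceLibrary(entries=[])
    with pytest.raises(ValueError, match="empty"):
        rank_by_method(mk_compound("CCO"), lib, "2d")


def test_consensus_unanimity():
    cfg = ConsensusConfig()
    rankings = {
        "2d": _ranking("2d", "N02", 0.9),
        "fragment": _ranking("fragment", "N02", 0.8),
        "3d": _ranking("3d", "N02", 0.7),
    }
    res = consensus_from_rankings(rankings, cfg)
    assert res.predicted_class == "N02"
    assert res.decision_path == "three_agree"
    assert res.consensus_score == pytest.approx((0.9 + 0.8 + 0.7) / 3)


def test_consensus_majority_of_two():
    cfg = ConsensusConfig()
    rankings = {
        "2d": _ranking("2d", "N02", 0.9),
        "fragment": _ranking("fragment", "N02", 0.6),
        "3d": _ranking("3d", "C01", 0.95),
    }
    res = consensus_from_rankings(rankings, cfg)
    assert res.predicted_class == "N02"
    assert res.decision_path == "two_agree"
    assert res.consensus_score == pytest.approx((0.9 + 0.6) / 2)


def test_consensus_threshold_tiebreak_picks_largest_margin():
    cfg = ConsensusConfig()  # thresholds 0.45 / 0.45 / 0.30
    rankings = {
        "2d": _ranking("2d", "N02", 0.60),     # margin 0.15
        "fragment": _ranking("fragment", "C01", 0.40),  # below threshold
        "3d": _ranking("3d", "J05", 0.42),     # margin 0.12
    }
    res = consensus_from_rankings(rankings, cfg)
    assert res.predicted_class == "N02"
    assert res.decision_path == "threshold_tiebreak"
    assert res.consensus_score == pytest.approx(0.60)


def test_consensus_no_method_above_threshold_is_unclassified():
    cfg = ConsensusConfig()
    rankings = {
        "2d": _ranking("2d", "N02", 0.30),
        "fragment": _ranking("fragment", "C01", 0.20),
        "3d": _ranking("3d", "J05", 0.10),
    }
    res = consensus_from_rankings(rankings, cfg)
    assert res.predicted_class == "unclassified"
    assert res.decision_path == "no_prediction"
    assert res.consensus_score == 0.0


def test_classify_deterministic_and_self_consistent(tiny_library):
    query = tiny_library.entries[4].compound
    first = classify(query, tiny_library)
    second = classify(query, tiny_library)
    assert first.predicted_class == second.predicted_class
    assert first.consensus_score == second.consensus_score
    # all three methods rank the identical compound first -> unanimity
    assert first.decision_path == "three_agree"
    assert first.predicted_class == truncate_atc(
        tiny_library.entries[4].atc_codes[0], tiny_library.config.atc_level
    )


def test_leave_one_out_requires_two_entries(tiny_library):
    single = ReferenceLibrary(
        entries=tiny_library.entries[:1],
        fingerprints=tiny_library.fingerprints,
        fragment_sets=tiny_library.fragment_sets,
        conformers=tiny_library.conformers,
        config=tiny_library.config,
    )
    with pytest.raises(ValueError):
        evaluate_prediction_rate(single)


def test_external_mode_rejects_unlabeled_queries(tiny_library, mk_compound):
    with pytest.raises(ValueError, match="unlabeled"):
        evaluate_prediction_rate(
            tiny_library, mode="external",
            external_queries=[(mk_compound("CCO"), [])],
        )


def test_rank1_stays_within_query_series_for_2d(atc_fixture):
    """The fixture guarantees within-series similarity dominates, so the 2D
    nearest neighbour of each member is another member of its own series."""
    lib = atc_fixture.library
    by_series = {e.compound.canonical_id: e.atc_codes[0] for e in lib.entries}
    for entry in lib.entries[::5]:
        ranking = rank_by_method(entry.compound, lib, "2d")
        # skip rank 1 = self, check the best non-self neighbour
        non_self = [r for r in ranking.ranked if r[0] != entry.compound.canonical_id]
        assert by_series[non_self[0][0]] == entry.atc_codes[0]


def test_loo_report_shapes_and_monotone_recall(atc_fixture, consensus_config):
    report = evaluate_prediction_rate(
        atc_fixture.library, atc_level=1, config=consensus_config
    )
    assert report.n_queries == len(atc_fixture.labeled)
    assert len(report.bin_table) == 10
    hits = sum(h for _, h, _, _ in report.bin_table)
    misses = sum(m for _, _, m, _ in report.bin_table)
    assert hits + misses == report.n_queries
    assert all(
        report.recall_at_k[i] <= report.recall_at_k[i + 1]
        for i in range(len(report.recall_at_k) - 1)
    )
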