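"""Target-set curation and the raw-score / Z-score / λ / E-value statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chempred.compound_model import RawCompound
from chempred.fingerprints import Fingerprint
from chempred.target_predictor import (
    BackgroundModel,
    CalibrationError,
    CurationConfig,
    InteractionRecord,
    PredictionConfig,
    TargetSet,
    build_target_set,
    calibrate_background,
    curate,
    e_value,
    lambda_weight,
    predict_targets,
    raw_score,
    z_score,
)


def _record(cid, smiles, target, btype="Ki", affinity=100.0):
    return InteractionRecord(
        compound=RawCompound(source_id=cid, structure=smiles),
        target_id=target,
        binding_type=btype,
        affinity_nM=affinity,
    )


_LIGS = ["CCO", "CCN", "CCC", "CCF", "CCCl", "CCBr"]


def test_curate_drops_target_below_min_ligands():
    records = [_record(f"c{i}", smi, "T1") for i, smi in enumerate(_LIGS[:4])]
    records += [
        _record("w1", "CCCC", "T1", affinity=50_000),
        _record("w2", "CCCCC", "T1", affinity=50_000),
    ]
    result = curate(records)
    assert result.targets == []
    reasons = {(r.compound_id, r.reason) for r in result.rejects}
    assert ("w1", "affinity") in reasons and ("w2", "affinity") in reasons
    assert sum(1 for r in result.rejects if r.reason == "target_too_small") == 4


def test_curate_keeps_five_distinct_ligands_and_counts_pairs():
    records = [_record(f"c{i}", smi, "T1") for i, smi in enumerate(_LIGS[:5])]
    result = curate(records)
    assert len(result.targets) == 1
    target = result.targets[0]
    assert target.n_ligands == 5
    assert target.n_self_pairs == 10
    assert result.rejects == []


def test_curate_filters_disallowed_binding_type_and_merges_duplicates():
    records = [_record(f"c{i}", smi, "T1") for i, smi in enumerate(_LIGS[:5])]
    records.append(_record("e1", "CCCC", "T1", btype="EC50"))
    records.append(_record("dup", "OCC", "T1"))  # same InChI as CCO
    result = curate(records)
    assert [r.reason for r in result.rejects] == ["binding_type"]
    assert result.targets[0].n_ligands == 5  # duplicate merged, not added


def _toy_target(bits_list, threshold=0.45):
    fps = [Fingerprint("circular_d4", frozenset(b)) for b in bits_list]
    from chempred.target_predictor import _self_similarity

    self_raw, n_pairs = _self_similarity(fps, threshold)
    return TargetSet(
        target_id="TOY",
        ligands=[],
        fingerprints=fps,
        n_ligands=len(fps),
        self_raw_score=self_raw,
        n_self_pairs=n_pairs,
        lambda_weight=lambda_weight(self_raw, n_pairs) if n_pairs else 1.0,
    )


def test_raw_score_thresholded_sum():
    base = frozenset(range(10))
    # similarities to the query (= base): 0.9, 0.5, 0.4
    target = _toy_target([set(list(base)[:9]), set(list(base)[:5]), set(list(base)[:4])])
    query = Fingerprint("circular_d4", base)
    raw, n = raw_score(query, target)
    assert raw == pytest.approx(1.4)
    assert n == 2
    none_above = _toy_target([{100, 101}, {102, 103}])
    assert raw_score(query, none_above) == (0.0, 0)


def test_z_score_closed_forms():
    bg = BackgroundModel(mu=0.2, sigma=0.1, n_samples=1000, seed=0)

    def target_of_size(n):
        t = _toy_target([frozenset({i}) for i in range(2)])
        t.n_ligands = n
        return t

    # raw/N == mu -> Z = 0 for any N
    assert z_score(0.2 * 7, target_of_size(7), bg) == pytest.approx(0.0)
    # raw/N = mu + sigma, N = 1 -> Z = 1
    assert z_score(0.3, target_of_size(1), bg) == pytest.approx(1.0)
    # raw/N = mu + sigma, N = 32 -> Z = 32^0.335
    assert z_score(0.3 * 32, target_of_size(32), bg) == pytest.approx(32 ** 0.335)


def test_lambda_weight_forms_and_stated_range():
    # perfectly uniform set: every pairwise similarity 1.0
    assert lambda_weight(10.0, 10, "stated_range") == pytest.approx(1.0)
    assert lambda_weight(10.0, 10, "printed") == pytest.approx(1.0)
    # very diverse set: mean above-threshold similarity 0.001
    assert lambda_weight(0.001 * 10, 10, "stated_range") == pytest.approx(
        1000 ** 0.335
    )
    assert lambda_weight(0.001 * 10, 10, "printed") == pytest.approx(0.001 ** 0.335)
    # zero within-set similarity: clamped with a warning
    assert lambda_weight(0.0, 10, "stated_range") == 100.0


def test_e_value_closed_forms_and_scaling():
    assert e_value(0.0, 1) == pytest.approx(1.0)
    assert e_value(math.log(221), 221) == pytest.approx(1.0)
    assert e_value(50.0, 10) < 1e-18
    assert e_value(2.0, 10) == pytest.approx(2 * e_value(2.0, 5))


@settings(deadline=None, max_examples=100)
@given(
    z=st.floats(-5, 20),
    dz=st.floats(0.01, 5),
    n=st.integers(1, 10_000),
)
def test_e_value_strictly_decreasing_in_z(z, dz, n):
    assert e_value(z + dz, n) < e_value(z, n)


def test_raw_score_monotone_under_ligand_addition():
    base = frozenset(range(10))
    query = Fingerprint("circular_d4", base)
    small = _toy_target([set(list(base)[:9])])
    bigger = _toy_target([set(list(base)[:9]), set(list(base)[:6])])  # sim 0.6
    assert raw_score(query, bigger)[0] > raw_score(query, small)[0]


def test_duplicating_ligands_scales_size_correction():
    bg = BackgroundModel(mu=0.0, sigma=0.1, n_samples=1000, seed=0)
    t1 = _toy_target([frozenset({i}) for i in range(3)])
    t2 = _toy_target([frozenset({i}) for i in range(3)])
    t2.n_ligands = t1.n_ligands * 4  # 4-fold duplication
    z1 = z_score(0.5 * t1.n_ligands, t1, bg)
    z2 = z_score(0.5 * t2.n_ligands, t2, bg)
    assert z2 / z1 == pytest.approx(4 ** 0.335)


def test_calibration_validates_decoy_count_and_disjointness(curation, target_fixture):
    with pytest.raises(CalibrationError, match="100 decoys"):
        calibrate_background(curation.targets, target_fixture.decoys[:50], seed=0)
    poisoned = target_fixture.decoys[:-1] + [curation.targets[0].ligands[0]]
    with pytest.raises(CalibrationError, match="disjoint"):
        calibrate_background(curation.targets, poisoned, seed=0)


def test_calibration_deterministic_and_finite(curation, target_fixture, background):
    again = calibrate_background(curation.targets, target_fixture.decoys, seed=1)
    assert (again.mu, again.sigma) == (background.mu, background.sigma)
    assert background.sigma > 0
    assert background.n_samples == len(target_fixture.decoys) * len(curation.targets)


def test_calibration_rejects_all_zero_background(curation):
    from chempred.compound_model import standardize

    # decoys from a chemistry alien to every target scaffold -> all raw 0
    decoys = [
        standardize(RawCompound(f"d{i}", "C" * (i % 5 + 1) + "O"))
        for i in range(120)
    ]
    decoys = [d for i, d in enumerate(decoys)]
    # pad with distinct simple chains to reach >= 100 distinct structures
    from chempred.compound_model import deduplicate

    extra = [
        standardize(RawCompound(f"x{i}", "C" * (i + 1)))
        for i in range(1, 110)
    ]
    pool = deduplicate(decoys + extra)[:110]
    with pytest.raises(CalibrationError, match="σ = 0"):
        calibrate_background(curation.targets, pool, seed=0)


def test_predict_targets_planted_identity(curation, background):
    # a ligand of exactly one uniform target set must rank that target first
    target = curation.targets[0]
    query = target.ligands[0]
    preds = predict_targets(query, curation.targets, background)
    assert preds[0].target_id == target.target_id
    assert preds[0].e_value < 1.0


def test_predict_targets_dissimilar_query_yields_nothing(curation, background, mk_compound):
    preds = predict_targets(mk_compound("CCO"), curation.targets, background)
    assert preds == []


def test_predict_targets_requires_targets(background, mk_compound):
    with pytest.raises(ValueError):
        predict_targets(mk_compound("CCO"), [], background)


def test_lambda_ordering_uniform_below_diverse(curation, target_fixture):
    levels = dict(zip(
        sorted(t.target_id for t in curation.targets),
        ("uniform",) * 6 + ("medium",) * 2 + ("diverse",) * 2,
    ))
    lam = {t.target_id: t.lambda_weight for t in curation.targets}
    uniform = [lam[t] for t, lvl in levels.items() if lvl == "uniform"]
    diverse = [lam[t] for t, lvl in levels.items() if lvl == "diverse"]
    assert max(uniform) < min(diverse)
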