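"""Statistical ligand-based target prediction.

A protein target is represented by its *target set*: the standardized,
deduplicated ligands with measured binding (IC50/Ki/KD at or under
10 000 nM; at least five distinct ligands).  A query compound is scored
against target set A by the thresholded-Tanimoto raw score

    raw_A = Σ  T(query, ligand)   over ligands with T >= 0.45,

normalized by the ligand count N_A and converted to a background-calibrated,
size-corrected Z-score

    Z_A = ((raw_A / N_A) - μ) * N_A^0.335 / σ,

where μ and σ describe the random background of the database, estimated by
scoring decoy compounds against every target set.  Because chemically
diverse target sets produce inflated Z-scores, a per-target diversity weight
λ_A derived from the within-set pairwise similarity rescales Z before
ranking, and an E-value (expected number of equally good hits by chance,
E = n_targets * exp(-Z)) flags predictions indistinguishable from noise
(E > 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .compound_model import (
    RawCompound,
    StandardizationConfig,
    StandardizedCompound,
    deduplicate,
    standardize,
)
from .fingerprints import Fingerprint, fingerprint, tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "TargetSet",
    "BackgroundModel",
    "TargetPrediction",
    "CurationConfig",
    "CurationResult",
    "PredictionConfig",
    "build_target_set",
    "RejectedRecord",
    "CalibrationError",
    "curate",
    "raw_score",
    "calibrate_background",
    "z_score",
    "lambda_weight",
    "e_value",
    "predict_targets",
    "SIZE_EXPONENT",
]

SIZE_EXPONENT = 0.335
DEFAULT_SIMILARITY_THRESHOLD = 0.45
DEFAULT_AFFINITY_MAX_NM = 10_000.0
DEFAULT_MIN_LIGANDS = 5
DEFAULT_BINDING_TYPES = frozenset({"IC50", "KI", "KD"})
_LAMBDA_CLAMP = (1.0, 100.0)


class CalibrationError(RuntimeError):
    """Background calibration could not produce a usable (μ, σ)."""


@dataclass(frozen=True)
class InteractionRecord:
    compound: RawCompound
    target_id: str
    binding_type: str
    affinity_nM: float | None


@dataclass
class TargetSet:
    """One target's curated ligand collection plus its diversity statistics."""

    target_id: str
    ligands: list[StandardizedCompound]
    fingerprints: list[Fingerprint]
    n_ligands: int
    self_raw_score: float  # sum of within-set pairwise Tanimoto >= threshold
    n_self_pairs: int      # unordered distinct ligand pairs
    lambda_weight: float


@dataclass(frozen=True)
class BackgroundModel:
    mu: float
    sigma: float
    n_samples: int
    seed: int


@dataclass(frozen=True)
class TargetPrediction:
    target_id: str
    raw_score: float
    z_score: float
    weighted_z: float
    e_value: float
    n_contributing: int


@dataclass(frozen=True)
class CurationConfig:
    binding_types: frozenset = DEFAULT_BINDING_TYPES
    affinity_max_nM: float = DEFAULT_AFFINITY_MAX_NM
    min_ligands: int = DEFAULT_MIN_LIGANDS
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    lambda_form: str = "stated_range"  # or "printed"
    fingerprint_kind: str = "circular_d4"
    standardization: StandardizationConfig = field(
        default_factory=StandardizationConfig
    )


@dataclass(frozen=True)
class RejectedRecord:
    compound_id: str
    target_id: str
    reason: str  # binding_type | affinity | parse_error | target_too_small


@dataclass
class CurationResult:
    targets: list[TargetSet]
    rejects: list[RejectedRecord]


def lambda_weight(
    self_raw_score: float, n_self_pairs: int, form: str = "stated_range"
) -> float:
    """Diversity weight of a target set from its within-set similarity.

    ``stated_range`` (default): λ = (N_AA / raw_AA)^0.335 clamped to
    [1, 100] — close to 1 for uniform sets, growing past 10 for very
    diverse ones.  ``printed``: λ = (raw_AA / N_AA)^0.335, the literal
    inverse form, kept selectable for comparison (it maps diverse sets
    to values *below* 1).
    """
    if n_self_pairs < 1:
        raise ValueError("lambda_weight requires at least one ligand pair")
    if form == "stated_range":
        if self_raw_score <= 0:
            logger.warning(
                "target set with zero within-set similarity above the "
                "threshold; lambda clamped to %.0f", _LAMBDA_CLAMP[1]
            )
            return _LAMBDA_CLAMP[1]
        lam = (n_self_pairs / self_raw_score) ** SIZE_EXPONENT
        return float(min(max(lam, _LAMBDA_CLAMP[0]), _LAMBDA_CLAMP[1]))
    if form == "printed":
        if self_raw_score <= 0:
            return 0.0
        return float((self_raw_score / n_self_pairs) ** SIZE_EXPONENT)
    raise ValueError(f"unknown lambda form {form!r}")


def _self_similarity(
    fps: list[Fingerprint], threshold: float
) -> tuple[float, int]:
    n = len(fps)
    raw = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            t = tanimoto(fps[i], fps[j])
            if t >= threshold:
                raw += t
    return raw, n * (n - 1) // 2


def build_target_set(
    target_id: str,
    ligands: list[StandardizedCompound],
    config: CurationConfig | None = None,
) -> TargetSet:
    """Assemble a TargetSet (fingerprints + diversity statistics) from
    already standardized, deduplicated ligands."""
    config = config or CurationConfig()
    fps = [fingerprint(lig, config.fingerprint_kind) for lig in ligands]
    self_raw, n_pairs = _self_similarity(fps, config.similarity_threshold)
    lam = lambda_weight(self_raw, n_pairs, config.lambda_form)
    return TargetSet(
        target_id=target_id,
        ligands=ligands,
        fingerprints=fps,
        n_ligands=len(ligands),
        self_raw_score=self_raw,
        n_self_pairs=n_pairs,
        lambda_weight=lam,
    )


def curate(
    records: list[InteractionRecord], config: CurationConfig | None = None
) -> CurationResult:
    """Filter an interaction table into curated target sets.

    Keeps records with an allowed binding type and affinity <= the cutoff
    (records without a numeric affinity are removed), standardizes and
    deduplicates ligands per target, and drops targets left with fewer than
    the minimum number of distinct ligands.  Nothing is fatal: every removed
    record lands in the rejects report with a reason code.
    """
    config = config or CurationConfig()
    allowed = {bt.upper() for bt in config.binding_types}
    rejects: list[RejectedRecord] = []
    per_target: dict[str, list[StandardizedCompound]] = {}
    kept_rows: dict[str, list[RejectedRecord]] = {}
    for rec in records:
        cid = rec.compound.source_id
        if rec.binding_type.upper() not in allowed:
            rejects.append(RejectedRecord(cid, rec.target_id, "binding_type"))
            continue
        if rec.affinity_nM is None or not math.isfinite(rec.affinity_nM) \
                or rec.affinity_nM <= 0 or rec.affinity_nM > config.affinity_max_nM:
            rejects.append(RejectedRecord(cid, rec.target_id, "affinity"))
            continue
        try:
            comp = standardize(rec.compound, config.standardization)
        except Exception:
            rejects.append(RejectedRecord(cid, rec.target_id, "parse_error"))
            continue
        per_target.setdefault(rec.target_id, []).append(comp)
        kept_rows.setdefault(rec.target_id, []).append(
            RejectedRecord(cid, rec.target_id, "target_too_small")
        )
    targets = []
    for target_id in per_target:
        ligands = deduplicate(per_target[target_id])
        if len(ligands) < config.min_ligands:
            rejects.extend(kept_rows[target_id])
            continue
        targets.append(build_target_set(target_id, ligands, config))
    targets.sort(key=lambda t: t.target_id)
    return CurationResult(targets=targets, rejects=rejects)


def raw_score(
    query_fp: Fingerprint,
    target: TargetSet,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> tuple[float, int]:
    """Thresholded-Tanimoto sum of the query against one target set and the
    number of contributing ligands."""
    raw = 0.0
    n = 0
    for fp in target.fingerprints:
        t = tanimoto(query_fp, fp)
        if t >= threshold:
            raw += t
            n += 1
    return raw, n


def calibrate_background(
    targets: list[TargetSet],
    decoys: list[StandardizedCompound],
    seed: int = 0,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    fingerprint_kind: str = "circular_d4",
) -> BackgroundModel:
    """Estimate the random-background (μ, σ) of normalized raw scores.

    Every decoy is scored against every target set; μ and σ are the mean and
    standard deviation of the pooled raw/N_A values.  Decoys must be distinct
    from all target ligands (by canonical_id) and number at least 100.
    """
    if len(decoys) < 100:
        raise CalibrationError(
            f"background calibration needs >= 100 decoys, got {len(decoys)}"
        )
    ligand_ids = {lig.canonical_id for t in targets for lig in t.ligands}
    overlap = [d.canonical_id for d in decoys if d.canonical_id in ligand_ids]
    if overlap:
        raise CalibrationError(
            f"{len(overlap)} decoys coincide with target ligands; decoys must "
            "be disjoint from every target set"
        )
    values = np.empty(len(decoys) * len(targets))
    k = 0
    for decoy in decoys:
        fp = fingerprint(decoy, fingerprint_kind)
        for target in targets:
            raw, _ = raw_score(fp, target, threshold)
            values[k] = raw / target.n_ligands
            k += 1
    sigma = float(values.std())
    if sigma <= 0.0:
        raise CalibrationError(
            "all background scores are identical (σ = 0); use more or "
            "chemically looser decoys"
        )
    return BackgroundModel(
        mu=float(values.mean()), sigma=sigma, n_samples=len(values), seed=int(seed)
    )


def z_score(raw: float, target: TargetSet, bg: BackgroundModel) -> float:
    """Background-normalized, size-corrected significance of a raw score:
    Z = ((raw / N_A) - μ) * N_A^0.335 / σ."""
    return (raw / target.n_ligands - bg.mu) * target.n_ligands ** SIZE_EXPONENT / bg.sigma


def e_value(z: float, n_targets: int) -> float:
    """Expected number of hits at least this good by chance:
    E = n_targets * exp(-Z).  Decreases exponentially in Z and scales with
    the database size."""
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    return n_targets * math.exp(-z)


@dataclass(frozen=True)
class PredictionConfig:
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    e_max: float | None = 1.0  # None disables the E-value filter
    lambda_form: str = "stated_range"
    use_lambda: bool = True
    fingerprint_kind: str = "circular_d4"


def predict_targets(
    query: StandardizedCompound,
    targets: list[TargetSet],
    bg: BackgroundModel,
    config: PredictionConfig | None = None,
) -> list[TargetPrediction]:
    """Rank target sets for a query compound by diversity-weighted Z-score.

    Under the default λ form (λ >= 1, larger for more diverse sets) the
    weighted score is Z/λ, penalizing diverse sets whose Z-scores behave
    like inflated random scores; under the ``printed`` form it is Z·λ.
    Predictions with E-value above ``e_max`` are dropped as indistinguishable
    from chance.
    """
    config = config or PredictionConfig()
    if not targets:
        raise ValueError("predict_targets requires a nonempty target list")
    query_fp = fingerprint(query, config.fingerprint_kind)
    predictions = []
    for target in targets:
        raw, n_contrib = raw_score(query_fp, target, config.similarity_threshold)
        z = z_score(raw, target, bg)
        if config.use_lambda:
            lam = lambda_weight(
                target.self_raw_score, target.n_self_pairs, config.lambda_form
            )
            wz = z / lam if config.lambda_form == "stated_range" else z * lam
        else:
            wz = z
        e = e_value(wz, len(targets))
        if config.e_max is not None and e > config.e_max:
            continue
        predictions.append(
            TargetPrediction(
                target_id=target.target_id,
                raw_score=raw,
                z_score=z,
                weighted_z=wz,
                e_value=e,
                n_contributing=n_contrib,
            )
        )
    predictions.sort(key=lambda p: (-p.weighted_z, p.target_id))
    return predictions
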