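"""Consensus prediction of a compound's ATC class.

A query is ranked against a labeled reference library by three independent
similarity methods — 2D fingerprint Tanimoto, fragment-assignment similarity
and 3D superposition — and each method nominates the ATC class of its
top-ranked reference drug (truncated to the requested ATC level).  The
consensus rule: if at least two methods agree, their class is the final
prediction; if all three disagree, the method whose top score clears its
per-method threshold by the largest margin decides; if none does, the query
stays unclassified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .compound_model import StandardizedCompound
from .fingerprints import Fingerprint, fingerprint, tanimoto
from .fragmenter import FragmentSet, fragment, fragment_similarity
from .superposer import (
    DEFAULT_CONFORMER_SEED,
    Conformer,
    generate_conformers,
    inertial_frame,
    score_conformer_sets,
)

__all__ = [
    "ReferenceLibrary",
    "LibraryEntry",
    "MethodRanking",
    "ConsensusResult",
    "ConsensusConfig",
    "EvaluationReport",
    "METHODS",
    "rank_by_method",
    "classify",
    "evaluate_prediction_rate",
]

METHODS = ("2d", "fragment", "3d")
_ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_LEVEL_PREFIX = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


def truncate_atc(code: str, level: int) -> str:
    return code[: _LEVEL_PREFIX[level]]


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds and knobs of the consensus pipeline.

    The 3D threshold sits lower than the 2D/fragment ones because the
    exp(-rmsd) factor keeps even good superpositions well under 1.
    """

    atc_level: int = 2
    thresholds: dict = field(
        default_factory=lambda: {"2d": 0.45, "fragment": 0.45, "3d": 0.30}
    )
    methods: tuple = METHODS
    fingerprint_kind: str = "circular_d4"
    max_conformers: int = 100
    conformer_seed: int = DEFAULT_CONFORMER_SEED
    max_pair_distance: float = 1.0


@dataclass
class LibraryEntry:
    compound: StandardizedCompound
    atc_codes: list[str]


@dataclass
class ReferenceLibrary:
    """Labeled drug library with precomputed similarity artifacts."""

    entries: list[LibraryEntry]
    fingerprints: dict[str, Fingerprint] = field(default_factory=dict)
    fragment_sets: dict[str, FragmentSet] = field(default_factory=dict)
    conformers: dict[str, list[Conformer]] = field(default_factory=dict)
    config: ConsensusConfig = field(default_factory=ConsensusConfig)

    @classmethod
    def build(
        cls,
        labeled: list[tuple[StandardizedCompound, list[str]]],
        config: ConsensusConfig | None = None,
        with_conformers: bool = True,
    ) -> "ReferenceLibrary":
        config = config or ConsensusConfig()
        seen = set()
        entries = []
        for comp, codes in labeled:
            if not codes:
                raise ValueError(f"entry {comp.canonical_smiles!r} has no ATC code")
            for code in codes:
                if not _ATC_PATTERN.match(code):
                    raise ValueError(f"invalid ATC code {code!r}")
            if comp.canonical_id in seen:
                raise ValueError(
                    f"duplicate canonical_id in library: {comp.canonical_id}"
                )
            seen.add(comp.canonical_id)
            entries.append(LibraryEntry(compound=comp, atc_codes=sorted(codes)))
        lib = cls(entries=entries, config=config)
        for entry in entries:
            cid = entry.compound.canonical_id
            lib.fingerprints[cid] = fingerprint(entry.compound, config.fingerprint_kind)
            lib.fragment_sets[cid] = fragment(entry.compound, config.fingerprint_kind)
        if with_conformers and "3d" in config.methods:
            for entry in entries:
                cid = entry.compound.canonical_id
                lib.conformers[cid] = [
                    inertial_frame(c)
                    for c in generate_conformers(
                        entry.compound,
                        max_conformers=config.max_conformers,
                        seed=config.conformer_seed,
                    )
                ]
        return lib

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MethodRanking:
    method: str
    ranked: list[tuple[str, float]]  # (reference canonical_id, score) descending
    predicted_class: str
    top_score: float


@dataclass
class ConsensusResult:
    predicted_class: str  # ATC class at the configured level, or "unclassified"
    consensus_score: float
    per_method: dict[str, MethodRanking]
    decision_path: str  # two_agree | three_agree | threshold_tiebreak | no_prediction


class MissingPrecomputationError(RuntimeError):
    pass


def _query_artifacts(
    query: StandardizedCompound, method: str, config: ConsensusConfig
):
    if method == "2d":
        return fingerprint(query, config.fingerprint_kind)
    if method == "fragment":
        return fragment(query, config.fingerprint_kind)
    if method == "3d":
        return [
            inertial_frame(c)
            for c in generate_conformers(
                query, max_conformers=config.max_conformers, seed=config.conformer_seed
            )
        ]
    raise ValueError(f"unknown method {method!r}")


def _score_entry(
    artifact, method: str, library: ReferenceLibrary, cid: str, config: ConsensusConfig
) -> float:
    if method == "2d":
        return tanimoto(artifact, library.fingerprints[cid])
    if method == "fragment":
        return fragment_similarity(artifact, library.fragment_sets[cid])
    if method == "3d":
        if cid not in library.conformers:
            raise MissingPrecomputationError(
                f"library conformers missing for the 3d method (entry {cid})"
            )
        return score_conformer_sets(
            artifact, library.conformers[cid],
            max_pair_distance=config.max_pair_distance,
        )
    raise ValueError(f"unknown method {method!r}")


def _ranking_from_scores(
    method: str,
    scored: list[tuple[str, float]],
    classes: dict[str, list[str]],
    atc_level: int,
) -> MethodRanking:
    ranked = sorted(scored, key=lambda cs: (-cs[1], cs[0]))
    top_id, top_score = ranked[0]
    predicted = truncate_atc(classes[top_id][0], atc_level)
    return MethodRanking(
        method=method, ranked=ranked, predicted_class=predicted, top_score=top_score
    )


def rank_by_method(
    query: StandardizedCompound,
    library: ReferenceLibrary,
    method: str,
    atc_level: int | None = None,
    config: ConsensusConfig | None = None,
) -> MethodRanking:
    """Score every library entry against the query with one similarity
    method; ties are broken by canonical_id so rankings are deterministic."""
    config = config or library.config
    atc_level = atc_level or config.atc_level
    if not library.entries:
        raise ValueError("reference library is empty")
    artifact = _query_artifacts(query, method, config)
    scored = [
        (e.compound.canonical_id,
         _score_entry(artifact, method, library, e.compound.canonical_id, config))
        for e in library.entries
    ]
    classes = {e.compound.canonical_id: e.atc_codes for e in library.entries}
    return _ranking_from_scores(method, scored, classes, atc_level)


def consensus_from_rankings(
    rankings: dict[str, MethodRanking], config: ConsensusConfig
) -> ConsensusResult:
    """Apply the consensus rule to per-method rankings (pure decision logic,
    reusable when rankings come from precomputed score matrices)."""
    votes: dict[str, list[str]] = {}
    for method, ranking in rankings.items():
        votes.setdefault(ranking.predicted_class, []).append(method)
    best_class, supporters = max(votes.items(), key=lambda kv: len(kv[1]))
    if len(supporters) >= 2:
        path = "three_agree" if len(supporters) == len(rankings) else "two_agree"
        score = float(np.mean([rankings[m].top_score for m in supporters]))
        return ConsensusResult(
            predicted_class=best_class, consensus_score=score,
            per_method=rankings, decision_path=path,
        )
    # All methods disagree: threshold tie-break on the score margin.
    margins = {
        m: r.top_score - config.thresholds[m]
        for m, r in rankings.items()
        if r.top_score > config.thresholds[m]
    }
    if margins:
        winner = max(margins, key=lambda m: (margins[m], m))
        return ConsensusResult(
            predicted_class=rankings[winner].predicted_class,
            consensus_score=rankings[winner].top_score,
            per_method=rankings, decision_path="threshold_tiebreak",
        )
    return ConsensusResult(
        predicted_class="unclassified", consensus_score=0.0,
        per_method=rankings, decision_path="no_prediction",
    )


def classify(
    query: StandardizedCompound,
    library: ReferenceLibrary,
    config: ConsensusConfig | None = None,
) -> ConsensusResult:
    """Run all three similarity methods and combine them by the consensus
    rule."""
    config = config or library.config
    rankings = {
        m: rank_by_method(query, library, m, config.atc_level, config)
        for m in config.methods
    }
    return consensus_from_rankings(rankings, config)


# ---------------------------------------------------------------------------
# Evaluation harness


@dataclass
class EvaluationReport:
    accuracy: float
    n_queries: int
    bin_table: list[tuple[str, int, int, float]]  # (score_range, hits, misses, rate)
    recall_at_k: list[float]  # index k-1 -> recall@k
    results: list[tuple[str, ConsensusResult, bool]]  # (query id, result, correct)


def pairwise_method_scores(
    library: ReferenceLibrary, method: str, config: ConsensusConfig | None = None
) -> np.ndarray:
    """Symmetric matrix of method scores between all library entries."""
    config = config or library.config
    n = len(library.entries)
    ids = [e.compound.canonical_id for e in library.entries]
    mat = np.zeros((n, n))
    for i in range(n):
        if method == "2d":
            artifact = library.fingerprints[ids[i]]
        elif method == "fragment":
            artifact = library.fragment_sets[ids[i]]
        else:
            artifact = library.conformers[ids[i]]
        for j in range(i, n):
            s = _score_entry(artifact, method, library, ids[j], config)
            mat[i, j] = mat[j, i] = s
    return mat


def _correct(predicted: str, codes: list[str], level: int) -> bool:
    return predicted in {truncate_atc(c, level) for c in codes}


def _winning_method(result: ConsensusResult) -> MethodRanking:
    rankings = result.per_method
    if result.decision_path in ("two_agree", "three_agree"):
        supporters = [
            r for r in rankings.values()
            if r.predicted_class == result.predicted_class
        ]
        return max(supporters, key=lambda r: r.top_score)
    if result.decision_path == "threshold_tiebreak":
        for r in rankings.values():
            if r.predicted_class == result.predicted_class:
                return r
    return max(rankings.values(), key=lambda r: r.top_score)


def _bin_table(
    outcomes: list[tuple[float, bool]]
) -> list[tuple[str, int, int, float]]:
    """Hits/misses per consensus-score bin, ten equal bins over [0, 1]."""
    table = []
    for b in range(10):
        lo, hi = b / 10, (b + 1) / 10
        in_bin = [
            ok for score, ok in outcomes
            if (lo <= score < hi) or (b == 9 and score == 1.0)
        ]
        hits = sum(in_bin)
        misses = len(in_bin) - hits
        rate = hits / len(in_bin) if in_bin else 0.0
        table.append((f"{lo:.1f}-{hi:.1f}", hits, misses, rate))
    return table


def evaluate_prediction_rate(
    library: ReferenceLibrary,
    atc_level: int | None = None,
    mode: str = "leave_one_out",
    external_queries: list[tuple[StandardizedCompound, list[str]]] | None = None,
    config: ConsensusConfig | None = None,
    max_recall_k: int = 20,
) -> EvaluationReport:
    """Measure classification accuracy.

    ``leave_one_out`` removes each library drug in turn and classifies it
    against the rest (pairwise score matrices are computed once and reused).
    ``external`` classifies a separate labeled query list against the full
    library.  A prediction counts as correct when it matches any of the
    query's ATC codes at the evaluated level.  Alongside the accuracy the
    report carries the ten-bin consensus-score table and the cumulative
    recall@k curve of the consensus-winning method.
    """
    config = config or library.config
    atc_level = atc_level or config.atc_level
    ids = [e.compound.canonical_id for e in library.entries]
    classes = {e.compound.canonical_id: e.atc_codes for e in library.entries}
    outcomes: list[tuple[float, bool]] = []
    results = []
    recall_hits = np.zeros(max_recall_k)

    def tally(qid: str, codes: list[str], result: ConsensusResult):
        ok = result.predicted_class != "unclassified" and _correct(
            result.predicted_class, codes, atc_level
        )
        outcomes.append((result.consensus_score, ok))
        results.append((qid, result, ok))
        winner = _winning_method(result)
        want = {truncate_atc(c, atc_level) for c in codes}
        found_at = None
        for rank, (cid, _) in enumerate(winner.ranked[:max_recall_k]):
            if any(truncate_atc(c, atc_level) in want for c in classes_all[cid]):
                found_at = rank
                break
        if found_at is not None:
            recall_hits[found_at:] += 1

    if mode == "leave_one_out":
        if len(library.entries) < 2:
            raise ValueError("leave-one-out needs at least two library entries")
        classes_all = classes
        mats = {
            m: pairwise_method_scores(library, m, config) for m in config.methods
        }
        for qi, entry in enumerate(library.entries):
            rankings = {}
            for method in config.methods:
                scored = [
                    (ids[j], float(mats[method][qi, j]))
                    for j in range(len(ids)) if j != qi
                ]
                rankings[method] = _ranking_from_scores(
                    method, scored, classes, atc_level
                )
            result = consensus_from_rankings(rankings, config)
            tally(entry.compound.canonical_id, entry.atc_codes, result)
    elif mode == "external":
        if not external_queries:
            raise ValueError("external mode requires a labeled query list")
        for comp, codes in external_queries:
            if not codes:
                raise ValueError(
                    f"unlabeled query {comp.canonical_smiles!r} in external mode"
                )
        classes_all = classes
        for comp, codes in external_queries:
            result = classify(comp, library, config)
            tally(comp.canonical_id, codes, result)
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")

    n = len(outcomes)
    accuracy = sum(ok for _, ok in outcomes) / n
    recall = list(recall_hits / n)
    return EvaluationReport(
        accuracy=accuracy,
        n_queries=n,
        bin_table=_bin_table(outcomes),
        recall_at_k=recall,
        results=results,
    )
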