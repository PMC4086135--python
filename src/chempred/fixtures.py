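"""Deterministic synthetic chemistry for end-to-end testing.

Real drug libraries and interaction databases cannot ship with the package,
so every pipeline stage is exercised on generated congeneric series: a
scaffold template with two substitution sites is decorated with substituents
from a pool, giving chemically valid, mutually similar series members, while
different series use structurally unrelated scaffolds.  Two generators are
provided:

``make_atc_library``
    Congeneric series, each labeled with a distinct synthetic ATC code.
    Generation verifies the planted signal — the minimum within-series
    fingerprint similarity must exceed the maximum cross-series similarity —
    and retries with fresh substituents (bounded) if it does not hold.

``make_target_db``
    Planted target sets of controllable within-set diversity plus an
    interaction table that deliberately contains too-weak affinities,
    disallowed binding types and an undersized target, together with a
    manifest of which rows the curation step must reject.  Held-out
    congeners of each target and scaffold-matched decoy compounds (for
    background calibration) are emitted alongside.

Everything is regenerable byte-identically from (spec, seed).
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .atc_classifier import ConsensusConfig, ReferenceLibrary
from .compound_model import RawCompound, StandardizedCompound, standardize
from .fingerprints import fingerprint, tanimoto
from .target_predictor import InteractionRecord

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "AtcFixture",
    "TargetFixture",
    "SCAFFOLD_TEMPLATES",
    "make_atc_library",
    "make_target_db",
    "write_atc_fixture",
    "write_target_fixture",
    "read_interaction_tsv",
]


class FixtureError(RuntimeError):
    """The generator could not satisfy its similarity guarantees."""


# Two-site scaffold templates.  The first eleven are mutually dissimilar
# (pairwise member similarity < 0.3 on unfolded circular fingerprints); the
# last two overlap mildly with earlier entries and serve only as secondary
# scaffolds inside deliberately diverse target sets.
SCAFFOLD_TEMPLATES = (
    "c1ccc2nc({R1})cc({R2})c2c1",          # quinoline
    "O=c1cc({R1})oc2cc({R2})ccc12",        # chromone
    "Cn1nc({R1})c2cc({R2})ncc21",          # pyrazolo-pyrimidine
    "O=C1SC({R1})C(=O)N1C{R2}",            # thiazolidinedione
    "O=C(NC{R1})NC1CCC({R2})CC1",          # cyclohexyl urea
    "c1cc({R1})c(-c2ccc({R2})o2)cn1",      # furyl-pyridine
    "c1nc({R1})nc({R2})c1N1CCOCC1",        # morpholino-pyrimidine
    "O=S(=O)(NC{R1})c1ccc({R2})cc1",       # benzenesulfonamide
    "O=C1CN(c2ccc({R1})cc2)CCN1C({R2})",   # aryl piperazinone
    "Cn1cc({R1})nc1C1CCC({R2})CC1",        # imidazolyl-cyclohexane
    "O=C1CC({R1})CN1c1ccc({R2})nc1",       # pyridyl-pyrrolidinone
    "Cn1c({R1})cc2cc({R2})ccc21",          # N-methylindole (secondary only)
    "Cc1nc2cc({R1})c({R2})cc2s1",          # benzothiazole (secondary only)
)

SMALL_SUBSTITUENTS = ("C", "CC", "F", "Cl", "O", "OC", "N", "C#N", "CCC", "Br")


def _substituent_pool(wide: bool) -> tuple:
    """Programmatic substituent enumeration: short carbon linkers combined
    with terminal groups.  The core pool holds small aliphatic/halogen/polar
    substituents (one chemotype class); the wide pool adds branched and
    bulkier polar groups for deliberately heterogeneous series."""
    prefixes = ["", "C", "CC", "CCC", "CCCC"]
    terminals = [
        "C", "O", "N", "F", "Cl", "Br", "C#N", "OC", "CO", "CN",
        "C(C)C", "C(F)(F)F", "OCC", "N(C)C", "CCl", "CF",
    ]
    if wide:
        prefixes += ["C(C)", "CC(C)"]
        terminals += ["C(=O)C", "C(=O)OC", "C(=O)N", "OC(C)C", "CCOC", "CBr"]
    seen = []
    for prefix, term in ((p, t) for p in prefixes for t in terminals):
        sub = prefix + term
        if sub not in seen:
            seen.append(sub)
    return tuple(seen)


CORE_SUBSTITUENTS = _substituent_pool(wide=False)
WIDE_SUBSTITUENTS = _substituent_pool(wide=True)

_ATC_LETTERS = "ABCDGHJLNPRSV"
DIVERSITY_LEVELS = ("uniform", "medium", "diverse")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for both generators."""

    # ATC library fixture
    n_series: int = 4
    series_size: int = 10
    seed: int = 2014
    # target-database fixture
    n_targets: int = 10
    ligands_per_target: int = 25
    holdout_per_target: int = 20
    diversity_levels: tuple = (
        "uniform", "uniform", "uniform", "uniform", "uniform", "uniform",
        "medium", "medium", "diverse", "diverse",
    )
    weak_fraction: float = 0.2
    n_binding_type_rejects: int = 2
    undersized_target_size: int = 4
    decoys_per_target: int = 11
    max_retries: int = 10

    def __post_init__(self):
        if self.n_series > 11:
            raise FixtureError("at most 11 mutually dissimilar scaffolds available")
        if self.n_targets > 11:
            raise FixtureError("at most 11 primary scaffolds available")
        if len(self.diversity_levels) < self.n_targets:
            raise FixtureError("diversity_levels shorter than n_targets")
        for lvl in self.diversity_levels:
            if lvl not in DIVERSITY_LEVELS:
                raise FixtureError(f"unknown diversity level {lvl!r}")


def _member(template: str, r1: str, r2: str, source_id: str) -> StandardizedCompound:
    smiles = template.format(R1=r1, R2=r2)
    return standardize(RawCompound(source_id=source_id, structure=smiles))


class _CongenerDraw:
    """Draw congeners of one scaffold without replacement.

    One substitution site is fixed per scaffold (part of the series
    identity); the other varies over the pool, so series members differ in
    exactly one substituent and stay chemically close — the congeneric-series
    structure of a real target set.
    """

    def __init__(self, pool: tuple, rng: random.Random):
        self.r2 = rng.choice(SMALL_SUBSTITUENTS)
        r1s = list(pool)
        rng.shuffle(r1s)
        self._iter = iter(r1s)

    def take(self) -> tuple[str, str]:
        r1 = next(self._iter, None)
        if r1 is None:
            raise FixtureError("substituent pool exhausted for a scaffold")
        return r1, self.r2


@dataclass
class AtcFixture:
    library: ReferenceLibrary
    labeled: list[tuple[StandardizedCompound, list[str]]]
    min_within: float
    max_cross: float
    similarity_rows: list[tuple[str, str, str, float]]  # (id_a, id_b, kind, sim)


def make_atc_library(
    spec: FixtureSpec | None = None,
    config: ConsensusConfig | None = None,
    with_conformers: bool = True,
) -> AtcFixture:
    """Generate the congeneric-series reference library with planted ATC
    labels and verify the within/cross similarity separation."""
    spec = spec or FixtureSpec()
    config = config or ConsensusConfig()
    rng = random.Random(spec.seed)
    for attempt in range(spec.max_retries):
        labeled: list[tuple[StandardizedCompound, list[str]]] = []
        series_ids: list[list[str]] = []
        fps = {}
        seen = set()
        ok = True
        for si in range(spec.n_series):
            template = SCAFFOLD_TEMPLATES[si]
            pool = list(SMALL_SUBSTITUENTS)
            r2 = rng.choice(pool)
            r1_choices = rng.sample(pool, len(pool))
            code = f"{_ATC_LETTERS[si]}01AA01"
            members = []
            for r1 in r1_choices:
                if len(members) == spec.series_size:
                    break
                comp = _member(template, r1, r2, f"S{si}_{r1}")
                if comp.canonical_id in seen:
                    continue
                seen.add(comp.canonical_id)
                members.append(comp)
                fps[comp.canonical_id] = fingerprint(comp, config.fingerprint_kind)
            if len(members) < spec.series_size:
                ok = False
                break
            labeled.extend((m, [code]) for m in members)
            series_ids.append([m.canonical_id for m in members])
        if not ok:
            continue
        min_within = 1.0
        max_cross = 0.0
        rows = []
        for si, ids in enumerate(series_ids):
            for a, b in itertools.combinations(ids, 2):
                s = tanimoto(fps[a], fps[b])
                min_within = min(min_within, s)
                rows.append((a, b, "within", s))
            for sj in range(si + 1, len(series_ids)):
                for a in ids:
                    for b in series_ids[sj]:
                        s = tanimoto(fps[a], fps[b])
                        max_cross = max(max_cross, s)
                        rows.append((a, b, "cross", s))
        if min_within > max_cross:
            library = ReferenceLibrary.build(
                labeled, config=config, with_conformers=with_conformers
            )
            return AtcFixture(
                library=library,
                labeled=labeled,
                min_within=min_within,
                max_cross=max_cross,
                similarity_rows=rows,
            )
    raise FixtureError(
        "could not plant a separable ATC signal within the retry budget"
    )


@dataclass
class TargetFixture:
    records: list[InteractionRecord]
    holdouts: dict[str, list[StandardizedCompound]]  # target_id -> held-out queries
    decoys: list[StandardizedCompound]
    expected_rejects: list[dict]  # {compound_id, target_id, reason}
    scaffold_of_target: dict[str, list[int]] = field(default_factory=dict)


def make_target_db(spec: FixtureSpec | None = None) -> TargetFixture:
    """Generate the planted target sets, the raw interaction table with its
    deliberate curation bait, the held-out queries and the decoy pool."""
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed + 1)
    binding_cycle = itertools.cycle(("Ki", "IC50", "KD"))
    records: list[InteractionRecord] = []
    holdouts: dict[str, list[StandardizedCompound]] = {}
    decoys: list[StandardizedCompound] = []
    expected_rejects: list[dict] = []
    scaffold_of_target: dict[str, list[int]] = {}
    n_weak = round(spec.weak_fraction * spec.ligands_per_target)
    diverse_seen = 0
    decoy_seen_ids: set[str] = set()

    def affinity_ok() -> float:
        return round(10 ** rng.uniform(0.0, 4.0), 1)

    def affinity_weak() -> float:
        return round(10 ** rng.uniform(4.05, 6.0), 1)

    for ti in range(spec.n_targets):
        target_id = f"TGT{ti:02d}"
        level = spec.diversity_levels[ti]
        if level == "diverse":
            secondary = 11 + diverse_seen
            diverse_seen += 1
            scaffolds = [ti, secondary]
        else:
            scaffolds = [ti]
        scaffold_of_target[target_id] = scaffolds
        pool = CORE_SUBSTITUENTS if level == "uniform" else WIDE_SUBSTITUENTS
        draws = {s: _CongenerDraw(pool, rng) for s in scaffolds}
        counter = itertools.count()

        used_ids: set[str] = set()

        def congener(scaffold_idx: int) -> StandardizedCompound:
            r1, r2 = draws[scaffold_idx].take()
            cid = f"{target_id}_C{next(counter):03d}"
            comp = _member(SCAFFOLD_TEMPLATES[scaffold_idx], r1, r2, cid)
            used_ids.add(comp.canonical_id)
            return comp

        # active ligands: diverse sets draw ~60/40 from their two scaffolds
        n_primary = (
            spec.ligands_per_target if len(scaffolds) == 1
            else round(0.6 * spec.ligands_per_target)
        )
        for li in range(spec.ligands_per_target):
            scaffold = scaffolds[0] if li < n_primary else scaffolds[1]
            comp = congener(scaffold)
            records.append(
                InteractionRecord(
                    compound=RawCompound(
                        source_id=comp.provenance_ids[0],
                        structure=comp.canonical_smiles,
                    ),
                    target_id=target_id,
                    binding_type=next(binding_cycle),
                    affinity_nM=affinity_ok(),
                )
            )
        # too-weak interactions (must be rejected by the affinity filter)
        for _ in range(n_weak):
            comp = congener(scaffolds[0])
            rid = comp.provenance_ids[0]
            records.append(
                InteractionRecord(
                    compound=RawCompound(source_id=rid, structure=comp.canonical_smiles),
                    target_id=target_id,
                    binding_type=next(binding_cycle),
                    affinity_nM=affinity_weak(),
                )
            )
            expected_rejects.append(
                {"compound_id": rid, "target_id": target_id, "reason": "affinity"}
            )
        # held-out queries, always from the primary scaffold
        holdouts[target_id] = [
            congener(scaffolds[0]) for _ in range(spec.holdout_per_target)
        ]
        # scaffold-matched decoys for background calibration: same ring system
        # as the target's ligands but an independent series decoration, so
        # they score against the target without looking like true actives
        decoy_draw = _CongenerDraw(WIDE_SUBSTITUENTS, rng)
        di = 0
        while di < spec.decoys_per_target:
            r1, r2 = decoy_draw.take()
            d = _member(
                SCAFFOLD_TEMPLATES[scaffolds[0]], r1, r2, f"{target_id}_D{di:03d}"
            )
            if d.canonical_id in used_ids or d.canonical_id in decoy_seen_ids:
                continue
            decoy_seen_ids.add(d.canonical_id)
            decoys.append(d)
            di += 1

    # disallowed binding types (must be rejected by the type filter)
    extra_draw = _CongenerDraw(WIDE_SUBSTITUENTS, rng)
    for bi in range(spec.n_binding_type_rejects):
        r1, r2 = extra_draw.take()
        rid = f"BT{bi:02d}"
        comp = _member(SCAFFOLD_TEMPLATES[0], r1, r2, rid)
        records.append(
            InteractionRecord(
                compound=RawCompound(source_id=rid, structure=comp.canonical_smiles),
                target_id="TGT00",
                binding_type="EC50",
                affinity_nM=affinity_ok(),
            )
        )
        expected_rejects.append(
            {"compound_id": rid, "target_id": "TGT00", "reason": "binding_type"}
        )

    # one undersized target (all its rows must be rejected)
    small_draw = _CongenerDraw(WIDE_SUBSTITUENTS, rng)
    for si in range(spec.undersized_target_size):
        r1, r2 = small_draw.take()
        rid = f"SMALL_{si:02d}"
        comp = _member(SCAFFOLD_TEMPLATES[12], r1, r2, rid)
        records.append(
            InteractionRecord(
                compound=RawCompound(source_id=rid, structure=comp.canonical_smiles),
                target_id="TGT_SMALL",
                binding_type=next(binding_cycle),
                affinity_nM=affinity_ok(),
            )
        )
        expected_rejects.append(
            {"compound_id": rid, "target_id": "TGT_SMALL", "reason": "target_too_small"}
        )

    return TargetFixture(
        records=records,
        holdouts=holdouts,
        decoys=decoys,
        expected_rejects=expected_rejects,
        scaffold_of_target=scaffold_of_target,
    )


# ---------------------------------------------------------------------------
# On-disk form (standard SMILES/TSV consumed by the CLI)


def write_atc_fixture(fixture: AtcFixture, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "library.smi", "w") as fh:
        for comp, _codes in fixture.labeled:
            fh.write(f"{comp.canonical_smiles}\t{comp.provenance_ids[0]}\n")
    with open(outdir / "atc_codes.tsv", "w") as fh:
        fh.write("compound_id\tatc_codes\n")
        for comp, codes in fixture.labeled:
            fh.write(f"{comp.provenance_ids[0]}\t{';'.join(codes)}\n")
    with open(outdir / "similarity_check.tsv", "w") as fh:
        fh.write("id_a\tid_b\tkind\ttanimoto\n")
        for a, b, kind, s in fixture.similarity_rows:
            fh.write(f"{a}\t{b}\t{kind}\t{s:.6f}\n")
    summary = {
        "min_within_series": fixture.min_within,
        "max_cross_series": fixture.max_cross,
        "n_compounds": len(fixture.labeled),
    }
    (outdir / "verification.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def write_target_fixture(fixture: TargetFixture, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "interactions.tsv", "w") as fh:
        fh.write("compound_id\tsmiles\ttarget_id\tbinding_type\taffinity_nM\n")
        for rec in fixture.records:
            fh.write(
                f"{rec.compound.source_id}\t{rec.compound.structure}\t"
                f"{rec.target_id}\t{rec.binding_type}\t{rec.affinity_nM}\n"
            )
    with open(outdir / "holdout_queries.smi", "w") as fh:
        for target_id in sorted(fixture.holdouts):
            for comp in fixture.holdouts[target_id]:
                fh.write(f"{comp.canonical_smiles}\t{comp.provenance_ids[0]}\n")
    with open(outdir / "holdout_labels.tsv", "w") as fh:
        fh.write("query_id\ttarget_id\n")
        for target_id in sorted(fixture.holdouts):
            for comp in fixture.holdouts[target_id]:
                fh.write(f"{comp.provenance_ids[0]}\t{target_id}\n")
    with open(outdir / "decoys.smi", "w") as fh:
        for comp in fixture.decoys:
            fh.write(f"{comp.canonical_smiles}\t{comp.provenance_ids[0]}\n")
    (outdir / "reject_manifest.json").write_text(
        json.dumps(fixture.expected_rejects, indent=2, sort_keys=True) + "\n"
    )


def read_interaction_tsv(path) -> list[InteractionRecord]:
    """Read an interaction table: compound_id, smiles, target_id,
    binding_type, affinity_nM (tab-separated with a header)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["compound_id", "smiles", "target_id", "binding_type", "affinity_nM"]
        if header != expected:
            raise ValueError(f"interaction table must have columns {expected}")
        for line in fh:
            cid, smiles, tid, btype, aff = line.rstrip("\n").split("\t")
            try:
                affinity = float(aff)
            except ValueError:
                affinity = None
            records.append(
                InteractionRecord(
                    compound=RawCompound(source_id=cid, structure=smiles),
                    target_id=tid,
                    binding_type=btype,
                    affinity_nM=affinity,
                )
            )
    return records
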