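# Methods

This note records the models implemented in `chempred`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic test chemistry does and does not demonstrate.

## Compound standardization

Every structure entering the system is reduced to a canonical
single-fragment record:

1. parse (SMILES or MOL block; input coordinates are discarded — 3D work
   always regenerates conformers so 2D and 3D inputs behave identically);
2. keep the largest covalent fragment by heavy-atom count (ties: higher
   molecular weight, then lexicographically smallest canonical SMILES, so
   the choice is deterministic);
3. strip explicit hydrogens, perceive aromaticity;
4. neutralize formal charges by protonating/deprotonating simple acid/base
   groups; charges that cannot be removed without changing bonds
   (quaternary nitrogen, charge-balanced zwitterion pairs) are kept
   (`neutralize_charges`, default on);
5. remove stereo descriptors (`keep_stereo`, default off) so stereoisomer
   records merge — the identity of a compound is its standard InChI of the
   final structure.

Tautomer canonicalization is deliberately out of scope; two tautomers are
two records.

## Fingerprints and Tanimoto similarity

The pipeline's working fingerprint is the circular (Morgan-type)
fingerprint of diameter 4, used **unfolded**: the bit set holds the raw
environment identifiers.  Folding to a fixed length loses information to
hash collisions; on the synthetic library the folded (2048-bit) and
unfolded Tanimoto values differ by well under 0.1, but unfolded is the
default because it is strictly more faithful at negligible cost at this
scale.  Two other backends exist so method-comparison harnesses can run:
the 166 MDL structural keys and a hashed linear-path fingerprint (paths up
to 7 bonds, 1024 bits) standing in for proprietary path fingerprints.

Tanimoto on two *empty* bit sets is defined as 0.0, not 1.0: a degenerate
atom-poor input must not look like a perfect match.

## Fragment similarity (linker rule)

Ring systems (rings sharing an atom) are fragment cores.  Acyclic
connected components touching two or more distinct ring systems are linkers
and are deleted entirely — including branch atoms hanging off the linker
path, which keeps the rule a function of the component rather than of an
arbitrary choice of path.  Components touching exactly one system stay with
it.  Attachment points are hydrogen-capped so each fragment is a valid
standalone molecule; fragments are deduplicated by canonical SMILES and
fingerprinted with the same circular fingerprint as the 2D method, keeping
one similarity vocabulary.  A molecule without rings degrades to a single
whole-molecule fragment, which makes fragment similarity collapse to plain
Tanimoto — the least surprising behavior for acyclic inputs.

Comparing fragment sets of sizes n and m: the n×m Tanimoto matrix is
searched for the one-to-one assignment of min(n, m) pairs maximizing the
coefficient sum (Hungarian algorithm via `scipy.optimize.linear_sum_assignment`),
and the score is that sum divided by min(n, m).  Maximizing is the only
reading under which a molecule compared with itself scores exactly 1; the
solver is validated against exhaustive enumeration over all injective
mappings in the test suite.

## 3D superposition

* **Conformers.** Distance-geometry embedding (ETKDGv3) with force-field
  minimization (MMFF94, falling back to UFF where MMFF parameters are
  missing), pruned for distinctness (0.3 Å RMS) and sorted by energy.  The
  embedding seed (default 2014) is fixed and recorded; conformer ensembles
  are reproducible.  The library default is 100 conformers per molecule
  (at most 10 000 pair comparisons per molecule pair).
* **Inertial frame.** Heavy atoms only, standard atomic masses.  The
  center of mass is translated to the origin and the principal axes of
  inertia aligned with the coordinate axes, largest moment on x, smallest
  on z, proper rotation only.  Because axes are defined up to sign, only
  four orientations (identity and 180° about x, y, z) need searching when
  superposing two frames.
* **Symmetric tops.** When two principal moments coincide (relative gap
  < 1e-6) the eigenbasis is arbitrary within the degenerate plane.  Two
  safeguards restore determinism and rigid-motion invariance: the
  degenerate plane is re-anchored to the projection of the atom farthest
  from the origin (an equivariant function of the geometry), and the
  orientation search widens to all 24 proper axis permutations/flips.
  Molecules with a *continuous* symmetry axis (e.g. benzene) are exactly
  invariant in practice because the anchor atom choice differs only between
  symmetry-equivalent atoms.
* **Atom mapping.** Nearest-first greedy pairing under a maximum pair
  distance of 1.0 Å (configurable; at this threshold exp(−rmsd) ≥ 0.37 for
  every mapped structure).  Element identity is *not* required for a pair
  by default (`match_elements` enables strict mode): shape similarity is
  the point of the 3D method.  An optimal assignment mode (maximum mapped
  pairs, then minimum rmsd) exists and is what the brute-force oracle
  tests exercise; greedy is the pipeline default for speed and for its
  nearest-first semantics.
* **Score.** `N_S / max(N_A, N_B) · exp(−rmsd)` over mapped pairs, maximized
  over conformer pairs.  The max(N_A, N_B) denominator is the only
  normalization under which self-superposition scores exactly 1 while
  partial overlap is penalized by the size of the larger molecule.  With no
  pair under the threshold the score is 0 and the result is flagged.

## Consensus ATC classification

Each method ranks the reference library (ties broken by canonical
identifier) and nominates the ATC class of its rank-1 drug, truncated to
the requested level (default level 2, the therapeutic subgroup; level 1
gives the 14 anatomical main groups).  Decision rule: ≥ 2 agreeing methods
win; with three distinct nominations, the method exceeding its threshold by
the largest margin decides; otherwise "unclassified".  Per-method
thresholds default to 0.45 (2D), 0.45 (fragment) and 0.30 (3D) — the 3D
threshold sits lower because exp(−rmsd) compresses even good superpositions.
The consensus score is the mean of the top scores of the methods voting for
the final class, which keeps it in [0, 1]; it is a confidence heuristic,
not a probability.  Drugs carrying several ATC codes contribute every code,
and a prediction matching *any* code of the query counts as correct in the
evaluation harness.

## Target prediction statistics

* **Curation.** Binding types restricted to {IC50, Ki, KD} (case-insensitive),
  affinity ≤ 10 000 nM inclusive (records without a numeric affinity are
  removed; units must already be nM — no conversion), ligands standardized
  and InChI-deduplicated per target, targets with < 5 distinct ligands
  dropped.  Nothing is fatal: every removed record lands in a rejects
  report with a reason code.
* **Raw score.** Sum of query-ligand Tanimoto values ≥ 0.45.
* **Background.** Decoys (≥ 100, disjoint from all target ligands) are
  scored against every target; μ and σ are the mean and population standard
  deviation of the pooled raw/N_A values.  All-zero backgrounds raise an
  error instead of silently producing infinite Z-scores.
* **Z-score.** `((raw/N_A) − μ) · N_A^0.335 / σ`.  The 0.335 size exponent
  is treated as a fixed constant of the method.
* **Diversity weight λ.** The within-set statistic is the sum of pairwise
  ligand Tanimoto values ≥ 0.45 (the same threshold as query scoring, so λ
  and raw scores share one scale) over the N_AA = N·(N−1)/2 unordered
  distinct pairs — self-pairs are excluded because they would only inflate
  apparent uniformity.  Two conventions are in circulation depending on
  which way the ratio is taken; both are implemented:
  * `stated_range` (default): λ = (N_AA / raw_AA)^0.335, clamped to
    [1, 100].  Uniform sets get λ ≈ 1, very diverse sets λ > 10, and the
    weighted score Z/λ *penalizes* diverse sets, whose unweighted Z-scores
    behave like inflated random scores.
  * `printed`: λ = (raw_AA / N_AA)^0.335, the literal inverse, which maps
    diverse sets *below* 1; under this form the combination is Z·λ.  It is
    kept selectable so the two behaviors can be compared directly.
* **E-value.** `E = n_targets · exp(−Z)` — the expected number of equally
  good hits by chance.  This functional form is a reconstruction from the
  two properties the statistic must have (proportionality to database size;
  exponential decrease in Z); predictions with E > 1 are treated as random
  and dropped by default.  Results are ranked by weighted Z.

## Synthetic study chemistry

The fixture generators build real, valid molecules — scaffold templates
decorated with enumerated substituents — so fingerprinting, fragmentation
and conformer generation are exercised genuinely rather than mocked.

* **ATC library**: 4 congeneric series × 10 members.  Eleven mutually
  dissimilar two-site scaffold templates are available (pairwise member
  similarity < 0.3 on unfolded circular fingerprints); each series fixes
  one site and varies the other.  Generation *verifies* the planted signal
  (minimum within-series similarity > maximum cross-series similarity) and
  retries with fresh substituents, so a passing build is a guarantee, not
  an accident.
* **Target database**: 10 targets × 25 ligands, plus 20 held-out congeners
  and 11 scaffold-matched decoys per target.  Each target's congeners share
  the scaffold and one fixed decoration and differ in a single substituent
  drawn from a programmatic pool (~64 core / ~129 wide), which is what makes
  them a congeneric series rather than a loose chemotype.  Six targets are
  uniform (core pool), two medium (wide pool), and two diverse (wide pool
  spread over *two* scaffolds, 60/40) — the diverse targets use the largest
  scaffolds so the shared core still dominates the fingerprint.  Decoys use
  the target's scaffold but an independent decoration, giving a background
  that is neither trivially zero nor indistinguishable from true actives.
  The interaction table deliberately contains ~20% too-weak affinities
  (> 10 000 nM, log-uniform up to 1 μM), two disallowed binding-type rows
  and one 4-ligand target, with a manifest of exactly which rows curation
  must reject.  Affinities of true actives are log-uniform on [1, 10 000] nM.

What the fixtures do **not** emulate: the scale of real interaction
databases (hundreds of thousands of compounds), their heavy-tailed and
correlated similarity distributions, multi-target promiscuity, assay noise
and unit heterogeneity, or multi-domain targets with distinct binding
sites.  Passing the planted-recovery tests therefore demonstrates that the
statistics and plumbing are implemented correctly and that the method
recovers a clean signal; it does not certify real-world accuracy figures.

## Problem sizes in tests and the acceptance script

The evaluation runs use 5 conformers per molecule: the fixture congeners
are small and fairly rigid, and the leave-one-out accuracy is already
saturated at that ensemble size, so larger ensembles only add cost.  The
library default remains 100 conformers.  Oracle-equivalence checks run on
500 random assignment matrices and 100 random ≤ 6-atom toy conformer pairs,
where exhaustive enumeration is exact and fast.

## Known limitations

* Charge neutralization is rule-based (simple acids/bases); exotic charged
  species may keep charges a more elaborate protocol would remove.
* The greedy atom mapping is not guaranteed to find the maximum-cardinality
  mapping (the optimal mode is); in practice the two agree on the fixture
  chemistry.
* 3D scores are comparable only within one build of a library: a different
  conformer generator or force field shifts the ensemble.
* λ's clamp at 100 is arbitrary but only reachable for target sets with *no*
  within-set pair above the similarity threshold, where any diversity
  weight is essentially undefined.
* The E-value form is a reconstruction (see above); absolute E-values
  should be read as an order-of-magnitude significance indicator.
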