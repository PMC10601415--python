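# Methods

This note records the models, conventions and design choices behind
vsbench, in the order the pipeline applies them.

## Sanitization and the molecule model

A library record is a SMILES string with a stable id; everything downstream
keys on the id. Sanitization (RDKit-backed) does three things, in order:
keep the largest fragment by heavy-atom count (salt stripping; ties broken
by the lexicographically smallest canonical SMILES), normalize
charge-separated depictions of the same functional group (nitro drawn as
`N(=O)=O` vs `[N+](=O)[O-]`, N-oxides, azides, ...) to one canonical form,
and canonicalize. Duplicates — records whose canonical SMILES coincide —
are removed keeping the first occurrence in file order, which makes the
operation deterministic and idempotent. Records that cannot be parsed or
normalized go to a failure list and are reported, never fatal: a screening
run over millions of vendor molecules should not die on one bad entry.

## Rotatable bonds and load balancing

The flexibility descriptor is the classic rotatable-bond pattern
`[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]`: an acyclic single bond whose two atoms
each have heavy-atom degree ≥ 2 and are not part of a triple bond. Amide
C–N bonds *count* as rotatable under this rule. The choice is deliberate:
only the relative ordering of molecules matters for load balancing, the
strict pattern is cheap and toolkit-independent, and backends that need the
amide-excluding variant can substitute their own SMARTS
(`vsbench.molecules.ROTATABLE_BOND_SMARTS` is the single point of truth).
The test suite checks the implementation against an explicit bond-by-bond
enumeration oracle rather than trusting the pattern.

Chunking deals the library into `n_chunks` worker slices (one per core, by
default). The balanced planner sorts by rotatable-bond count descending
(ties by id ascending, for determinism) and deals round-robin: sorted
position `p` goes to chunk `p mod n`. For a complete deal this guarantees
chunk 0 carries the largest rotatable-bond sum, the last chunk the
smallest, and the spread between them never exceeds the library's count
range — so per-chunk conformer/docking cost is evened out, which is the
point: each pipeline stage barriers until every chunk finishes, and a
single flexible-molecule-heavy chunk would stall the whole run. A snake
(boustrophedon) deal is available behind a flag but is not the default; the
plain deal is the simpler, more predictable rule. When `N mod n ≠ 0` the
earlier chunks receive one extra molecule, keeping sizes within ±1. The
sequential planner (contiguous blocks, sizes within ±1) exists as the
baseline the balanced planner is compared against.

Parallel dispatch uses a thread pool: stages are required to be pure
functions of their chunk, so results are identical to serial execution
under any worker scheduling, and the stage contract (not the executor) is
what tests verify. External engines run as subprocesses, so threads impose
no interpreter bottleneck where it matters.

## Ligand preparation

Preparation runs a fixed stage order — tautomer generation, ionization/
protonation-state enumeration, partial charges, conformer generation, final
deduplication — over a backend that implements the per-stage contracts
(records in → records out, pure, deterministic given the seed). The stage
chemistry itself is delegated: the identity backend passes records through
(for contract tests and for engines that take raw SMILES), and the RDKit
backend provides a working open-source implementation (tautomer
enumeration capped at 8 forms per input, uncharging as the protonation
cleanup, Gasteiger charges, seeded ETKDG conformers). The final dedup
exists because expansion stages can emit the same structure twice (two
tautomers that canonicalize identically); it keeps first occurrences, and
per-stage input/output/failure/removal counts are reported so the molecule
accounting balances end to end.

`n_conformers` defaults to 200. Ranking quality rises steeply up to ~100
conformers and then flattens, while preparation and docking time keep
growing roughly linearly, so 200 is the accuracy-versus-time compromise
adopted as the package default; it is recorded in every run manifest and is
a single config key.

Protein preparation is a contract with two knobs the pipeline relies on:
restricting output to one co-crystallized ligand by its three-letter code
(a missing code is a selection error), and alternate-location handling —
`primary` must yield exactly one output file, `enumerate` one per altloc
set. The bundled passthrough backend implements both over plain PDB text
with the naming convention `<stem>__<LIG>__alt<X>.pdb`; real preparation
tools slot in behind the same interface.

PDB entry selection pins "good structure" to the three criteria that
matter before docking: X-ray method, a bound ligand present, and lowest
resolution, with pdb_id as the tie-break. Entry metadata loads from JSON so
the filter is testable offline.

## Engines and ranking

An engine adapter declares its score direction (`higher_is_better` for
similarity-type scores, `lower_is_better` for docking energies) because
fused pipelines mix both; all ranking logic consumes the declared direction
rather than guessing. Ranks are assigned by sorting scores under the
direction with ties broken by id ascending — deterministic, and invariant
under strictly monotone score transforms. Per-molecule failures become
failure lists, not errors. Ranking the concatenation of per-chunk tables
equals ranking an unchunked run, so chunk count never changes results.

The toy similarity engine scores Morgan-fingerprint (radius 2, 2048-bit)
Tanimoto similarity to a reference molecule; it exists so end-to-end runs
and tests need no licensed software, not as a claim about screening power.
External tools attach through a templated shell command
(`{chunk_file}`, `{target_file}`, `{out_file}`) returning `id,score` CSV.

## Metrics

AUC uses the midrank Mann-Whitney form rather than trapezoidal ROC
integration: identical for untied data, well-defined with ties (each tied
active–decoy pair contributes ½). EF at fraction `x` selects
`n_top = ⌈x·N⌉` molecules under the deterministic ranking and computes
`(a_top/n_top)/(n_A/N)`; `EF(1.0) = 1` identically, and the ceiling (rather
than floor) cutoff guarantees `n_top ≥ 1` for any nonempty haystack. An
odds-ratio variant (`literal_odds_ratio=True`) divides top-fraction
active:decoy odds by whole-haystack odds, for users who read "ratio of
actives versus decoys" literally; it is not the default because the
standard form is what the decoy-design literature and the ~`1/x`-capped
published EF values correspond to.

Molecules an engine failed to score are ranked worst (below every scored
molecule, tied among themselves, id tie-break). This is the pessimistic
convention: an engine that fails on half the actives should not look good
on the half it liked.

Consensus fusion offers `rank_sum` (sum of per-engine ranks; the default,
equivalent to mean-rank Borda fusion) and `best_rank` (minimum rank, which
rewards molecules any single engine loves). Both are legitimate reading of
"consensus scoring" in the VS literature; neither is claimed to be uniquely
correct, which is why both ship.

Method comparison is a paired two-tailed t-test on per-target differences
(scipy's `ttest_rel`), refusing to produce a statistic when the differences
have zero variance.

Reported tables round AUC to 2 decimals and EF to 1 decimal, with exact
integers printed without a trailing `.0`; the `average` row is the
arithmetic mean of the (unrounded) column values rounded at the same
precision, half away from zero.

## Synthetic benchmarks

The generator emulates the composition of an average DUD-E target: 224
actives and 50 decoys per active (11 424 molecules), with planted scores —
actives ~ N(μ, σ), decoys ~ N(0, σ), higher better. For two Gaussians the
expected AUC has the closed form Φ(μ/(σ√2)), which gives the package an
analytic target for parameter-recovery tests: over replicates, the mean
empirical AUC must sit within 3 standard errors of the closed form, and at
μ = 0 within 3 SE of 0.5. Molecules are emitted as unique valid linear
heteroatom chains (an N-terminated {C,O} binary-coded body with an S
terminator — asymmetric ends so a chain can never collide with its own
reversal after canonicalization); the chemistry is deliberately trivial
because the planted-score benchmarks measure the *metrics and plumbing*,
not any screening engine.

What the synthetic benchmark does **not** emulate: property matching
between actives and decoys, chemical-series structure among actives,
score distributions of real docking functions (heavy tails, engine
failures), or inter-target difficulty variation. Passing synthetic
benchmarks therefore validates the statistical machinery and the pipeline's
determinism, not the screening power of any engine on real targets; the
bundled published reference tables are included precisely so the
aggregation and comparison code can also be exercised on real screening
numbers.

## Determinism and seeds

One top-level seed in the config is expanded into per-stage sub-seeds via
CRC-32 of `"{seed}:{tag}"` (stable across processes and platforms, unlike
Python's salted `hash`). Everything stochastic — synthetic generation, the
random control engine, conformer embedding — draws from a seeded generator,
and all orderings (sanitization, chunk deal, rank ties, merges) are
deterministic, so two runs from the same config and seed produce
byte-identical summary artifacts. This is a hard requirement: benchmark
results must be reproducible across users and machines, and the test suite
checks it at byte level.

## Problem sizes in tests and the acceptance script

The default test run uses small haystacks (tens of actives) for end-to-end
paths and full-size 11 424-molecule haystacks for parameter recovery (200
replicates per signal level), 1 000 random instances (N ≤ 200) for the
metric-oracle equivalence, and 500 random fixtures for the chunking
invariants — sizes chosen so the whole suite completes in well under a
minute per property while still estimating each quantity to far better
precision than the tolerances being asserted. The acceptance script runs
100 full-size replicates at μ = 2 and 50 at μ = 0, 300 oracle instances,
and one full-size end-to-end benchmark run executed twice for the
determinism check.

## Known limitations

* No BEDROC/ROCE/pROC metrics and no bootstrap confidence intervals on AUC
  (extension points, deliberately out of scope).
* The bundled reference tables carry their published rounding; their
  `average` rows were evidently computed from unrounded source metrics, so
  recomputing averages from the rounded per-target values can differ from
  the published average by one unit in the last printed digit (documented
  cell by cell in the acceptance tests).
* Protein preparation ships only the contract-level backend; real
  structure preparation (protonation, loop building) requires an external
  tool behind the adapter interface.
* The live ChEMBL/PDB fetchers are thin optional wrappers; only their
  recorded-fixture parsing paths are tested.
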