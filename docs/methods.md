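# Methods

## Scope and model

`emcdock` implements rigid-body ligand–receptor docking: a pose is a
six-component transformation descriptor (tx, ty, tz in Å; rx, ry, rz in
radians), realized as the extrinsic X-then-Y-then-Z rotation
R = R<sub>z</sub>·R<sub>y</sub>·R<sub>x</sub> about the ligand
conformation's centroid followed by a translation. The centroid pivot
keeps the translational and rotational search dimensions approximately
decoupled; angles are stored unwrapped. Ligand flexibility is
represented only through discrete conformations docked independently;
there are no torsional degrees of freedom.

## The scoring function

The pairwise energy is a sum of four gated terms (steric ramp/well,
screened tapered Coulomb, linear desolvation, triangular hydrogen-bond
well); the README states the formulas. Design properties that matter:

- **Soft core.** Every term is finite at d = 0: the steric clash is a
  linear ramp capped at S·ε<sub>ij</sub> and the Coulomb denominator is
  clamped at 1 Å. Rigid-body poses routinely contain small overlaps; a
  divergent potential would make ranking meaningless.
- **Compact support.** Each term is exactly zero beyond its cutoff, so
  the energy of a well-separated pair is exactly 0 — important both for
  testability and for the planted-optimum constructions below.
- **Intentional discontinuity.** The repulsive ramp meets the well floor
  at d = r<sub>ij</sub> with a jump of (S+1)·ε<sub>ij</sub>. The
  boundary rules are fixed (repulsion strictly d < r<sub>ij</sub>, well
  half-open, hydrogen-bond window closed) so the discontinuity's
  location is unambiguous and assertable.
- **Units.** Energies are arbitrary ("EU"); only the ranking matters.

Default global constants: well width w = 1 Å, repulsion scale S = 10,
electrostatic cutoff 8 Å, Coulomb constant 332.0637 EU·Å/e², dielectric
4, desolvation cutoff 6 Å and scale 0.2 EU, hydrogen-bond window
2.2–3.5 Å. These are physically conventional magnitudes and are all
overridable through the forcefield file. The packaged table defines
eight atom types (apolar and aromatic carbon, donor/acceptor nitrogen
and oxygen, their charged variants, amphoteric polar oxygen, sulfur);
larger tables (~35 types at production scale, ~1 KB as a lookup table)
load through the same text format.

## Branch-free kernel and accounting

The scalar scoring function branches on distance and type for every
pair, which is hostile to data-parallel execution. `compute_energies`
therefore evaluates every term for every pair unconditionally and
multiplies each by a 0/1 gate (predication), processes poses in
structure-of-arrays blocks (`block` poses per inner pass), gates on
squared distances where possible, and gathers per-type parameters by
type id inside the kernel rather than packing them per atom. Because the
masked path executes the same operations regardless of data, its cost is
a constant F = 46 floating-point operations per atom–atom interaction
(counting comparisons as 1 and fused multiply-adds as 2); the metrics
object asserts interactions = poses × ligand atoms × receptor atoms
exactly and flops = interactions × F. The scalar branched implementation
is retained as the test oracle, together with a counter showing its
executed-term count *is* data-dependent.

**Precision.** Coordinates, descriptors and stored energies are
single-precision (the 16-byte atom record is three float32 coordinates
plus an int32 type id). Term arithmetic and accumulation inside both
the masked kernel and the scalar reference are performed in double on
the float32-quantized inputs, with per-ligand-atom partial sums. This
makes the masked-vs-branched comparison and the block-size invariance
limited only by reduction order (observed agreement ~1e-15 relative,
asserted at 1e-5/1e-4), while keeping the data layout single-precision.
One consequence: identical inputs give bit-identical energies for every
block size in practice.

## Search (Evolutionary Monte Carlo)

Fixed number of generations, no early stopping. Generation 0 is uniform
over the search box and angle bounds. Each subsequent generation copies
the n_parents best poses unchanged (elitism) and fills the rest with
children: a parent chosen uniformly at random plus independent Gaussian
noise per component, σ_t = 1 Å and σ_r = 10° by default — the natural
search resolution of the scoring function's well widths — decaying by
0.75 per generation. Defaults are 8 generations × 65,536 poses with 128
parents (a parent count of order 10² that divides the population).
Elitism makes the best energy non-increasing across generations, which
the trace asserts on every run; it also means re-evaluated parents must
score identically, which the deterministic kernel guarantees.

Child translations are clamped to the search box: the box is a hard
statement of where the docking site is, and unbounded mutation walks
would otherwise let the population drift into receptor regions the user
excluded. Angles are not clamped (the full circle is usually the bound,
and descriptors are unwrapped by contract).

**Random numbers.** Streams are counter-based: output n of stream s
under seed g is a SplitMix64-style mix of (g, s, n) (golden-ratio
increment, MurmurHash3 finalizer). Each (generation, pose-slot) owns a
stream, so results are independent of evaluation order and fully
reproducible from the seed; normals use Box–Muller with σ = 0 returning
the mean exactly while still advancing the counter (the draw schedule
is sigma-independent). Statistical quality gates: chi-square uniformity
over 100 bins at α = 0.01 and second-moment checks at n = 10⁵.
Screening derives one sub-seed per ligand conformation by mixing the
run seed with a hash of the ligand's name and the conformation ordinal,
which is why shuffling a library file changes nothing.

## Selection

Best-K selection is the data-parallel two-stage algorithm, kept even
though a serial partial sort would suffice, because the algorithm itself
is part of the engine's design: stage 1 splits the energies into bins of
B = 1024 (configurable power of two) and sorts each with Batcher's
bitonic compare-exchange network, padded to a power of two with +∞
sentinels; stage 2 emits, K times, the minimum among the current bin
heads. Ordering is lexicographic (energy, original index) — the index
tie-break makes selection deterministic — and exhausted bins present +∞,
so K > B is safe. NaN energies are rejected: a compare-exchange network
cannot order them.

## File formats

Tripos Mol2 is the text input dialect: only `@<TRIPOS>MOLECULE` and
`@<TRIPOS>ATOM` are interpreted; `BOND` and other sections are tolerated
and ignored (rigid-body docking needs no connectivity). Declared atom
counts are validated, errors carry line numbers, and multi-molecule
files are the library format (molecules sharing a name are conformations
of one ligand). Hydrogens are dropped by default — scoring uses
non-hydrogen atoms — and SYBYL types map to dense forcefield ids through
a two-column text table.

The binary conformation format (BCF) is little-endian: per ligand a
12-byte header (magic `BCF1`, uint32 ligand id, uint32 atom count)
followed by 16-byte atom records (three float32 coordinates + int32
type id). Result records serialize the six-float32 descriptor (24
bytes) and the uint32 ligand identifier (4 bytes) exactly, plus a
float32 energy extension so rankings are self-contained; a TSV
companion reports angles in degrees. All round trips are bit-exact and
asserted as such.

## Synthetic data: what it emulates and what it does not

All tests and benchmarks run on generated data; nothing is downloaded.

`make_random_ligand` emulates the geometry envelope of screening
compounds: 15–40 non-hydrogen atoms in a 5 Å ball with ≥ 1.2 Å
separation, types drawn from the packaged table. It does **not** model
valence, bond lengths beyond the separation floor, or realistic
chemistry — passing tests demonstrate the engine's search and scoring
machinery, not predictive accuracy on real complexes.

`make_planted_scenario` builds a docking problem whose answer is known:
for each ligand atom posed at the planted descriptor, one complementary
receptor atom is placed at that pair's energy-optimal distance, plus
far-away decoy atoms. The construction has to be done carefully for the
planted pose to be a genuine optimum of the *total* energy rather than
of each pair separately, and three choices follow from that requirement:

- Placement distances avoid the steric discontinuity (they sit 0.05 Å
  inside the well when the pair optimum is the well floor), since
  float32 rounding at an exactly-critical distance would flip contacts
  onto the repulsive side.
- Partner directions are sampled over the outward hemisphere and chosen
  to maximize clearance from all other ligand atoms and partners. Purely
  radial contacts would leave rotations as soft modes (tangential motion
  changes pair distances only to second order) that the smooth
  desolvation background can exploit, displacing the optimum several
  degrees from the planted pose; off-radial contacts make rotations
  stiff. Partner–ligand complementarity uses the short-range terms only:
  charged ligand atoms get neutral hydrogen-bond partners, because the
  soft-core Coulomb term is monotone toward contact and would move the
  pair optimum to an unphysical overlap.
- Decoys are neutral, ≥ 8 Å from the pocket, ≥ 5 Å from each other, on a
  12–16 Å shell — isolated background atoms that cannot cluster into an
  alternative pocket.

With these rules, derivative-free refinement started at the planted
descriptor moves ≤ 0.03 Å and ≤ 1° — the planted pose is the optimum it
claims to be, verified independently of the search.

`make_benchmark_ligand` is the pose-recovery test compound: drug-sized
(35 heavy atoms) and amphiphilic, one apolar face and one face of
alternating donors/acceptors. Pose recovery is only a well-posed task
for ligands whose contacts determine their orientation — small fragments
dock ambiguously in any engine — and the amphiphilic pattern gives the
long-range desolvation term a preferred orientation (a funnel), as real
binding epitopes do, while the donor/acceptor pattern pins the final
pose through short-range complementarity.

## Benchmark scales and observed behaviour

The recovery benchmark runs the search at 8 generations × 4,096 poses
(a 16× reduction of the production 65,536-pose population, sized for
seconds-per-run testing) over 20 seeded scenarios, scoring a run as a
success when the best descriptor is within 0.5 Å translation and 5° per
angle of the planted pose. Measured recovery under the default search
parameters is ~80–85% at this reduced population across independent
seed sets, rising with population size (≈ 95% at the full 65,536) —
the refinement of the last few degrees is population-limited, and
per-run diagnostics show the remaining misses are search shortfall
(the recovered pose sits a few degrees from the verified optimum with
energy left unexploited), not scenario error. Parent counts below the
default 128 lower the rate further: parent diversity, not selection
pressure, is the binding constraint at this scale. The acceptance suite
asserts recovery at a ≥ 90% threshold, which the engine meets only at
population scales above the reduced benchmark; the corresponding test
is expected to fail at 4,096 poses and documents the measured rate.

Unit-test problem sizes elsewhere (populations of 10²–10³, receptors of
tens of atoms, screens of 10 single-conformation ligands at 1,024–4,096
poses) were chosen so the whole suite completes in a few minutes on one
CPU while still crossing every production code path; the screening
retrieval test runs its binder at the full 4,096 × 8 budget because
retrieval, unlike determinism, requires a converged search.

## Known limitations

- The scoring function is a structurally faithful stand-in with
  conventional constants, not a parameterization fitted to experimental
  affinities; absolute energies mean nothing outside ranking.
- Rigid-body only; conformer generation, torsional sampling, and
  receptor flexibility are out of scope.
- The kernel is vectorized NumPy on one CPU; the design (predication,
  SoA blocks, constant folding, binned selection) mirrors data-parallel
  hardware but no GPU execution is provided.
- Wall-clock throughput (interactions/s) is logged for information only
  and is never asserted — it is hardware-dependent.
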