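# Methods

## The model

`animatphi` simulates *animats*: virtual organisms controlled by Markov
Brains — networks of genetically encoded logic gates over 16 binary nodes
(4 sensors, 2 motors, 10 hidden), updated synchronously. Each gate maps a
pattern over up to four input nodes to a pattern over up to four output
nodes via a `2^i × 2^o` row-stochastic table. Three gate families make up
the default repertoire:

- **deterministic** gates (one certain output pattern per input pattern);
- **decomposable** probabilistic gates, whose per-input-pattern output
  distribution is the outer product of independent per-output-bit Bernoulli
  probabilities ("factors"). Decomposability — output bits sharing no
  information within a gate — is a prerequisite of the
  information-integration analysis;
- **decomposable feedback** gates, which learn during a lifetime: each
  update records the (input, output) decision in a ring buffer of up to 3
  time depths, and when the gate's positive (negative) reinforcement node
  is 1 after an update, every remembered decision's factors move by a
  per-depth delta toward (away from) the emitted bit values, clamped to
  `[p_min, 1 − p_min]`. Because factors are updated individually and rows
  are rebuilt from them, decomposability survives arbitrarily many updates.
  Reinforcement is *internal*: the brain itself must evolve wiring that
  drives those nodes — no external supervisor exists.

A legacy non-decomposable feedback gate (raw row entries shifted and
renormalised) is included behind a flag purely for comparison; it is
excluded from the default repertoire because its rows generally do not
factorise.

### Update semantics

Per step: sensors are written into nodes 0–3; every gate reads the time-`t`
state and samples its output; outputs OR-combine into the `t+1` buffer.
Motor/hidden nodes written by no gate decay to 0. Sensor nodes are
environment-owned: gate writes aimed at them are discarded and their values
persist through the update (the environment rewrites them next step). This
keeps reinforcement nodes wired to sensors functional — the new state,
from which feedback triggers are read, still carries the current percept —
and makes sensors self-copying free variables under the uniform-state TPM
construction. Feedback is applied after the state update, positive before
negative, so a gate's own consequences can trigger learning with one-step
latency.

### Genetic encoding

A genome is a string of integers in [0, 255] (length 1,000–20,000;
initial genomes: 5,000 loci, uniform random, with 4 start codons planted so
founders are rarely gateless). The two-locus start codon (42, 213) opens a
gene encoding, in order: gate type, arities `i`, `o`, input and output node
addresses (modulo 16), the payload (output patterns for deterministic
gates; `2^i × o` factor loci mapped by `v/255` for decomposable gates), and
for feedback gates a block with the two reinforcement node addresses, the
history length (`locus mod 4`) and three positive plus three negative
per-depth deltas mapped to `[0, delta_max]`. Genes may overlap; truncated
genes are skipped. Mutation applies per-locus point mutations (default
0.005) plus whole-gene duplication and deletion (default 0.05 each),
skipping a structural mutation that would violate the length bounds.

Defaults chosen where the encoding was open: `delta_max = 0.5` and
`p_min = 0.01` keep tables stochastic and learning reversible; per-depth
deltas are encoded separately but drawn from the same genome block.

## The task

A 64×64 lattice (desk profile: 16×16) with border walls and ~5% interior
obstacles; a uniformly drawn goal cell; Dijkstra distance and direction
fields over the 4-neighbourhood (scipy's csgraph solver; arrow ties broken
in fixed N, E, S, W order for determinism). The animat senses only the
relation of its heading to the arrow under it (one-hot: idle / right /
forward / left; a 180° arrow is signalled as a right turn, and the idle bit
fires only on arrowless cells). It emits one of four abstract actions A–D;
one of the 24 action→result bijections (enumerated once, in lexicographic
order) translates actions into {turn left, turn right, idle, forward}.
Forward into a wall is a no-op. Reaching the goal scores a point and
respawns the animat at a uniformly drawn cell at exactly the spawn distance
(32; desk: 8 — the same half-width ratio) with uniform random heading.
Fitness `Gtotal` sums goals over the mapping variants, with brain state
*and* learned tables reset before each variant so every mapping is learned
from a naive state. Lifetimes are 512 steps (desk: 256).

## Evolution

A generational GA: tournament selection (size 2, ties uniform), offspring
replace the whole population, no elitism, no crossover. One world is built
per replicate and reused across generations (a config switch allows
re-randomising). Every individual's parent pointer, fitness and genome hash
are archived per generation; genomes are kept for all ancestors of the
living population, so the line of descent (LoD) — the ancestor chain of a
random final individual — and the most recent common ancestor are always
reconstructible. An evolved animat is an *elite performer* if its `Gtotal`
with feedback enabled is at least twice its `Gtotal` with feedback disabled
(paired episode seeds) and non-zero.

Scale profiles: the `paper` profile mirrors the published conditions
(populations of 100, 200,000 generations, 200 replicates, all 24 mappings
per generation); the `desk` profile preserves that structure at
single-workstation cost (populations of 50, 2,000 generations, 10
replicates, 6 mappings resampled per generation for fitness, all 24 for
final evaluation). The problem sizes used by the test suite and the
acceptance script are the desk profile or smaller; they are stated in each
test.

## Integrated information

For node set `X = (X^(1), …, X^(n))` across one step,

    Φ_atomic = Σ_i H(X_t^(i) | X_{t+1}^(i)) − H(X_t | X_{t+1})

computed in bits with the plug-in convention `0·log 0 = 0`. The equivalent
assembly `I(X_t:X_{t+1}) − Σ_i I(X_t^(i):X_{t+1}^(i)) + Ī` with
`Ī = Σ_i H(X_t^(i)) − H(X_t)` is implemented separately with its own sums
and serves as a permanent numerical cross-check (agreement within 1e-9 is
asserted in the tests). Partition-based Φ variants (minimum-information
partitions, Bell-number enumeration, main-complex search) are out of scope.

Two sources for the joint distribution:

- **traces**: consecutive state pairs recorded from a behaving animat
  (maximum-likelihood plug-in; no bias correction — at 512-step lifetimes
  over 2^16 states the plug-in estimate is biased, which is acceptable for
  the comparative analyses it feeds and is flagged here);
- **TPMs**: the frozen brain's transition matrix at one instant. With the
  uniform (maximum-entropy) current-state distribution this is **ΦmaxH**,
  measurable at any point of a lifetime. TPMs are exact (enumeration of
  the joint gate-outcome space, OR-aggregation, default-0) when `n ≤ 12`
  and total gate output bits ≤ 20; otherwise they are estimated by
  stochastic sampling, default 64 draws per start state, with learning and
  history recording disabled during measurement. Sampling error shrinks as
  `O(k^{-1/2})`; the suite checks the 100 → 10,000 draw ratio.

Φ is computed over all 16 nodes by default; excluding sensors (which are
self-copying free variables under uniform `H_t`) is an explicit
configuration choice (`node_set="exclude_sensors"`), implemented by
clamping sensor inputs to 0 and marginalising sensor-directed outputs.

ΦmaxH trajectories snapshot the gate tables every 50 lifetime steps
(desk: 25), including birth (t = 0), giving `⌊lifetime/stride⌋ + 1`
checkpoints; the ordinary-least-squares slope (free intercept) of ΦmaxH
against time is the lifetime-change proxy. A brain without feedback gates
has one TPM for its whole life, so its analytic trajectory is exactly flat
— asserted to 1e-12.

## Synthetic fixtures and what they show

All inputs are generated internally. The fixture generator provides
closed-form anchors: the independent-copy pair (Φ = 0), the swap pair
(Φ = 2 bits), the XOR broadcast (Φ = 1 bit), a fair-coin node, a feedback
probe whose reinforcement nodes are sensors, a straight corridor where an
oracle policy scores exactly 512/32 = 16 goals per episode, and a 5×5 open
arena with a hand-checkable Dijkstra field. Passing tests on these show the
machinery is correct at desk scale; they do not reproduce the published
cluster-scale statistics (13/200 elite replicates and the reported
regression coefficients required 200 replicates of 200,000 generations),
which are replaced by directional and property-based checks: the LoD gains
`Gtotal` in ≥ 9/10 desk-scale seeds, and evolved final bests perform at
least as well with their feedback mechanism as without it. Because the
archived per-generation fitness of the desk profile is a single draw over
a 6-mapping subset — not `Gtotal`, which is by definition pooled over all
24 mappings — both checks use proper estimators: the LoD gain re-evaluates
the generation-0 and final LoD members' true `Gtotal` (all 24 mappings,
mean of three evaluation seeds), and the learning comparison is a paired
design (identical episode seeds per pair, 6 repetitions over all 24
mappings) whose mean difference must not fall significantly (2 SE) below
zero.

## Numerical and design choices

- Log base 2 throughout; Φ in bits. Row-stochasticity enforced to 1e-9;
  decomposability tested by outer-product reconstruction to 1e-9.
- Φ_atomic ≥ 0 is *not* asserted in general (the plug-in estimate can be
  negative); instead Φ = 0 is asserted exactly for systems whose TPM
  factorises over nodes.
- All randomness flows through `numpy.random.Generator`; identical seeds
  give byte-identical archives and Φ tables. A numba-compiled flat-array
  engine executes the hot loops (episodes during evolution, TPM sampling);
  it mirrors the reference Python semantics and the suite asserts
  agreement — exact for deterministic brains, distributional for
  stochastic ones. The direct genome→engine parser is asserted
  array-identical to the object path.
- Motor bits decode to actions as `m0·2 + m1` (00→A … 11→D). Dijkstra ties,
  mapping enumeration order, and the N, E, S, W neighbour order are all
  fixed for reproducibility.
- When both reinforcement nodes fire in one update, positive feedback is
  applied before negative (the order is otherwise unconstrained).
- Fitness-mapping subsets are redrawn each generation (shared by the whole
  population) so lineages cannot overfit one subset of the 24 variants.

## Known limitations

- Trace-based Φ at 16 nodes is strongly undersampled at single-lifetime
  lengths; use it comparatively, not absolutely.
- Sampled ΦmaxH inherits plug-in bias from finite draws per state; the
  default (64) trades bias against the cost of the 2^16-state sweep.
- The desk profile demonstrates direction, not effect sizes; quantities
  such as elite counts are stochastic and are reported, never asserted.
- Worlds are static within a replicate by default; the published runs'
  world-regeneration policy is not stated and both options are exposed.
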