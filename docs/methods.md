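# Methods

## Model

A signed directed network G(V, E) induces a synchronous Boolean model. Node
states are x_i ∈ {0, 1}; every node updates simultaneously by the
inhibitor-dominant rule: active iff at least one retained activator is
active and no retained inhibitor is. The logic is encoded algebraically
(AND as product, OR as a + b − ab, NOT as 1 − x), so the update of a
regulated node is x′ = OR(activators) · (1 − OR(inhibitors)), with the
empty-activator OR equal to 0 and the empty-inhibitor factor equal to 1.
Both encodings are implemented and their exhaustive equality on all 2^n
states of small networks is a standing test.

Two conventions cover cases the regulatory rule leaves open:

* **Orphaned regulation.** A node whose activators have all been pruned
  away (but which had regulators in the PKN) evaluates to constant 0 —
  the strict reading of "at least one activator". This also removes the
  degenerate optimum in which pruning every edge would turn every state
  into a fixed point.
* **Input nodes** (in-degree 0 in the *reference* PKN) hold their state,
  x′ = x. They model external stimuli or unmeasured regulators; forcing
  them to 0 would contradict phenotypes in which they are active. The flag
  is recorded when rules are built from the PKN and inherited by every
  pruned subnetwork, so pruning cannot promote an internal node to an
  input. `inputs_hold_state=False` disables the convention and applies the
  strict rule everywhere.

Trajectories iterate the update until a fixed point (x′ = x), a revisit of
any earlier state (a cyclic attractor, any period ≥ 2), or a step cutoff
(`max_steps`, default 1000), after which the trajectory is classed
truncated. State identity is exact byte equality over the canonical sorted
node order, so detection is reproducible across platforms. `steps_taken`
counts updates to first reach the attractor state; certifying a fixed point
costs one additional (uncounted) update, so a trajectory needing k updates
is only classified fixed when `max_steps ≥ k + 1`.

The didactic three-node system (a = b ∧ c, b = ¬b, c = a ∨ b) uses a
bespoke AND of two activators that the OR-of-activators rule cannot
produce; it ships as an explicit polynomial model satisfying the same
update protocol and serves as a cycle-detection oracle (its negation
self-loop denies it any fixed point; all 8 trajectories cycle).

## Fitness

Each phenotype φ seeds the initial state; network nodes without a phenotype
value follow the fill policy — `zero` (default, deterministic) or `random`
(Bernoulli(0.5), seeded). If the reached attractor α is a fixed point, the
mismatch is the normalized Hamming distance h over the *scored genes*; the
fitness over N_p phenotypes is f = 1 − (Σ h_i)/N_p. Any cyclic or truncated
trajectory sets f = 0 (truncation maps to the same score as cycling, which
keeps the population size constant instead of discarding candidates).

N_g — the normalization of h — is the number of scored genes: measured
genes present in the network. During cross-validation only the training
genes are scored while optimizing; evaluation afterwards scores the full
profile. Phenotype genes absent from the PKN are retained in the data
containers but excluded from simulation and scoring (logged); pruning never
removes nodes, but user data may be broader than the PKN.

The method rests on the assumption that a state in the basin of a given
attractor is closer (in Hamming terms) to that attractor than to any other;
this is an assumption about biological networks, documented here, not a
property the code enforces.

## Search

Univariate estimation-of-distribution algorithm over the 2^|E| subnetworks:

1. draw `population_size` subnetworks, each PKN edge kept independently
   with `initial_edge_probability` (default 0.5, maximizing initial
   entropy over edge inclusion);
2. score the population and select the `selection_number` best; ties on f
   break by fewer edges (parsimony matches the pruning intent) and then by
   a SHA-1 hash of the sorted edge list, so runs are reproducible;
3. estimate each edge's inclusion frequency *within the selected group
   alone* and sample `population_size − elitism_number` new candidates
   (edge kept iff uniform(0,1) ≤ frequency; the "≤" makes frequency 1
   permanent and frequency 0 removable only on a measure-zero draw). No
   Laplace smoothing by default — raw frequencies can fix edges
   permanently, which is the intended convergence behaviour; a
   `frequency_epsilon` clip is available;
4. append the `elitism_number` best-ever networks (deduplicated by edge
   set; the population is padded with fresh samples if duplicates shrink
   the elite list), and repeat for `max_iterations`.

Defaults: population 30, selection 10, 100 iterations, elitism 5 (the
recommended maximum of half the selection number). Scoring is memoized on
the edge set; the evaluation counter nevertheless counts every candidate
generated, which is the bookkeeping used to equate budgets with the
baseline. A callback receives a snapshot after every iteration, so long
runs can be stopped early with partial results. With elitism ≥ 1 the
best-so-far trace is non-decreasing; identical inputs, config and seed give
bit-identical results.

`random_search_baseline` is the identical loop with step 3 replaced by
fresh draws at `initial_edge_probability` — elitist random search under the
same evaluation budget. The pooled final-population scores of the two modes
are compared with Welch's unequal-variance t-test (scipy); if both samples
have zero variance the limits of the statistic apply (equal means → p = 1,
different means → p = 0), keeping the pipeline total.

## Perturbations

A perturbation instantaneously sets chosen genes to chosen states in the
phenotype's state vector; the network then updates freely (no clamping —
sustained knockouts that override the rule each step are a non-goal).
Because inputs hold their state, flipping an input is persistent while
flipping a regulated node is transient; both follow from the same
instant-flip semantics. The reached attractor is classified against a
target phenotype: non-fixed trajectories are `cyclic_or_truncated`; a fixed
point equal (on the scored genes) to the attractor obtained by relaxing the
*unperturbed* initial state is `stayed_initial`; otherwise the match
fraction 1 − h against the target decides `transition_matched` (≥
threshold) vs `other_attractor`. The threshold is an experiment-level
input, not a constant — exact match, 75 % and 50 % are all used in
practice depending on how sharply the target profile is defined. The
response rate of a network collection is the fraction classified
`transition_matched`.

## Synthetic benchmarks

Real validation cases start from a curated network that already explains
two phenotypes and expand it blindly with literature-mined edges, some
inconsistent with the phenotypes. `generate_planted` emulates exactly that:

1. draw a random signed digraph with `n_inputs` in-degree-0 nodes, every
   regulated node keeping at least one activator (signs ~70 % activating,
   typical of curated regulatory cores);
2. relax random states and their complements until two distinct fixed
   points differ on at least half the regulated nodes; these become the
   phenotypes (complementary seeds emulate Booleanized two-condition
   comparisons without forcing exact complementarity);
3. add `n_spurious` random edges, accepting a candidate only if the
   expanded network no longer holds both phenotypes as exact fixed points;
   spurious edges never target inputs, so the input set of PKN and truth
   coincide. Retry budgets exhausted → error suggesting different sizes.

Construction guarantees score(truth) = 1 and score(PKN) < 1 (waived in the
degenerate `n_spurious = 0` mode used for plain dynamics tests). Two tiers:
`planted_small` (6 nodes, 12 PKN edges) keeps all 4096 subnetworks
enumerable in seconds, so an exhaustive oracle certifies the attainable
optimum in tests and in the acceptance script; `planted_medium` (40 nodes,
240 edges) matches the scale of a mid-sized curated network for
performance-oriented checks. What the planted fixtures do *not* emulate:
measurement noise in the Booleanization, biased literature coverage,
multi-valued expression levels, and phenotypes that are oscillatory rather
than steady — passing tests show the machinery recovers planted structure
under the stated model, not that the model captures any particular
biological system.

## Validation protocols

* **Cross-validation**: repeated random sub-sampling; for each training
  size, `n_splits` (default 10) independent gene splits, one optimization
  per split scored on the training genes, and the full final population
  evaluated on the complete profile (population × splits pooled scores,
  e.g. 30 × 10 = 300). Evaluating on the full profile — not the held-out
  genes alone — is what makes "predicting missing expression values"
  measurable as a single score per network; per-split training/validation
  gene sets are retained for finer breakdowns. Held-out genes fall back to
  the fill policy in the initial state.
* **Sensitivity, missing information**: optimize with chosen genes'
  phenotype values withheld (excluded from scoring and initialized by the
  fill policy), evaluate against the complete original phenotypes.
* **Sensitivity, wrong information**: optimize with chosen genes'
  phenotype states bit-flipped in both the training signal and the initial
  states, evaluate against the original phenotypes. When the two
  phenotypes are exact bitwise complements, flipping every gene merely
  swaps their roles and leaves scores unchanged — an identity used as a
  test on the toggle-switch fixture.

Per-task seeds derive from the root seed through `numpy` `SeedSequence`
spawning (kept below 2^31), so every protocol is reproducible from one
integer.

## Problem sizes in the acceptance script

The script runs the small planted tier: exhaustive enumeration over all
4096 subnetworks, 10 optimization + 10 baseline runs at the study
configuration (30/10/100, elitism 5; 3030 candidates per run), 10-split
cross-validation at half and full training sizes, and perturbation
simulation on the 5 best networks of each optimized run (50 networks),
flipping the initial phenotype's differing input states to the target's
values at threshold 0.75. The perturbation response rate is strongly
instance-dependent (alternative subnetworks explaining the same attractors
need not respond alike), so its value characterizes the drawn instance
rather than a universal constant.

## Known limitations

* Only point attractors are scored; processes whose phenotypes are
  oscillatory are out of scope by construction.
* Only topology is optimized, never the logic functions; regulatory logic
  beyond inhibitor-dominance must be encoded by auxiliary nodes upstream.
* The zero fill policy for unmeasured genes is a convention; with many
  unmeasured nodes the `random` policy plus repeated runs gives a fairer
  picture.
* Frequencies estimated from the selected group alone, with no smoothing,
  can fix an edge's fate early; increase `selection_number` or set
  `frequency_epsilon` if premature convergence is suspected.
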