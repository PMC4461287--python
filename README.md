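# boolprune

Contextualize a signed, directed prior-knowledge network (PKN) to a pair of
observed stable phenotypes by pruning edges until the network's Boolean
model reproduces the phenotypes as fixed points.

## The problem

PKNs aggregate regulatory interactions (activation / inhibition edges
between genes or gene products) reported across many cell types and
conditions. In any *one* biological context — a specific cell type, a
disease state, a differentiation stage — only a subset of those edges is
active, and the surplus edges make the network useless for dynamical
simulation. Given a PKN and Booleanized expression profiles of two stable
phenotypes (e.g. epithelial vs mesenchymal, or the two endpoints of a
differential-expression comparison), `boolprune` searches for subnetworks
whose dynamics explain both profiles, removing the context-inconsistent
interactions.

## The model and the score

Each gene *i* carries a Boolean state *x<sub>i</sub>* ∈ {0, 1}; all nodes
update synchronously under the inhibitor-dominant rule

> *x′<sub>i</sub>* = (∨ activators of *i*) ∧ ¬(∨ inhibitors of *i*)

equivalently, in polynomial form, *x′* = OR(act) · (1 − OR(inh)) with
OR(a, b) = a + b − ab. Nodes with in-degree 0 in the reference PKN are
external inputs and hold their state. Each phenotype φ is injected as the
initial state and relaxed to an attractor α; if α is a fixed point the
mismatch is the normalized Hamming distance
*h* = (1/N<sub>g</sub>) Σ<sub>j</sub> |x<sub>j</sub><sup>φ</sup> − x<sub>j</sub><sup>α</sup>|,
and the fitness over N<sub>p</sub> phenotypes is

> *f* = 1 − (Σ<sub>i</sub> h<sub>i</sub>) / N<sub>p</sub> ∈ [0, 1],

the fraction of gene states the model explains. Cyclic or over-long
trajectories score 0: stable phenotypes are modelled as point attractors.

The search is an estimation-of-distribution evolutionary algorithm: score a
population of random subnetworks, select the top scorers, estimate each
edge's inclusion frequency among them, sample the next population from
those marginals, and carry the best-ever networks forward (elitism). An
elitism-only random search under the identical evaluation budget serves as
the validation control.

## Worked example

```python
import boolprune as bp

inst = bp.planted_small(seed=1)          # 6 nodes, 8 true + 4 spurious edges
print(bp.score_subnetwork(inst.pkn, inst.pkn, inst.phenotypes).f)
# 0.5833333333333334  <- the raw PKN fails to hold the phenotypes fixed

result = bp.optimize(inst.pkn, inst.phenotypes, None,
                     bp.OptimizationConfig(seed=7))
net, f = result.top(1)[0]
print(f, net.n_edges)
# 1.0 4  <- a pruned network with both phenotypes as exact fixed points
```

`f = 1.0` means every measured gene state of both phenotypes is reproduced
by the pruned model's fixed points; the optimizer reached it from a PKN
scoring 0.58. The scripts in `examples/` walk through the four
capabilities: Boolean dynamics, contextualization, validation against
random search (cross-validation + Welch's t-test), and perturbation
simulation.

The same workflows are available from the shell:

```sh
boolprune fixtures make --seed 1 --out fixture/
boolprune prune --network fixture/pkn.sif --phenotypes fixture/phenotypes.tsv \
                --out run/ --seed 1
boolprune perturb --network run/contextualized_01_f1.0000.sif \
                  --pkn fixture/pkn.sif --phenotypes fixture/phenotypes.tsv \
                  --from stateA --to stateB --flip G01=1 --threshold 0.75
```

Networks are 3-column TSV edge lists (`source <TAB> activate|inhibit <TAB>
target`, SIF-compatible); phenotypes are TSV tables with a `gene` column
and one 0/1 column per phenotype. Sheets of a spreadsheet holding a
network's interactions and phenotype profiles export directly to these
formats (save each sheet as tab-separated text).

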