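# Methods

This note documents the model, the numerical choices, and what the synthetic
studies do and do not establish.

## Boolean model construction

A signed directed network (nodes = merged protein entities; complexes carry a
`_c` suffix, isoform groups `_i`; autocrine ligands have activating
self-loops) is compiled into update rules by fixed conventions:

- multiple activators combine with OR;
- any inhibitor dominates: `(act₁ or act₂ …) and not (inh₁ or inh₂ …)`;
- an inhibitor-only node is `not (inh₁ or …)`;
- a self-loop node lists itself among its activators;
- a regulator-free node holds its current value (identity rule). Holding
  rather than decaying is deliberate: unlisted inputs behave like constitutive
  boundary conditions, which matches the autocrine-ligand convention and
  avoids spuriously draining the network.

Parallel edges of opposite sign between the same pair are both kept and both
enter the default rule (inhibition then wins whenever the source is active);
merged curation sources do not forbid dual-sign regulation, and the rule table
is the place to resolve it explicitly when it matters.

Personalisation is layered with clamps > overrides > defaults: mutation clamps
(GOF → 1, LOF → 0) are constitutive and cannot be overridden by curated rule
replacements or by drugs; rule overrides replace expressions for listed nodes
only. Rule expressions are case-insensitive infix AND/OR/NOT strings, parsed
by a small recursive-descent parser into an AST that is also the compilation
unit for the vectorised simulator. AND/OR are flattened associatively, so
structurally different but associatively equal trees compare equal.

## Initial states from expression

Expression values (TPM-like, non-negative) are min–max scaled per gene across
the modeled cell lines; the scaled value is the probability the node starts
ON. Choices where the mapping is underdetermined:

- constant gene across cell lines → 0.5 (uninformative, maximum entropy);
  a warning is emitted;
- model nodes without a measurement (complexes, ligands) → 0.5, overridable;
- multi-gene nodes → mean of member genes' scaled values.

Each repeat draws its initial state from its own deterministic stream
(`seed + repeat index`), so ensembles are reproducible repeat-by-repeat
independently of batch size.

## Asynchronous simulation and steady-state detection

The update scheme is uniform-asynchronous: per time step, among non-clamped
nodes whose rule output differs from their current value, exactly one is
chosen uniformly and flipped; a state with no flippable node is a fixed point
and absorbs the trajectory. The ensemble (default R = 100 repeats, T = 5000
steps; both configurable and deliberately smaller in the desk-scale studies
below) is advanced as a (R × n) boolean matrix — one NumPy pass per step —
with a fixed random-stream layout (one uniform draw per repeat per step) so
runs are bit-identical given the seed.

Steady state is detected from the entropy of the ensemble state distribution:
`P_t(S)` is the frequency of full state S among the repeats at step t, and
`H(t) = −Σ P_t log2 P_t` (bits). H starts near `log2 R` while trajectories are
scattered and falls as an attractor takes over, reaching exactly 0 when a
single state dominates. H is subsampled every 10 steps and slopes are centered
finite differences over a ±50-step window (both configurable); the steady
state starts at the window with minimal slope, ties to the earliest step
(with a 1e-12 tolerance so float noise cannot defeat the tie-break).
Activities are averaged over `[t*, T]`.

Design note: an alternative entropy definition pools observations cumulatively
over steps 0..t. That profile decays like 1/t, which places the minimum slope
at t = 0 for *any* dynamics and returns a steady window containing the entire
transient; we verified the resulting bias against the exact oracle and use the
per-step ensemble distribution instead.

## Drugs and the dose grid

A dose d ∈ [0, 1] is the probability that a target node is clamped
(antagonist → 0, agonist → 1), drawn once per target per repeat at the moment
the drug is applied; on success the node is set to the clamp value and held.
Multi-target drugs draw independently per target (a shared per-drug draw is
available as an option). Drug clamps that contradict a mutation clamp are
dropped with a logged conflict — genetic lesions are constitutive.

Pair simulation is two-phase: the unperturbed ensemble runs to its detected
steady state (this baseline is shared across all pairs of the same cell
line), then for each of the 16 cells of the {0, 0.25, 0.75, 1}² grid the
clamps of both drugs are drawn and the ensemble continues to a new steady
state, re-applying the entropy criterion to the post-application segment. If
phase-1 entropy is still rising at the horizon, the last window is used and a
warning is logged.

## PSS, consensus and the predicted HSA score

Monotherapy activities for grid cell (a, b) are read off the grid edges
(a, 0) and (0, b) — never re-simulated — mirroring the per-dose HSA
construction. PSS is `min(X₁, X₂) − X₁₊₂` for oncoproteins and
`Y₁₊₂ − max(Y₁, Y₂)` for tumor suppressors; activities in [0, 1] bound it to
[−1, +1], and it is symmetric in the two drugs. The consensus PSS is the 75th
percentile (linear interpolation between order statistics) over *all* 16 grid
cells, including the zero-dose row and column whose PSS is 0 or negative by
construction; this shrinks the consensus toward 0 and is the reason predicted
sums sit below zero on average (see Evaluation). The predicted HSA score of a
pair is the sum of consensus PSS over the selected panel. The onco /
tumor-suppressor role table is a required input; a small built-in default
covers the common panel proteins and is user-overridable (roles are an
interpretive annotation, not something the model can infer).

## Genetic algorithm

Chromosomes are protein subsets that always contain the two read-out proteins
E2F1 and CASP3; fitness is the Pearson correlation between the chromosome's
predicted scores and the observed scores over the training pairs (constant
predictions score −1). Per generation: rank 60 chromosomes, keep the top 30
as parents, breed 30 offspring (uniform set-crossover then add/remove/swap
mutation, each applied with probability 0.9 — the search space is large), and
add 30 fresh random chromosomes; parents do not re-enter, and a one-slot hall
of fame keeps the best-ever chromosome, making the reported optimum immune to
the non-elitist replacement. Initial lengths are uniform in [3, 20]. Fitness
is cached by protein set; on ≤15 optional candidates the GA reproducibly ties
the exhaustive optimum within a few hundred generations, which is why the
command-line default is 500 generations with a flag for long runs.

## Evaluation and mechanism clustering

Predictions and observations are compared by Pearson correlation, by AUC
(ranking predictions against the sign of the observed score; synergy = 
positive class), and by sensitivity/specificity. The threshold-0 decision is
taken on predictions min–max rescaled to [−1, +1] — i.e. at the midrange of
the predicted scores — because the consensus construction shifts raw sums
negative; Pearson and AUC are invariant to this affine map, only the confusion
counts depend on it. Constant predictions are an error, single-class label
sets report AUC as missing.

PSS profiles are clustered hierarchically with correlation distance
(1 − Pearson between profiles; a zero-variance profile has no direction and
is assigned the maximal distance 2, with a warning) and average linkage — the
usual partner of correlation distance — cut to a user-chosen k (defaults
follow the 5 synergistic / 3 antagonistic grouping of the motivating
analysis). Group signatures list proteins whose within-group mean PSS exceeds
a threshold (default 0.1). Dendrograms export as Newick.

## Synthetic studies and the exact oracle

`make_scenario` generates every pipeline input from a hidden true model of
n ≤ 12 nodes. Topology matters: in a fully random signed digraph essentially
no drug pair exhibits HSA synergy (blocking one input of an OR cascade either
does everything or nothing), so the generator wires a small number of pathway
hubs (default 3) that redundantly activate the proliferation reporter (kept
as an OR rule) and repress the apoptosis reporter; drugs preferentially
target hubs. This creates the classic synergy motif — one redundant pathway
blocked achieves little, two blocked collapse the read-out — and yields
ground-truth HSA scores spanning both signs (sd ≈ 0.4 under defaults).

Observed scores are *computed, never assigned*: a drug's effect is the
suppression of the proliferation reporter (1 − occupancy) in the exact
asynchronous Markov chain of the mutation-clamped hidden model with its
targets clamped at full dose; the pair's score is the HSA statistic on those
effects plus Gaussian noise (default sd 0.02). Expression matrices are
TPM-like with per-gene random dynamic ranges; mutations are sparse
(rate 0.08 per node per cell line) GOF/LOF draws sparing the reporters;
drugs hit 1–4 targets, 80% antagonist.

The oracle builds the full 2ⁿ-state uniform-asynchronous transition matrix
(flippable nodes equiprobable, fixed points self-looping) and finds the
long-run distribution by power iteration on the lazy chain (I + P)/2 — which
shares every limit of P while damping periodic attractors — to a 1e-10 max-
norm tolerance. `exact_mean_occupancy` additionally evolves the distribution
step by step and averages occupancy over the simulator's steady window
[t*, T]: this is the exact expectation of the statistic the ensemble reports,
the right comparison target when the window still contains tail transients;
it converges to the limiting occupancy as T grows.

What the synthetic studies show — and what they do not: they verify the
simulator's dynamics against exact chains, the calibration of dose clamps,
and that the GA and clustering recover planted structure. They do not emulate
realistic mutational signatures, TPM distributions beyond min–max-relevant
structure, or the curation noise of real interaction databases, so passing
them says the machinery is correct, not that predictions on real cell lines
reach any particular accuracy.

## Study sizes and determinism

The bundled verification runs use deliberately desk-scale conditions chosen
once: oracle equivalence on 20 random ≤10-node models at R = 500, T = 2000;
dose-clamp calibration at 10,000 repeats; GA recovery on 10 candidates with 2
informative proteins, 20 seeded runs of 200 generations; the end-to-end
pipeline on a 12-node hidden model, 5 cell lines, 8 drugs and 75
pair×cell-line samples at 1000 steps and 30 grid repeats. All randomness
descends from a single root seed; identical configuration and seed give
byte-identical outputs.

In the oracle-equivalence check, per-node discrepancies are ~N(0, SE)
deviates, so across ~150 node comparisons the family-wise correct reading of
"every node within 3 SE" is: ≥98% of comparisons within 3 SE (the binomial
expectation is 99.7%) and all within the Bonferroni 99% family bound. A
localized bias fails the family bound; a diffuse bias fails the coverage
clause.

## Known limitations

- Boolean abstraction: no reaction time scales (protein synthesis vs
  phosphorylation are one "step"), no dose–occupancy pharmacology beyond the
  dose-as-probability convention, pairs only.
- The steady window can retain tail transients on slowly mixing models; the
  entropy-slope criterion trades a principled stopping rule for a small,
  quantifiable truncation bias (measured against the window-matched oracle).
- The GA fits the panel on all pairs (no cross-validation), matching the
  intended use as an explanatory decomposition rather than an out-of-sample
  predictor.
- Mechanism groups depend on the user-chosen cut k; no automatic selection.
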