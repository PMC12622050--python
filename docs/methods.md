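# Methods

This note documents the models, numerical conventions, and design
decisions behind `novelforge`, and what its surrogate-scale tests do and
do not demonstrate.

## Burial fraction and SASA

Solvent-accessible surface area is computed with a Shrake–Rupley
implementation using a deterministic golden-spiral point set (default 960
points per atom, probe radius 1.4 Å) rather than random sphere points, so
every result is exactly reproducible. Atom radii are element-keyed
(C 1.70, N 1.55, O 1.52, S 1.80 Å); hydrogens are ignored. Against the
analytic two-overlapping-spheres solution the per-sphere error at 960
points is ≈ 0.03%, and total area changes by < 1% between 960 and 3840
points on typical chains.

The burial fraction is `B = clamp(1 − SASA_folded / SASA_ref, 0, 1)`,
with a conformation-independent reference so that B measures compactness
only:

* **All-atom structures** — `SASA_ref` is the sum of tabulated per-residue
  theoretical maxima on the Gly-X-Gly tripeptide scale (Tien-style
  values). The scale is fixed; alternate scales are deliberately not
  exposed as options.
* **Cα-pseudo-atom structures** (the surrogate predictor's output: one
  3.0 Å sphere per residue) — the Gly-X-Gly table does not apply to a
  single-sphere-per-residue model, whose chain-neighbour occlusion at the
  3.8 Å virtual bond is far larger than atomic-scale occlusion. The
  reference is instead the exact single-sphere analog of the tripeptide
  reference: the analytic exposed area of the middle sphere in a linear
  trimer at 3.8 Å spacing (≈ 105 Å² per residue at radius 3.0 Å,
  probe 1.4 Å). Under this scale, open chains score B ≈ 0.3 and collapsed
  hydrophobic chains B ≈ 0.6–0.8, so the 0.5 compactness threshold
  separates the two regimes meaningfully.

A fully extended ideal chain built by the all-atom extended builder
(φ = ψ = ω = 180°, backbone N/CA/C/O plus Cβ) has B ≈ 0.13 for poly-Gly —
the regression constant frozen in the tests. Because the builder places
no side-chain atoms beyond Cβ, extended chains of large-side-chain
residues under-report SASA relative to their full-residue reference and
can reach B ≈ 0.5; extended-state oracles therefore use glycine.

## TM-score (fixed alignment)

For equal-length pairs with a residue-i ↔ residue-i correspondence the
TM-score is maximized over superpositions found by the standard
seed-fragment iteration: seed windows of length L, L/2, L/4 … 4 at every
start position; superpose on the seed (Kabsch, reflection-corrected);
iteratively re-superpose on the subset of residues within a distance
cutoff (d0, relaxed in 0.5 Å steps until ≥ 3 residues qualify) until the
subset stabilizes. The score sums `1/(1+(dᵢ/d0)²)` over **all** residues;
`d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5)`. The implementation is verified to
±0.01 against an independent re-implementation that uses quaternion
(Horn) superposition and explicit-loop iteration.

The surrogate structure-search engine compares unequal-length structures
by sliding the shorter chain over every window of the longer and taking
the maximum fixed-alignment TM-score with d0 from the longer length — a
deterministic, conservative stand-in for an alignment-free search tool.
Inside the engine the seed starts are subsampled with stride 4; this
yields a lower bound on the exhaustive-seed score and is indistinguishable
from it in the near-identity regime that the > 0.5 assignment threshold
probes.

## Sequence-energy model and replica exchange

`E(s) = −w_lik·L̄(s) − w_con·C(s)` with both weights defaulting to 1 and
both scorers contracted to return O(1)-per-residue magnitudes. Sampling
is single-substitution Metropolis (proposals exclude self-mutation,
uniform over the 19 alternatives, keeping the chain aperiodic); replica
exchange uses a strictly ascending temperature ladder (default geometric
over [1, 4] with 4 replicas) with neighbour swaps attempted on an
alternating even/odd schedule every `swap_interval` steps, accepted with
probability `min(1, exp((1/Tᵢ − 1/Tⱼ)(Eᵢ − Eⱼ)))`. Long-run visit
frequencies on an enumerable two-letter toy agree with the exact
Boltzmann distribution (χ², p > 0.01), and per-replica marginals under
exchange match single-temperature chains, which is the detailed-balance
property the swap move must preserve.

## Genetic algorithm

Recombination mixes an interior splice (probability 0.5; cut points
exclude the sequence ends) with end-to-end fusion; fusion is what lets
40-aa fragments grow into domain-scale products, splice supplies
fine-grained recombination. Children are resampled into a [10, 250]
length window (the fallback after repeated rejection is a length-capped
fusion). Mutation is an independent per-position substitution (default
rate 0.02). Offspring are then refined by single-temperature Metropolis
(default 100 steps at T = 1, the coldest ladder temperature) on the same
energy landscape that produced the fragment library.

Selection is weighted sampling **without replacement** down to the target
population, with weight `burial + 1e-6`; the epsilon keeps zero-burial
individuals selectable, and the scheme reproduces exact proportionality
in the two-member limit (0.8/0.2 weights → 80%/20% survival). Parents
are drawn uniformly without replacement. Per-epoch records carry the
population mean burial and cumulative counts of unique CATH folds (CAT
level — class.architecture.topology) and novel clusters; novel candidates
are de-redundified by arrival-order greedy clustering at TM ≥ 0.5 against
existing cluster founders. Annotation during a run can be disabled
(`GAConfig.annotate=False`) when only the selection dynamics are under
study, since structure search dominates runtime.

## Foldtuning loop

Each round: sample `n_samples` sequences → predict structures → burial →
annotate → keep candidates that are compact (B > 0.5) and unassigned (no
hit with TM > 0.5) → rank by descending burial (ties broken by id) → the
top `top_n` become the finetuning set. A shortfall (fewer survivors than
`top_n`) finetunes on all survivors with a logged warning. Round reports
carry mean burial over all samples, novel and assigned counts, and the
structural hit rate; printed percentages are always exact
count/denominator ratios. The hyperparameter-scan harness reports, per
(top_k, temperature) cell, unique CATH and CAT label counts among
assigned samples and the fractions unassigned, compact, and both (the
novelty rate).

## Inverse-folding funnels

Designs are pre-clustered at 60% sequence identity (exact-match fraction;
designs off one template are equal-length, so no alignment is needed;
greedy by input order). Each representative contributes one landscape
point: per-residue energy (total energy / L) and fixed-alignment TM to
the template. The pass filter is strict on both thresholds
(E < −2.2 REU/aa, TM > 0.5).

The landscape verdict is made quantitative by a fixed rule table over
rank-based metrics — the funnel/pathology distinction is otherwise a
by-eye judgement. With the low-energy subset defined by the 25th
percentile of energies: (1) `off_target_minimum` if the subset's median
TM < 0.5; (2) `multi_minimum` if its TM histogram (bin width 0.1) has ≥ 2
modes (a mode is a bin strictly above both neighbours with ≥ 3 points);
(3) `flat` if |Spearman ρ(E, TM)| < 0.15 (all-equal energies are flat by
convention); (4) `funnel` if ρ ≤ −0.3 and the subset's trapped fraction
(TM < 0.5) is < 0.1; otherwise `ambiguous`. Landscapes with fewer than 10
points are reported as `insufficient`. All constants live in
`FunnelParams`. Rank-based metrics make the verdict invariant to point
order and to monotone affine energy rescaling.

## Surrogate backends

The surrogates exist to make the full pipeline executable and testable at
desk scale with no pretrained models; they are not physically realistic
and are not benchmarks.

* **Structure predictor** — greedy self-avoiding chain growth on a cubic
  lattice (3.8 Å spacing), each step maximizing new hydrophobic–
  hydrophobic contacts (Kyte–Doolittle > 0 defines hydrophobic,
  |i−j| ≥ 3, contact < 8 Å), ties broken by a hash of (sequence,
  position), with backtracking on dead ends. Output is Cα-only with a
  3.0 Å pseudo-radius (a surrogate-only convention standing in for
  full-residue bulk). The hydrophobicity → collapse link gives selection
  loops a real compositional gradient to climb, which is what makes the
  trend tests informative rather than vacuous.
* **Likelihood scorer** — an order-2 Markov model (Laplace-smoothed) fit
  to a deterministic 200-sequence synthetic corpus that itself carries
  strong second-order structure; corpus sequences outscore their shuffles.
* **Contact scorer** — contacts per residue of the predicted lattice
  structure.
* **Energy scorer** — pseudo-REU: −1.0 per hydrophobic–hydrophobic
  contact, −0.2 per contact of any kind.
* **Inverse folder** — per-position substitution noise on the template
  sequence.
* **Sequence generator** — an interpolated 3-mer model (weights
  0.7/0.2/0.1) with temperature rescaling of log-probabilities and top-k
  truncation of each step's candidate set (the 20-letter alphabet means
  vocabulary-scale settings such as top_k 950 are no-ops, as intended);
  finetuning blends half the count mass toward the provided sequences.
* **Fixture reference library** — distinct lattice folds with jittered
  copies as members and four-level dotted labels, cross-fold distinctness
  (TM < 0.5) verified at generation.

What the surrogates do **not** emulate: real secondary structure,
realistic energetics, sequence–structure degeneracy, or database-scale
fold diversity. Passing trend tests therefore demonstrates that the
*selection and enrichment machinery* responds to a compactness gradient
as designed — not that the pipeline would discover novel folds at the
published rates against real models and databases.

## Problem sizes in tests and the acceptance script

Surrogate-scale runs use deliberately small study conditions chosen once:
fragment libraries of 60 × 40-aa fragments from short (20-step,
2-replica, ladder 0.3/1.5) replica-exchange runs, genetic-algorithm
populations of 30 with 9 offspring over 20 epochs, and foldtuning
campaigns of 1,000 samples × 5 rounds. The toy energy model weights
contact density over likelihood (0.5/2.0) and offspring refinement runs
60 Metropolis steps at the coldest ladder temperature (0.3): on this
landscape refinement genuinely climbs toward contact-dense, compact
sequences, so the burial trend the selection loop produces is driven by
the mechanism under test rather than by snapshot noise. Production
defaults (800 fragments, population 100, unit energy weights, 10,000
samples/round) remain the config defaults.

## Known limitations

* Single chain, canonical residues, no insertion codes or mmCIF.
* The extended-chain builder places no side-chain atoms beyond Cβ (see
  above for the consequence).
* `run_remc` records full trajectories by default; use
  ``record_interval`` for long runs.
* The arrival-order novel-cluster bookkeeping inside `run_ga` is greedy
  and order-dependent (as is the batch `greedy_tm_cluster`, which orders
  by burial); neither is a globally optimal clustering.
* The generator surrogate samples fixed-length sequences; length
  modelling is out of scope.
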