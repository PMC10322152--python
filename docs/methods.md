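# Methods

`statecoev` reconstructs the computational core of a coevolution-driven,
state-specific analysis of transporter conformational cycles: from multiple
sequence alignments and conformational-state-labeled structures to
state-specific contact signatures, structural-bias constraint files,
machine-learned collective variables (CVs), and reweighted one-dimensional
free-energy profiles with point-wise error estimates. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic ground-truth worlds do and do not establish.

## Sequence model and coevolution scores

An alignment over the 21-letter alphabet (20 amino acids + gap; ambiguous
residues B/Z/X/U/O map to the gap state, case is ignored) is gap-filtered
(columns with strictly more than 20% gaps removed; original column indices
retained for mapping back to structures) and reweighted: sequence *n* gets
weight 1/|{m : id(n,m) ≥ 0.8}|, identity computed over mutually non-gap kept
columns (a pair with no comparable column counts as identity 0). The sum of
weights is the effective sequence count M_eff; duplicated sequences share one
unit of weight, so M_eff is invariant under duplication.

The Potts model assigns fields v_i(a) and pair-symmetric couplings
w_ij(a,b) = w_ji(b,a) with zero diagonal blocks. Parameters maximize the
weighted, L2-regularized pseudolikelihood — the sum over sequences and
columns of the log conditional probability of the observed residue given the
rest of the sequence — via L-BFGS on the joint symmetric parameterization
(defaults: λ_v = 0.01, λ_w = 0.01·(L−1), gradient max-norm tolerance 1e-5).
The analytic gradient is verified against finite differences in the tests.

The plain double sum of a coupling block is gauge-dependent (it vanishes
identically in the zero-sum gauge), so pair scores are computed after fixing
the zero-sum gauge, either as the Frobenius norm of the block (default) or as
the sum of absolute gauge-fixed couplings (`paper_sum`). Scores are then
standardized to zero mean and unit variance over the off-diagonal upper
triangle; a constant score matrix standardizes to all zeros by convention.
No average-product correction is applied — standardization is the only
normalization. Per-subfamily maps combine by (weighted) element-wise mean,
which up-weights family-wide pairs relative to subfamily-specific ones.
Ranked pair lists exclude |i−j| < 5 (sequence-local secondary-structure
contacts).

## Contact maps and the discriminative contact count t

A structure becomes the matrix of minimum heavy-atom inter-residue distances
r (hydrogens excluded), softened to M(A,B) = 1/(1 + exp(2r − 8)) — a sigmoid
switching at 4 Å. Similarity between structures x, y seen through a
coevolution map C is ⟨C⊗M_x, C⊗M_y⟩, restricted to the current top-t pair
set. For each t in a grid the similarity matrix is converted to the
kernel-induced distance d(x,y) = sqrt(d_xx + d_yy − 2 d_xy), embedded to 1D
(deterministic classical multidimensional scaling by default; UMAP available
as a pluggable backend with a fixed, recorded seed), one Gaussian kernel
density per state is fitted (Silverman bandwidth, floored at 5% of the data
span — a state cloud collapsed to near-identical embedding values carries no
separability information and would otherwise become a spuriously sharp
density), densities are floored at 1e-12, and the symmetric Kullback–Leibler
divergence is summed over state pairs.

t is defined as the number of contacts *sufficient* to distinguish the
states. The selection therefore takes the smallest grid value whose
divergence is within 0.5% (relative) of the curve maximum; 0.5% is the scale
of the objective's kernel-density sampling noise on ensembles of ~10 members
per state. A configuration flag selects the opposite (least discriminative)
convention, and the full objective curve is always returned so any
convention is recoverable downstream.

Known limitation: on planted worlds with p discriminative contacts the
selection returns exactly p in most replicates but p−1 in roughly a quarter
of them — the last-entering planted contact of a cycle-end state can be
marginally redundant once its siblings are included. The selection is thus
accurate to ±1 with a slight parsimony bias, which is the intended trade-off
of the sufficiency definition.

Structure comparison plumbing: Cα RMSD after Kabsch superposition
(SVD-based, proper-rotation corrected), BLOSUM62-normalized sequence
distance d = 1 − S(a,b)/√(S(a,a)S(b,b)) over mutually non-gap columns, PCA
with a deterministic sign convention, and structure→alignment column maps via
global alignment (BLOSUM62, gap open 10, extend 0.5).

## State classifier and relevance signatures

The classifier maps a soft contact map to five state scores through: a hard
coevolution filter (only the top-t pairs enter), non-overlapping
average-pooling of retained pairs over `pool_size`×`pool_size` cells of the
residue-pair grid (grid-adjacent contacts belong to the same structural
element; the published architecture figure says 4×4 while the corresponding
table caption says 5×5 — the default here is 4, configurable, and recorded
in signature metadata), a dense layer to a 30-dimensional hidden layer, and
a dense layer to one output per state. The loss is Σ(e−d)² + Σe² with one-hot
targets d: the second term penalizes output magnitude, holding the sigmoid
outputs away from saturation. Training is full-batch gradient descent
(learning rate 0.5, 500 epochs, fixed seed); the model deliberately overfits
its training structures and is an analysis device, never a predictor.

Two architecture choices exist purely so that attribution is exact:

* **No bias terms.** Layer-wise relevance propagation (LRP, ε-rule with
  ε = 1e-6) then conserves the target output's pre-sigmoid activation
  exactly up to the ε slack (measured ~1e-7 relative).
* **tanh hidden activation.** tanh is the zero-centered sigmoid: a hidden
  unit with zero input contributes nothing (a logistic unit would output
  0.5 — an unattributable constant whose relevance the ε-rule smears onto
  arbitrary near-zero weights), and tanh(z)/z > 0 keeps the redistribution
  sign-consistent for units operating at negative pre-activation. The
  output layer remains logistic.

Per state, relevance is averaged over that state's training maps. Contacts
with |relevance| > 0.1 form the state's signature: positive = encouraged
(characteristically present), negative = discouraged (characteristically
absent). Pooled-cell aggregates are retained alongside as contact bundles.
Note that a discouraged contact can only carry relevance on a state's own
maps if it is at least partially formed there (relevance is proportional to
the input value); fully absent contacts are invisible to LRP by
construction. Shared background contacts — formed in every state — absorb
the network's global inhibition and may carry negative relevance; their sign
is a calibration artifact, not a statement about state-specific
presence/absence, and is excluded from sign-semantics checks.

## Bias constraints

Signatures translate to constraint files for an external relaxation engine:
encouraged pairs as flat-bottomed harmonics (x0 = 4 Å, sd = 1, tol = 1)
inside `AmbiguousConstraint` blocks, discouraged pairs as fade functions
(0–8 Å window, fade zone 2, well depth +5) inside `MultiConstraint` blocks,
Cα atoms by default, residue numbering 1-based, overall weight 0.1 per
block. Stiffness is capped at 20 (1/sd² for harmonics, |well depth| for
fades): the biases must steer, not overwhelm, the engine's native
energetics. Signature pairs whose alignment columns have no residue in the
target are dropped with a logged count. Files round-trip exactly through the
package's own reader (the per-block `#WEIGHT` comment carries the weight).

## Collective variables

A linear SVM (C = 1, standardized features, coefficients mapped back to the
distance scale) separates two adjacent states on top-pair minimum-distance
features (in nm; Å↔nm conversions are explicit at module boundaries). The
occluded state is excluded from training. The coefficient spectrum is
thresholded at the midpoint of the first adjacent gap wider than 5× the
median adjacent spacing (falling back to the top 20 with a warning when no
such gap exists). Positive-coefficient contacts weight CV1, negated negative
ones CV2; each CV is the weight-normalized sum of minimum residue distances,
hence a convex combination: its value always lies between the smallest and
largest term distance, it is invariant under rigid motion, linear under
uniform scaling, and *high* when the state's specific contacts are *broken*.
Per-process sampling configurations (diffusion constants, force constants,
0.4 nm cover diameter, free-energy cutoffs of 40–60 kJ/mol, four walkers)
export as flat key=value text with user overrides marked in place.

## Free-energy reweighting, alignment and diagnostics

Frames carrying an adaptive-bias free-energy estimate U(ξ_t) reweight as
w(t) = exp(−U(ξ_t)/RT)/n(bin(ξ_t)) — a Boltzmann factor of the bias divided
by the occupancy of the frame's bin (uniform grid, default 100 bins over the
observed range padded 5%, half-open intervals). T = 298 K,
R = 8.314462618×10⁻³ kJ/mol/K. Projected on any per-frame scalar
coordinate, bin free energies are E(x_i) = −RT ln(Σ_t u(i,t) w_t / Σ_t w_t),
gauged to min E = 0; empty bins are flagged (NaN), never errors. Per-bin
standard errors use the Kish effective sample size, se = RT/√n_eff.

The global 1D coordinate is an order-constrained discriminant: maximize
Σ_ij (i−j)² (μ_i−μ_j)² / within-class scatter. Both forms are quadratic in
w, so the objective is a generalized Rayleigh quotient, scale-invariant in
w; w is reported unit-norm and an optional soft penalty (default 1e-3) keeps
the raw optimizer iterates near the unit sphere. The ratio is non-convex
once the order constraint enters, so optimization restarts from random unit
directions (default 1000; analytic gradients make this cheap) and accepts
the best direction whose projected class means are strictly increasing in
cycle order — at the scale of the projections, not float round-off; the
fraction of ordered restarts is reported. The two-class case reduces to the
classical closed form S_W⁻¹(μ₂−μ₁), which the tests verify to 1e-6.

Per-process profiles on a shared grid are aligned by additive offsets (first
profile fixed at zero) minimizing the inverse-variance-weighted squared
disagreement over overlapping bins — a linear solve — then combined by
inverse-variance-weighted mean and re-gauged. Disconnected overlap graphs
raise an error naming the orphaned segments.

Error and overlap diagnostics: directed transitions between *adjacent* bins
are counted from consecutive frames of each walker; each edge carries
δ = RT·|ln((N_up+1)/(N_down+1))| (add-one smoothing keeps sparse edges
finite), and per-bin errors accumulate edge terms in quadrature along the
bin axis from the most-occupied bin — one consistent reading of
"imbalance → free-energy error", recorded as such. A perfectly converged
adaptive bias gives balanced transitions and errors that shrink as n^(−1/2)
(verified: quadrupling the trajectory halves the mean error). The walker
overlap O(x) counts walkers whose unbiased per-walker distribution at bin x
reaches 10% of the across-walker mean distribution there (the raw-threshold
variant is available). Convergence reports require profile changes below
0.5 kJ/mol between snapshots, evaluated only below the process free-energy
cutoff, plus the 2-norm series of successive profile differences.

## Synthetic worlds: what they emulate, and what they do not

All tests run against generated fixtures with machine-readable ground truth:

* **Planted Potts worlds** (defaults L = 30, q = 8 — a reduced alphabet
  keeps fits fast — k = 10 residue-disjoint coupled pairs with |i−j| ≥ 5,
  identity-favoring couplings of strength 1.2). Sequences are Gibbs-sampled,
  all chains in parallel, 150 burn-in sweeps. Single-site marginals and
  pair factorization of the sampler are tested directly.
* **Multi-state structure worlds**: five states on a conformational cycle,
  each defined by exclusive contacts (3.5 Å when formed) over a shared
  background, plus non-structural flexible pairs. Contact breaking is graded
  by cycle distance (4.75 Å in cycle-adjacent states, 12 Å beyond) because
  real conformational cycles are sequential — five mutually exclusive
  contact sets would form a simplex that no 1D embedding can represent.
  Planted pairs occupy distinct pooling cells, mirroring the pooling
  assumption that grid-adjacent contacts share state-dependence. Within-state
  Gaussian distance noise (default 0.5 Å) models structural heterogeneity.
  The classifier study uses the strictly binary variant
  (`neighbor_distance = 12`) with flexible pairs at 8–18 Å; the t-selection
  study uses the graded variant with flexible pairs at 3–8 Å (the
  false-positive class real coevolution maps contain). Bead-chain 3D
  coordinates are decorative (rigid-motion and superposition checks only);
  the distance matrices are constructed directly because an arbitrary
  planted contact set is generally not realizable by a 3D chain.
* **Biased trajectories**: Metropolis chains per walker sampling
  exp(−(F−U)/RT) for an analytic double well F(x) = b(x²−1)² (barrier b =
  10 kJ/mol at x = 0, minima at ±1), domain [−1.8, 1.8], step 0.35,
  500-sweep burn-in, acceptance monitored (< 1% raises).

Passing these tests shows the algorithms recover planted truth under
controlled conditions. It does not show that real alignments satisfy the
Potts model, that real structures separate cleanly in contact space, or that
real adaptive-bias estimates are converged — those are properties of the
data, not of this code.

## Problem sizes

Study-scale runs used throughout the tests and the acceptance script:
coupling recovery at L = 30, q = 8, 2000 sequences, five replicate worlds;
t selection on 50 structures (10 per state), five worlds; classifier
recovery on 25 structures, three worlds; discriminant recovery on 250
20-dimensional samples, five replicates; reweighting on 10⁵ frames over
four walkers, five replicates. The end-to-end pipeline demonstration runs a
reduced world (L = 40, 300 sequences) and completes in a few seconds.
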