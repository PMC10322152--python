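# statecoev

State-specific coevolution analysis for transporter conformational cycles.

Secondary transporters such as the sugar porters work by cycling through a
series of conformational states (outward open → outward occluded → occluded
→ inward occluded → inward open), but most members of a family have
structures solved in only one or two of those states. `statecoev` implements
a pipeline that extracts the *state-dependence* of residue–residue contacts
from evolutionary couplings and the few available structures, and carries
that information through to enhanced-sampling collective variables and
free-energy profiles:

1. **Coevolution** — fit a Potts model to each subfamily alignment by
   weighted, L2-regularized pseudolikelihood maximization
   (P(x_i | x_−i) ∝ exp(v_i(x_i) + Σ_j w_ij(x_i, x_j))), reduce the
   gauge-fixed coupling blocks to standardized pair scores C_ij, and average
   per-subfamily maps into a global map.
2. **Contact-space state geometry** — convert structures to soft contact
   maps M(A,B) = 1/(1+exp(2r_AB − 8)), measure structure similarity as
   ⟨C⊗M_x, C⊗M_y⟩ on the top-t coevolving pairs, and pick the smallest t
   whose symmetric Kullback–Leibler divergence between state distributions
   (on a 1D embedding) is within tolerance of the maximum: the number of
   contacts sufficient to tell the states apart.
3. **State signatures** — train a small coevolution-filtered contact-map
   classifier (pooling over adjacent residue pairs, 30-dim hidden layer,
   loss Σ(e−d)² + Σe²) and run layer-wise relevance propagation per state:
   positive relevance marks encouraged (characteristically present)
   contacts, negative marks discouraged (characteristically absent) ones.
4. **Bias constraints** — translate signatures into weak attractive
   (flat-bottom harmonic) and repulsive (fade) pair constraints in a
   Rosetta-style constraint-file dialect, for steering structure models
   between states with an external relaxation engine.
5. **Collective variables** — separate adjacent states with a linear SVM on
   top-pair distances, keep coefficients above the first spectral gap, and
   build CV₁ = Σ max(0,c_i) x_i / Σ max(0,c_i) (and CV₂ from the negative
   coefficients): normalized weighted contact distances that are high when a
   state's specific contacts are broken.
6. **Free energies** — reweight adaptively-biased trajectories with
   w(t) = e^(−U(ξ_t)/RT)/n(bin(ξ_t)), project E(x) = −RT ln Σ u·w / Σ w onto
   an order-constrained discriminant coordinate (class means forced into
   cycle order), align per-process segments by inverse-variance-weighted
   offsets, and attach transition-imbalance errors and walker-overlap
   diagnostics.

Every stage is validated against synthetic worlds with planted ground truth
(`statecoev.synthetic`): Potts models with known coupled pairs, multi-state
structure ensembles with planted state-defining contacts, and biased
trajectories from an analytic double-well surface.

## Worked example: recovering planted couplings

```python
from statecoev import synthetic, coevolution, msa

world = synthetic.make_planted_potts(L=30, q=8, k=10, seed=0)
aln = synthetic.sample_potts_msa(world.potts, n=2000, seed=0)
aln = msa.compute_weights(aln)
print(f"M_eff = {aln.meff:.1f} over {aln.n_sequences} sequences")

model = coevolution.fit_potts(aln, alphabet=world.potts.alphabet)
cmap = coevolution.coupling_scores(model)          # standardized z-scores
top = coevolution.top_pairs(cmap, 10)
planted = set(world.planted_pairs)
for i, j in top:
    print(f"  {i+1:>2} {j+1:>2}  {cmap.scores[i, j]:6.2f}  {(i, j) in planted}")
print(f"precision@10 = {sum(p in planted for p in top)/10:.2f}")
```

Output:

```
M_eff = 2000.0 over 2000 sequences
   9 24    6.58  True
  18 30    6.49  True
  11 25    6.31  True
  20 28    6.21  True
   4 17    6.10  True
  13 29    6.01  True
   3 16    5.87  True
  10 27    5.73  True
  21 26    5.64  True
   6 19    5.35  True
precision@10 = 1.00
```

All 2000 Gibbs-sampled sequences are mutually below the 80% identity
threshold (M_eff = 2000), the ten planted coupled pairs are exactly the ten
highest standardized coupling scores (z ≈ 5–7 against a background of unit
variance), and precision@10 is 1.0.

## Command line

`statecoev run --seed 3 --outdir out/` executes the full chain on a
self-contained synthetic world and writes the alignment, coevolution map,
t-selection curve, state signatures, per-state constraint files, CV
definitions with a sampling configuration, and the reweighted free-energy
profile with error and overlap columns. Re-running an unchanged
configuration reproduces every artifact byte for byte. Individual stages are
exposed as `statecoev msa filter`, `statecoev dca fit|combine|top`, and
`statecoev contacts build`.

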