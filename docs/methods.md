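# Methods

## Model

The design problem is posed as maximizing `P(S | T)` for an Fv sequence `S`
given a target backbone `T`, optimized only over the designable subsequence
`S_D` with the rest of the Fv (`S_F`) held fixed. By Bayes' rule this splits
into a structure likelihood and a sequence prior:

```
max_{S_D} log P(S | T) = max_{S_D} log P(T | S) + max_{S_D} log P(S)
```

`P(T | S)` is supplied by an oracle that maps a sequence probability matrix to
per-pair categorical distributions over binned geometry channels. Six
channels describe each ordered residue pair: Cα–Cα, Cβ–Cβ and N<sub>i</sub>–O<sub>j</sub>
distances, the ω (CAi–CBi–CBj–CAj) and θ (Ni–CAi–CBi–CBj) dihedrals, and the
φ (CAi–CBi–CBj) planar angle, following the trRosetta orientation
conventions. d<sub>CA</sub>, d<sub>CB</sub> and ω are symmetric in (i, j);
d<sub>N−O</sub>, θ and φ are stored as ordered-pair matrices (the
N<sub>i</sub>–O<sub>j</sub> distance is intrinsically directional, so it is
kept asymmetric even though it is a distance channel). Channels requiring a
Cβ are masked invalid for glycine; masked pair-channels contribute no loss.

### Losses

* **Geometric**: `L_G = −(1/2C) Σ_X Σ_k log p_{X=T}(pair_k)` over the contact
  mask — the ordered pairs (i ∈ D, j ≠ i) with Cα–Cα ≤ 10 Å, counted exactly
  as the double sum over i ∈ D and j ∈ S (a pair with both ends designable is
  counted twice). The mask is computed once from the target structure and
  held fixed across iterations.
* **Sequence**: `L_S = −Σ_{i∈D} log p_i(wildtype_i)`, the negative
  log-likelihood of a reference sequence under the design rows. (The loss is
  implemented with the minus sign so that it is minimized at the reference;
  the positive-sum form would be maximized, which contradicts its use as a
  loss.)
* **Motif**: `L_M = Σ_{i∈M} KL(q⁰_i ‖ p_i)` toward per-position target
  distributions on a subset M ⊆ D.
* **Total**: `L = w_G·L_G + w_S·L_S + w_M·L_M`; all weights default to 1.
  Reference configurations: w_S = 25 for sequence-restricted and w_M = 100
  for motif-restricted runs.

Natural logarithms are used throughout (any other base rescales all losses
uniformly). Probabilities inside logarithms are floored at 1e−12; a triggered
floor in `L_S` is logged.

### Optimization

The optimization variable is a real |D|×20 matrix `a`. Each iteration:

1. decode: per-row argmax of softmax(a), ties to the lowest alphabet index;
2. forward the decoded one-hot through the oracle and evaluate `L_G`; the
   backward pass treats the one-hot as identity to the softmax rows
   (straight-through estimator);
3. evaluate `L_S`/`L_M` on the softmax rows themselves — these losses compare
   the design *distribution* to a target, and a one-hot argument would
   degenerate them to 0-or-floor values;
4. zero the gradient at disallowed letters, normalize it globally to unit ℓ2,
   and take a step of exactly `learning_rate` (default 0.05);
5. repeat up to `max_iterations` (default 60, the reference convergence
   range) or until convergence.

Convergence is declared when the total loss *evaluated on the soft rows*
changes by less than `loss_tolerance` (default 1e−3) over 5 consecutive
iterations. The decoded loss is piecewise constant in `a` and goes flat
between argmax flips, so monitoring it would stop runs while the optimizer is
still making progress; the soft loss moves continuously and plateaus only at
a genuine stationary point.

Initialization draws every entry from U(0, 1); wildtype seeding adds exactly
0.5 to the wildtype letter's entry per design position, which makes the
wildtype the initial argmax with probability
`∫₀¹ min(1, r+0.5)^(k−1) dr ≈ 0.55` for k = 20 alphabet letters. Disallowed
letters (cysteine by default, overridable per position via an alphabet mask)
are pinned at a −10⁹ sentinel and receive zero gradient, so they can never be
decoded — exclusion is exact, not statistical.

## The toy oracle

The bundled oracle computes, for pair (i, j) and channel X, bin logits as the
bilinear form `z_b = Σ_{a,a'} s_i[a]·s_j[a']·W_X[a,a',b]` with a weight
tensor drawn once from a seed, and probabilities `softmax(z / temperature)`
(temperature default 1.0; sharper landscapes speed recovery experiments).
Its gradient is closed-form and is verified against central finite
differences (relative error < 1e−4 in tests; measured ≈ 1e−9). Targets are
built by taking the argmax bins of the oracle's prediction for a reference
sequence, which makes the reference a verifiable optimum candidate: tests
check it beats every single-mutant neighbor exhaustively, and the design loop
is required to reach the global minimum of the 8-letter, 3-position
enumeration (512 candidates) in ≥ 90 % of seeded runs.

Ensembles average member probabilities and renormalize (logit averaging
would be the alternative; probability averaging keeps members exchangeable
and the mean a distribution). External pretrained predictors register in
`ORACLE_REGISTRY` and must satisfy the same forward/vjp contract, checkable
on demand with the finite-difference helper.

## Geometry binning

Bin edges are configuration, with defaults of 0.5 Å bins on [0, 20] Å plus a
catch-all overflow bin for distances, 15° bins on (−180°, 180°] for
dihedrals, and 12° bins on [0°, 180°] for the planar angle. Bins are
half-open `[e_k, e_{k+1})` — a value exactly on an interior edge belongs to
the higher bin; a distance below 0 is an error; the top edge closes the last
angular bin.

## Library metrics

AAR is the percentage of design positions matching the wildtype, averaged
over a library. PSSMs are raw empirical frequencies without pseudo-counts.
The Bhattacharyya coefficient uses the standard `BC = Σ √(p·q)` per position
with `BD = −ln(max(BC, 1e−6))`; the floor prevents infinite distances for
disjoint profiles. Perplexity is `2^H` with the Shannon entropy H in bits,
so it ranges from 1 (one-hot) to 20 (uniform). Levenshtein distances are
exact unit-cost edit distances (computed with edlib; validated against a
Wagner–Fischer dynamic program in tests). FR scores are straight lookup sums
over supplied per-position enrichment tables.

## Developability

Instability index: Guruprasad dipeptide weights summed over the full heavy
chain, `II = (10/L)·Σ DIWV(x_i, x_{i+1})` (tables from Biopython's published
ProtParam data). GRAVY: mean Kyte–Doolittle hydropathy over the designed
stretch padded by 10 residues each side, clipped at chain boundaries. Net
charge: Henderson–Hasselbalch sum over D, E, C, Y (negative), H, K, R
(positive) and the free termini, EMBOSS pKa values, default pH 7.0 — both the
pH and the pKa set are configuration, since different tool lineages disagree
at the second decimal. Structure-based properties (aggregation patches,
solubility, MHC-II immunogenicity) require external tools and are left
absent rather than imitated.

## Screening

Design-region RMSD uses a two-stage rule: superpose the model on the target
over the framework (non-design) backbone N/CA/C atoms, then measure RMSD over
the design-region N/CA/C in that frame (O excluded). Per-residue RMSDs are
reported from the same framework frame. The fold gate passes designs with
RMSD ≤ 2.0 Å (default). The bind gate takes the minimum ΔG over 5 decoys per
design and passes designs at or below the wildtype reference ΔG (margin
default 0), with the reference computed through the same adapter. Adapter
failures mark the design failed and the run continues. The screened library
is the intersection of the two pass sets; the report carries per-design
metrics, gate counts and the screened-set PSSM.

## Synthetic fixtures and what they do not show

The fixture generator produces random Fv sequences (cysteine-free so default
masks accept the wildtype), toy backbones built on a self-avoiding walk with
3.8 Å Cα spacing and N/C/O/CB atoms placed in a local frame, and libraries
drawn from specified PSSMs so metric estimators have known expectations.
Default problem sizes (20-residue Fv, 3 design positions, 8 geometry bins,
libraries of 50–200) keep every test and the acceptance script fast while
exercising every code path. These fixtures carry no secondary structure,
no real loop geometry and no antibody physics: passing tests demonstrate the
correctness of the losses, gradients, optimizer mechanics, metrics and
pipeline logic — not the biological quality of designs, which depends
entirely on the oracle and adapters plugged in.

## Known limitations

* The straight-through estimator is a design choice; the soft-forward
  alternative (feeding softmax rows to the oracle) is available through the
  same API but is not the default loop.
* The contact mask is fixed from the target structure rather than refreshed
  from per-iteration predictions.
* Numbering is consumed, never computed — inputs must arrive Chothia-style
  annotated (or with any consistent per-chain labeling).
* The toy oracle's landscape is bilinear and far smoother than a real
  structure predictor's; convergence behaviour on real oracles will differ.
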