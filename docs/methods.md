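# Methods

## Models and estimators

### Multivariate Gaussian couplings

The MG estimator treats one-hot residues as continuous Gaussian variables.
The alignment is flattened to N × (L·A), mean-centered per column, and the
coupling matrix is the negative inverse of the shrunk empirical covariance
W = −(Cov(X̂) + (4.5/N)·I)⁻¹, reshaped to [L, A, L, A]. The ridge 4.5/N is
an empirically calibrated shrinkage constant; it guarantees invertibility
when N < L·A, which is the common regime. The covariance uses the 1/N
normalisation — the ridge dominates the 1/N-vs-1/(N−1) distinction, and
fixing it makes results bit-stable. The returned tensor keeps its diagonal
blocks (the classical "W + I makes no difference" observation); they are
excluded from contact ranking by zeroing the map diagonal before APC.

Gaps encode as all-zero one-hot slices rather than a 21st state, so A stays
20 and mean-centering treats a gap as the column mean.

### Contact maps and APC

Raw contact scores are per-pair Frobenius norms of the 20×20 coupling
blocks. The average product correction APC(i,j) = m_ij − (row_i·col_j)/total
removes the dominant rank-1 background (it cancels rank-1 inputs exactly and
leaves every row and column summing to zero). Ranking ties break by
ascending (i, j) for determinism.

### Categorical Jacobian

The Jacobian scans all L·A single-token substitutions (1 + L·A evaluations;
the mutant equal to the original token contributes a zero column, which is
kept for uniformity). Post-processing order is: center, then symmetrize.
Centering is a double-centering of each (i, j) block over both token axes;
this removes the per-block offset introduced by differencing against the
original sequence's logits and projects onto the zero-sum gauge, which is
what makes the linear-model identity exact. Symmetrization averages with
the (j, b, i, a) transpose — the Frobenius-closest symmetric tensor. Both
steps are idempotent and recorded in flags; the contact-map step refuses
unprocessed tensors.

The finite-difference variant adds `step` to one one-hot entry at a time
and divides by the step; it requires a model that accepts soft inputs. The
default step is 1.0, the categorical-like end of the range: on linear
models any step gives the identical post-processed tensor, and the
quantized-linear fixture demonstrates the saturating case where only a
large step reads anything out.

### Masked positions

Masked positions carry a sentinel token. The linear fixture gives them a
zero contribution — exactly the token-axis mean in the zero-sum gauge — so
masked-context Jacobians remain well defined. External adapters send the
wrapped model's mask id, and can present mask ids in the BOS/EOS framing
slots, the convention for contact-recovery experiments where the model
should not be told where the true termini are.

## Synthetic data generators

### Potts sampler

Alignments are Gibbs-sampled from an explicit Potts model: each sequence is
an independent chain (uniform random start, `n_sweeps` full passes over
positions, conditional softmax(h[i,:] + Σ_j W[i,:,j,x_j])). Independent
chains avoid autocorrelation/thinning choices; 20 sweeps is enough for the
small planted models used here (verified against exact enumeration on an
L=2, A=2 model, total variation < 0.02 at 50,000 samples). All randomness
flows through a single seeded generator.

Planted models place zero-sum-projected standard-normal 20×20 blocks
(default scale 1.0, comparable to the field scale and typical of a strong
contact) at disjoint position pairs, with zero fields so single-site
marginals stay near uniform. Default study conditions for parameter
recovery: L = 30, 5 planted pairs, N = 2,000 sequences — small enough to
run in seconds, large enough that the MG estimate separates planted from
background pairs cleanly.

What the generator does *not* emulate: phylogenetic relatedness (sequences
are i.i.d. draws), gaps, alignment errors, or the dense weak-coupling
background of real families. Passing the recovery tests therefore shows the
estimator and pipeline are correct, not that real-MSA accuracy matches any
particular benchmark figure.

### Synthetic contact model

The contact model returns base_map[i,j] when both i and j are "supported" —
at least `context_window` residues within ± `context_window` of the
position (excluding itself) are unmasked — else 0. For two far-separated
11-residue segments and window w > 10, every segment position becomes
supported at the same outer-flank length w − 10, so the recovery curve is
a clean 0 → 1 step whose location inverts to the construction parameter.
This emulates the qualitative step-function ("motif completion") behaviour
of supervised contact heads without any pretrained weights; it does not
emulate their graded probabilities, long-range context use, or noise.

## Experiment engine choices

* Segment pairs: 11 residues, centers scanned at stride 1 for the
  near-separation mode (centers exactly 15 apart); SSE-centered segments
  (centers supplied as input, ±5 residues) for separations 50–100 and >100,
  requiring more than 10 residues to each terminus. A pair qualifies when
  its 11×11 block sum strictly exceeds 10. Up to 3 pairs per protein: the
  first uniform at random, then farthest-point sampling on Euclidean
  center distance, ties to the lexicographically smallest pair.
* Random unmasking reveals 2k residues at step k so all strategies match
  counts (flank-symmetric adds k per outer flank), and random sets are
  nested across steps so a curve reflects one growing reveal.
* Recovery sums run over the 11×11 inter-segment block only; an all-zero
  reference block is undefined (NaN with a warning) and is excluded
  upstream by the block-sum selection rule.
* Jump classification: maximal one-step increase > 0.5 (strict); stability
  requires fewer than 3 of the next 10 steps dropping more than 0.2 below
  the value at the jump; total unmasked at the jump uses the curve's
  recorded counts (22 + 2·flank for untruncated symmetric schedules). The
  asymmetric variant grid-searches (k1, k2) for the minimal total reaching
  recovery. Only outward flank schedules are implemented; inward unmasking
  could reach smaller totals and is deliberately out of scope.

## Evaluation choices

* Structure contacts are Cα–Cα distances, strict `< threshold` (default
  10 Å); unresolved residues join neither ranking nor truth. Long-range
  means separation > 24 residues (|i − j| ≥ 25); P@L/2 uses k = ⌊L/2⌋.
* Tensor comparison gathers the top-L pairs by the linear model's APC map,
  double-centers each 20×20 block, and computes Spearman ρ over entries
  with |Ŵ| > b·SD(Ŵ); cutoffs retaining fewer than 3 entries report NaN.
  Per-block centering (rather than global) keeps the comparison in the same
  gauge the Jacobian post-processing uses.

## Numerical notes and limitations

* MSA filtering identity = matching columns / columns where not both
  sequences are gaps; greedy first-come-kept order in file order. Filtering
  is idempotent and monotone in both thresholds.
* The pairwise filter is O(N²L) Python; fine for the ≤ few-thousand-sequence
  alignments used here, not for metagenomic-scale inputs.
* The Jacobian is O(L·A) model calls — seconds for fixtures, but the cost
  is dominated by the wrapped model for real pLMs.
* Problem sizes used by the test suite and acceptance script (L ≤ 30,
  N ≤ 2,000, 3–5 seeds) were chosen so the full pipeline runs in seconds
  while leaving clear statistical margins.
* Reported precisions and correlations on fixtures exercise the exact code
  paths but do not estimate accuracy on real proteins; that requires
  pretrained model weights and curated structure sets, which are outside
  this package's scope.
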