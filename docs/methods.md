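# Methods

## Model

`dtocf` predicts chemical–protein interactions from positive-only data by
weighted nonnegative matrix factorization with two graph-Laplacian
penalties.  Let R be the n×m association matrix with known positives
Ω = {(i,j) : pair observed active}.  The loss is

    f(U, V) = Σ_ij W_ij (R̃_ij − U_i·V_j)²
            + p_reg (‖U‖²_F + ‖V‖²_F)
            + p_chem tr(Uᵀ(D_C − C)U)
            + p_prot tr(Vᵀ(D_T − T)V),      U ≥ 0, V ≥ 0,

with the one-class weight/target scheme

    W_ij = 1,   R̃_ij = 1       for (i,j) ∈ Ω,
    W_ij = p_wt, R̃_ij = p_imp  otherwise,

optionally replaced entry-by-entry by sparse override matrices.  The
scheme encodes the core one-class assumption: an unobserved pair is not a
negative but a weakly weighted observation whose expected value is the
prior probability `p_imp` that an untested pair truly interacts.  The
Laplacian terms equal ½ Σ S_ij ‖M_i − M_j‖² and pull latent rows of
similar entities together; this is what makes cold-start prediction
possible, since a chemical with no positives inherits its profile from its
structural neighbours.

### Assumptions

* Interactions are explained by r latent factors shared across the matrix
  (r well below min(n, m) in realistic use).
* The similarity principle holds: entities close in C (or T) have similar
  interaction profiles.  Where it fails (activity cliffs), the graph
  penalty is a bias; the benchmark's Tc strata expose exactly this regime.
* Similarity inputs are nonnegative, symmetric, bounded by 1, with zero
  diagonal (the diagonal cancels in the quadratic form and is therefore
  never stored; degrees exclude self).

## Optimization

The paper-standard fixed-budget scheme: seeded uniform initialization on
(0, 1/√r], then `p_iter` rounds of block multiplicative updates,

    U ← U ∘ [(W∘R̃)V + p_chem C U] ⊘ [(W∘(UVᵀ))V + p_reg U + p_chem D_C U + ε],

followed by the symmetric rule for V using the updated U.  With the global
scheme the two dense-looking products are decomposed exactly:

    (W∘R̃)V    = p_wt p_imp 1(1ᵀV) + A V,
    (W∘(UVᵀ))V = p_wt U(VᵀV) + B V,

where A and B are sparse on the support of Ω (plus overrides), with
A_ij = W_ij R̃_ij − p_wt p_imp and B_ij = (W_ij − p_wt)(U_i·V_j).  The
objective is evaluated the same way.  Nothing of size n×m is ever
allocated; per-round cost is O((n+m)r² + nnz(Ω)r + nnz(C)r + nnz(T)r).
Unit and acceptance tests pin both paths to a naive dense double-loop
implementation at 1e-10 relative tolerance, including per-entry overrides.

Numerical choices: division guard ε = 1e-12 added to denominators;
no early stopping unless an explicit relative tolerance is set (matching
the fixed iteration budget convention); objective recording costs one
sparse evaluation per round and can be disabled.  Multiplicative updates
preserve nonnegativity by construction and the recorded objective is
required (and tested) to be non-increasing within 1e-9 relative.
Ranking ties are broken by ascending protein index for determinism.

### Defaults

| parameter | default | meaning |
|---|---|---|
| p_wt | 0.1 | weight of unobserved entries |
| p_imp | 0.1 | imputed target (prior interaction probability) |
| p_reg | 0.1 | Tikhonov coefficient |
| p_chem | 0.75 | chemical-graph coefficient (0.25 paired with p_prot 0.25 is a documented alternative optimum) |
| p_prot | 0.1 | protein-graph coefficient |
| r | 300 | latent rank, sized for genome-scale corpora |
| p_iter | 400 | multiplicative rounds |
| ε | 1e-12 | division guard |

Desk-scale runs on the 200×100 synthetic instance use r = 40 with the same
regularization settings; r = 300 would be over-parameterized there (the
code warns when r exceeds min(n, m)).

## Similarity construction

Chemical: Tanimoto coefficient |a∩b|/|a∪b| on fingerprint bit sets, with
values below 0.5 zeroed as noise (a value exactly at 0.5 is retained).
Protein: directed bit-score ratio t(p₁,p₂) = d_bit(p₁,p₂)/d_bit(p₁,p₁)
from 12-column tabular sequence-search hits filtered at e-value 1e-5,
duplicate hits keeping the maximum bit score.  The ratio is asymmetric
while the Laplacian needs symmetry; the symmetric entry is the arithmetic
mean of the two directed ratios, a missing direction contributing 0, the
result clipped to [0,1].  The mean was chosen over max (biased up) and min
(discards one-directional evidence) as the unbiased bounded option.  No
noise floor is applied on the protein side.  `subsample_similarity`
removes unordered pairs at a given retention probability for ablation
experiments (half-filled / zero-filled matrices).

## Activity labelling

Assay records are aggregated per pair: all IC50 values at or below the
threshold (default 10 µM) → active; all above → inactive; records in both
ranges → ambiguous; no record → unknown (not stored).  Labels are decided
by set membership only — duplicate records within one class are not
averaged, since the label does not depend on it.  µg/L values convert to
µM by dividing by the molecular weight in g/mol.  Explicitly labelled
rows (curated drug–target lists) are accepted without IC50.

## Calibration

Raw scores of labelled pairs are binned at width 0.05; scores above 1.10
are outliers and dropped (a score exactly at the limit is kept in the top
bin).  With per-class normalized histograms p (active), N (inactive),
A (ambiguous), the mixture weight minimizing
E_sum(w₁) = Σ_i [A_i − (w₁ p_i + (1−w₁) N_i)]² is the closed form
w₁ = Σ(p−N)(A−N)/Σ(p−N)², clipped to [0,1] and verified against a 1e-4
grid search.  The inflation ratio w₂/w₁ multiplies each bin's inactive
count (rounded down) before the adjusted score
B_i = pos/(pos + ⌊ratio·neg⌋).  At the reference optimum w₁ = 0.16 the
ratio is exactly 5.25.  Empty interior bins interpolate linearly between
the nearest non-empty neighbours; empty edge bins take the nearest value;
scores above the outlier limit clamp to the top retained bin.
Calibration is strictly post-hoc and never enters benchmark CV.

## Benchmark harness

k-fold (default 10) uniform random partition of the positive pairs.  Per
fold the model is refit on the remainder and each held-out pair is ranked
against the chemical's candidate panel with that chemical's training
positives excluded — including them could only deflate recovery
mechanically.  The cutoff rank is ⌊fraction·candidates⌋ with a minimum of
1 (top 1% of 3,500 → 35).  Strata: NT class from the chemical's training
positives plus the hidden pair (NT1 = cold start, NT3 = three or more);
L bucket from the protein's training ligand count (1–5, …, ≥21, plus an
explicit L0 stratum for proteins with no training ligand so the views
stay exhaustive); Tc bucket from the chemical's maximum similarity to any
trained chemical, intervals (d−0.1, d] with the lowest bucket closed at
0.5 and a TcNone stratum below it.  Reports mean ± s.e.m. over folds and
keeps per-fold values so two methods can be compared by paired t-test.

## Repurposing

Latent profile similarity is the cosine of U rows (nonnegativity keeps it
in [0,1]; all-zero profiles are undefined and excluded).  Edges require
cosine strictly above the threshold (default 0.3, appropriate for sparse
genome-scale profiles; strongly graph-smoothed low-rank profiles have a
higher cosine baseline and warrant a higher cut).  Each edge carries the
structural Tanimoto value and a flag for Tanimoto < 0.5 — the
high-behavioural/low-structural combination that marks repurposing leads.
Markov clustering runs on the cosine-weighted network (not binarized) with
unit self-loops, expansion 2, inflation 2.0, pruning 1e-5 — canonical MCL
defaults, as no values are prescribed for this step.  Attractors define
clusters; a node claimed by several attractors joins the lowest-indexed
one, making the partition deterministic and permutation-invariant.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, at
desk scale: k = 4 latent blocks shared by n = 200 chemicals and m = 100
proteins.  Within a block, chemical i interacts with protein j with a
per-protein propensity drawn from Beta(mean = 0.5, concentration = 1);
cross-block pairs interact at 0.01.  The skewed propensity mirrors real
bioactivity corpora, where ligand counts per target are heavily
concentrated on a minority of promiscuous proteins — the very skew the
benchmark's L strata stratify over.  Similarities are
signal·1[same block] + N(0, 0.1) jitter, clipped to [0,1], with values
below a 0.5 floor dropped, because that is what the method's real inputs
look like: chemical similarities under 0.5 are suppressed as noise, and
sequence search returns no hit for unrelated proteins.  Without the floor
the jitter would join every entity pair into one dense graph and the
Laplacian would smooth all profiles toward a constant — a failure mode of
the emulation, not of the method.  Of the true pairs, 5% are observed
(bioactivity data is extremely incomplete) and 20% of those are held out
for recovery measurements.  Everything is driven by one seed.

What the generator does not emulate: real fingerprint geometry and
activity cliffs (similarity is exchangeable within blocks), assay noise
and inter-database inconsistency (no false positives), the empirical raw
score distribution of large corpora, and genome-scale skew beyond the
Beta propensity.  Passing the synthetic benchmarks therefore shows the
machinery is correct and the similarity principle is exploited; it does
not certify accuracy on any particular real corpus.

On this generator's default instance (5 seeds), held-out TPR@top-5% is
≈0.3 with p_chem = 0.75 against ≈0.15 with p_chem = 0 — the
similarity-ablation direction — and the protein-side analogue shows the
same direction when the chemical graph is absent; both are recomputed by
the test suite and `scripts/acceptance.py`, which also times a 2,000×500
fit (rank 50, 400 rounds, seconds on one CPU, peak traced allocation an
order of magnitude below a dense 2,000×500 array).

## Known limitations

* The multiplicative update rule is the package's own choice for
  minimizing the stated objective; only the objective, not the solver, is
  externally prescribed, so other implementations may reach different
  (equally valid) stationary points.
* Benchmark refits inside CV share the configuration seed across folds;
  fold-to-fold variation reflects data splits, not initialization noise.
* `build_chemical_similarity` is O(n²) over fingerprint pairs in Python —
  fine for desk scale; genome-scale corpora should supply precomputed
  similarity triplets instead.
* Scores are unbounded above 1; calibration, not clipping, is the
  supported way to interpret them probabilistically.
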