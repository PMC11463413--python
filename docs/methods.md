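# Methods

## Model and fitting procedure

HDMA treats the genome, transcriptome, and phenome of the same n individuals
as three similarity structures and asks for the one-dimensional scores
(G_C, T_C, P_C) most consistent with transcriptional mediation of genetic
effects. All three kernels are linear: features are rank-inverse-normalized
(Φ⁻¹((rank − 0.5)/n), average ranks for ties), column-standardized, and
K = ZZ'/m is double-centered and trace-normalized to n. Linear kernels were
chosen over nonlinear alternatives because the procedure is then a
constrained generalization of CCA, and loadings remain well-defined
back-projections (correlations of measured variables with the scores).
Trace normalization puts the three modalities on one scale so the path
coefficient ρ(G_C,T_C)·ρ(T_C,P_C) is comparable across fits.

Each kernel is represented by its top-r eigencomponents F = U·S^1/2. The
default r is the smallest rank capturing 95% of the kernel trace, capped at
n/2. The cap matters: with r ≈ n unconstrained projections can correlate any
two modalities almost perfectly (the standard CCA overfitting problem), and
the permutation test below exists precisely because the cap alone is not a
sufficient guard.

The fit alternates two exact steps from a deterministic start
(t = leading transcriptome eigencomponent):

1. given t, the genome and phenome scores are the orthogonal projections of
   t into their factor spaces (each maximizes its correlation with t);
2. given unit-norm g and p, the new t maximizes (a'b)(c'b)/(b'Sb) over
   transcriptome coordinates b (a = F_T'g, c = F_T'p). Every stationary
   point satisfies Sb ∈ span{a, c}, so the maximizer lies in
   span{S⁻¹a, S⁻¹c} and is found exactly by a 2×2 generalized symmetric
   eigenproblem. This replaces a gradient/line-search update: same
   objective, same fixed points, monotone, and step-size free.

Convergence is declared when the relative change in the path coefficient
falls below `tol` (default 1e-8, `max_iter` 500). At convergence the
perfect-mediation constraint is enforced exactly by projection: the
component of G_C orthogonal to T_C is removed from P_C, after which
ρ(G_C, P_C | T_C) = 0 to machine precision. Enforcing the constraint as a
terminal projection (rather than a penalty during iteration) keeps the
iteration a pure maximization and makes the constraint exact rather than
approximate.

Sign conventions: (i) if ρ(T_C,P_C) < 0, G_C and T_C are flipped jointly
(path invariant); (ii) when a trait matrix is available, all three scores
are flipped jointly so the trait with the largest |loading| loads
positively — the composite phenome score then reads as a disease index
(higher = more affected). If a score is exactly collinear with T_C the
partial correlation is undefined and reported as 0 (mediation is trivially
perfect).

## Permutation null

The observed path coefficient is compared with the paths obtained after
shuffling the individual labels of the (normalized) transcriptome matrix,
leaving the genome-phenome pairing intact, and refitting with identical
settings. Because column standardization is invariant to row permutation,
the permuted kernel is exactly P·K_T·P' and its eigenvectors are the
row-permuted originals; the implementation exploits this identity (verified
against an explicit rebuild in the tests, agreement ~1e-16) so each
permutation refit costs only the alternating iterations. p-values use the
add-one rule, p = (1 + #{null ≥ observed})/(n_perm + 1), and each
permutation's RNG stream derives from (seed, index), so results are
independent of execution order. Note that null paths are *large* (≈0.65-0.75
at n ≈ 100-200 with default ranks): unconstrained projections find highly
correlated composite vectors in any pair of big matrices. The test is
calibrated regardless, because observed and permuted statistics share that
overfitting; what is compared is whether the G-T and T-P correlations can be
maximized simultaneously.

## Heritability partition

For transcript y (rank-inverse-normalized; heritabilities are variance
ratios, so estimates are invariant to monotone-margin rescaling), REML under
y ~ N(0, σ²(h_l·K_local + h_d·K_distal + (1 − h_l − h_d)·I)) with an
intercept projected out via an orthonormal contrast basis. K_local uses
markers within ±10 Mb of the TSS (closed interval, configurable); K_distal
uses every remaining marker, including the rest of the TSS chromosome.
Kinships are scaled to mean diagonal 1. The likelihood is maximized on the
simplex by a coarse 0.05-step grid, a 0.01-step local grid, and two sweeps
of coordinate-wise golden-section polish; a property test checks agreement
with a dense 0.01 grid evaluation within one grid step. Solutions on the
simplex boundary are flagged; if the two kinships' off-diagonals correlate
above 0.999 only the total is identifiable and the estimate is flagged
`non_identifiable` with the total split evenly. Trait relevance is a
transcript's maximum absolute Pearson correlation across traits; the
package reports Pearson r (two-sided p) between each heritability component
and relevance across transcripts.

## Cross-population transfer

Transcript loadings learned in the discovery population score a new
population as Σ_g loading_g · z_g, with z_g standardized within the new
population — loadings encode direction and relative importance, not
absolute scale, so per-gene affine differences between cohorts are absorbed.
Local imputation fits, per gene, least squares of expression on the eight
founder-dosage columns of the single marker nearest the TSS (pseudoinverse
absorbs the dosages' sum-to-two collinearity); a windowed average would be a
drop-in alternative but the single nearest marker is the simplest faithful
"local genotype" model. Orthology or ID mapping enters as a two-column
table; unmapped and zero-variance genes are dropped and counted. Continuous
evaluations report Pearson r; two-group evaluations report the difference of
means with an exact two-sided Wilcoxon rank-sum p.

## Synthetic data generator

The generator emulates the two study designs end to end and is the basis of
every test:

- **Genomes.** Diploid founder mosaics: two independent founder-label Markov
  chains per individual per chromosome, switch probability 0.02 per adjacent
  marker interval, uniform founder frequencies; 8 founders, 10 chromosomes
  of 100 Mb, 1000 evenly spaced markers by default. The validation
  population is built from simulated inbred lines (single chains, doubled)
  crossed into F1s, giving long homozygous founder blocks and strain
  replicates — same founder alleles, sharply different kinship.
- **Transcripts.** Each transcript sits at a random marker (its TSS) and is
  the sum of a local founder-effect term at that marker (scaled to variance
  h²_local), a distal term summing weak founder effects at 50 markers on
  other chromosomes (scaled to h²_distal), and Gaussian noise. Background
  transcripts default to h²_local = h²_distal = 0.15, the observed scale for
  a median transcript in this study system. Core (trait-mediating)
  transcripts default to h²_local = 0.1 and h²_distal = 0.4, and draw half
  of their distal variance from one shared trans-acting program whose
  membership sign matches the transcript's trait weight — trait-relevant
  transcripts form a coherent, strongly distally heritable co-expression
  module, which is the regime the analysis is designed to detect. All effect
  scalings are recorded so the same founder effects regenerate expression in
  any population.
- **Phenotypes.** Every trait is the same weighted sum of the core
  transcripts plus independent noise (noise sd = 0.5 × the mediated
  component's sd by default, i.e. ~80% mediated trait variance). There is no
  direct genotype term, so perfect mediation holds by construction. Core
  weights have magnitudes uniform on [0.5, 1.5] with random signs: a core
  mediator has a substantive effect by definition.
- **Seeding.** One master seed; every sub-stream derives from
  (seed, labeled offset), so stages are individually and jointly
  reproducible.

What the generator does *not* emulate: realistic recombination maps, linkage
to selection, X-chromosome dosage, non-additive genetic effects,
tissue-specific expression correlation structure, count noise, or batch
effects. Passing tests therefore demonstrate correctness of the estimators
under the stated additive model, not robustness to every property of real
RNA-seq data.

## Problem sizes in tests and the acceptance script

The test suite and acceptance script run the full chain at desk scale,
chosen as the package's own reproducibility envelope: loading recovery at
the full default generator (n = 300, 2000 transcripts, 50 core mediators);
permutation calibration over 200 replicate null datasets (n = 100, 300
transcripts, 99 permutations each, fit tolerance 1e-6 for the batch);
heritability recovery over 200 transcripts at n = 400; the
relevance-direction check over 50 replicates at n = 140; and the
measured-versus-imputed contrast over 100 replicates (n = 200 discovery,
150 validation). The acceptance script reports single-batch versions of the
same quantities.

## Numerical choices and degenerate inputs

- Eigencomponents below 1e-10 of the leading eigenvalue are discarded;
  eigenvector orientation is fixed (largest-magnitude entry positive) so
  fits are bitwise reproducible.
- Constant features are dropped from kernels, get loading 0 with a
  `constant` flag, and relevance 0; constancy is detected by zero range, not
  near-zero variance.
- The 2×2 t-update falls back to the dominant single direction when the two
  candidate directions are numerically collinear.
- Matrix writers emit full-precision floats (%.17g) and readers parse with
  round-trip precision, so write→read is bitwise faithful; every writer
  emits a JSON sidecar manifest (dimensions + md5).
- Set-enrichment permutation p-values tolerate float summation-order noise
  when counting ties.

## Known limitations

- Single mediated axis only: the method extracts the leading mediation
  component; secondary axes are out of scope.
- The constraint is enforced at the optimum, not during iteration; on
  pathological inputs (e.g. phenome identical to genome) the terminal
  projection can visibly shift P_C.
- REML grid search is robust but O(grid × n³); transcriptome-wide scans at
  n in the thousands would want a dedicated AI-REML.
- The local window (±10 Mb) and the nearest-marker imputation model are
  pragmatic defaults, both configurable.
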