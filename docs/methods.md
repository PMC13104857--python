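# Methods

## The model

morphoscore calls hits in high-content imaging screens directly from
distributions of single-cell morphology profiles, rather than from per-well
aggregates.  It requires two control populations that define a phenotypic
axis: a **reference state** (e.g. diseased cells under vehicle control) and
a **target state** (e.g. healthy cells).  Everything else follows from two
steps.

**Signature derivation.**  For each morphology feature, a two-sample
Kolmogorov–Smirnov test compares the reference and target distributions;
the statistic is the supremum gap between the two empirical CDFs.  P-values
are corrected with the Benjamini–Hochberg step-up procedure across the full
feature space as a single family, at a significance threshold α (default
0.05).  Features with corrected p < α (strict) form the **on-morphology
signature** — the axis along which a successful perturbation must move
cells; the remainder form the **off-morphology signature**, where any
perturbation-induced change indicates off-target activity.  The two sets
are disjoint and jointly exhaustive by construction.

**Scoring.**  Let `d(A, B)` be the 1-Wasserstein (Earth Mover's) distance
between two single-cell populations restricted to the on-signature
features, computed as one multivariate discrete optimal-transport problem
with uniform point masses and Euclidean ground metric.  With reference R,
target T and perturbation P:

    on-score(P)  = d(P, T) / d(R, T)

The denominator — the **reference distance** — anchors the scale: the
reference point set itself scores exactly 1, the target point set exactly
0, and values above 1 mean the perturbation pushed cells past the reference
away from the target.  A fresh draw from the target distribution scores
slightly above 0 (sampling noise keeps the EMD positive).  The
**off-score** is the fraction of off-signature features whose distribution
differs significantly between the perturbation and a comparison population
(per-feature KS, BH-corrected within the perturbation's off-feature
family): 0 means no detectable off-target activity, 1 means every
off-feature moved.

## Numerical choices

- **Exact transport, two routes.**  Equal-size supports with uniform
  weights reduce optimal transport to a minimum-cost perfect matching,
  solved with the Hungarian algorithm; unequal sizes are solved exactly as
  a sparse transportation LP (HiGHS).  Only the optimal cost is ever used —
  the transport plan may be non-unique, the cost is not.  Cost grows
  quadratically with cell count, so scoring applies a
  `max_cells_per_population` cap (default 5,000; uniform seeded
  subsampling).  A labeled cheaper mode (`mode="per_feature"`) averages
  per-feature 1-D Wasserstein distances and deliberately ignores
  cross-feature structure; it is never the default.
- **KS p-values** use the asymptotic two-sample null by default; exact
  computation is available for small samples.  Ties need no jitter: the
  ECDF-sup statistic is well defined with ties.
- **BH rejection is strict** (adjusted p < α).  Constant features (zero
  spread in both populations) are degenerate for the KS test; they receive
  statistic 0, p = 1, fall to the off-signature, and are logged.
- **Kendall's W** is computed with the tie correction
  `W = 12S / (m²(n³−n) − mΣT)` by default; the correction can be switched
  off, since with midranks and no correction W cannot reach 1.
- **Empirical p-values** are plain proportions with ties counting as
  extreme; the (1+count)/(1+N) correction is an explicit option, off by
  default, so a reported 0 genuinely means "no permutation reached the
  observed value".
- **Degenerate inputs** fail loudly: an empty on-signature (states
  indistinguishable at α), a zero reference distance (identical point
  sets), constant input to a rank correlation, and populations below the
  2-cell floor are all hard errors, not silent zeros.

## Ambiguities resolved as configuration

Two readings of the method are genuinely open and are therefore explicit,
manifest-recorded configuration rather than silent defaults chosen deep in
the code:

- **Off-score comparison population.**  The off-score can test the
  perturbation against the *target* state (default) or the *reference*
  state (`off_comparison="reference"`).  Both are defensible; the default
  matches the interpretation of the score as "features that should have
  stayed where the target has them".
- **Control subsampling in the replicate analysis.**
  `control_subsample_fraction` defaults to 0.0002 (0.02%) with a floor of
  50 cells and a loud warning when the floor binds; at desk scale the floor
  always binds, and the fraction is first-class configuration.

## Evaluation procedures

**Leave-one-gene-out (LOGO).**  For each phenotype and each gene with at
least `min_cells` (default 5) cells labeled with it: the target population
is all cells of that phenotype *excluding the held-out gene's cells*, the
reference population is the negative-control (interphase analog)
selection, signatures are derived fresh, and the gene's full perturbation
group is scored.  Genes below the cell floor or whose derivation leaves a
signature empty are excluded with a recorded reason.  The guard is
auditable: with `record_indices=True` the result carries the target and
query row-id sets per pair, whose intersection must be empty.

**Feature-shuffled control.**  Signatures are derived on the original
profiles (so each keeps its real size), their on/off membership is randomly
reassigned at fixed sizes, and all scoring populations take their values
from a column-wise permutation of the table.  Deriving signatures from
shuffled values directly would leave them empty — after pooling, both
populations share the same marginals — which is why the control preserves
the original sizes; this is documented in `logo_analysis` and is the one
place where the procedure's order of operations is not the naive one.

**Rank concordance.**  Genes scored in every phenotype form a
phenotype × gene rank matrix (midranks on ties).  Kendall's W on this
matrix is compared against a null built by permuting gene labels within
each phenotype independently (default 5,000 iterations); the empirical p is
the proportion of permuted W at or above the observed value.  The null mean
sits near 1/m for m independent rankings, which the tests verify.  A
pairwise Spearman matrix of per-phenotype rank vectors accompanies W.

**Cross-plate replicate analysis.**  Each plate serves once as reference.
Per treatment and iteration, the plate's controls are subsampled, signatures
are derived with the treatment's reference-plate cells as reference state
and the subsampled controls as target state, and the treatment is scored on
every other plate (*paired*) alongside a randomly drawn different treatment
(*non_paired*).  Paired and non-paired distributions are compared with a
two-sided Mann–Whitney U test, BH-corrected across score types.

## What the synthetic screens emulate — and what they do not

The generator produces Gaussian profiles with unit marginal variance and an
optional single shared-factor correlation.  It plants exactly the structure
the method consumes: a known shifted feature subset between the two states
(default 5 of 20 features at 3 SD, 500 cells per group — large, clean
effects that make recovery checks sharp), treatments interpolated or
extrapolated along the reference→target axis at graded efficacy λ, optional
planted off-target shifts, gene/phenotype mixture labeling for LOGO, and
multi-plate layouts with additive plate offsets.  One root seed drives all
draws, so outputs are bit-reproducible.

Real image-based profiles are none of these things: features are heavy-
tailed, block-correlated by channel and compartment, and effects are small,
heterogeneous, and subpopulation-structured.  Passing tests on the
synthetic screens therefore demonstrates *correctness of the machinery* —
identities, invariances, error handling, recovery at planted effect sizes,
and the qualitative direction of every control — not expected performance
on any real screen.  Dataset-level numbers reported elsewhere for real
screens are not reproducible from this package alone and are not targets of
its test-bed.

In the multi-plate generator each treatment shifts its own small random
feature subset, so a non-paired (permuted) treatment tends to collapse
toward the control on the scored treatment's on-axis; paired scores
concentrate near 1.  The separation between paired and non-paired
distributions — tighter paired SD, significant Mann–Whitney U — is the
property under test, and holds regardless of which side of 1.0 the
non-paired mean falls on.

## Problem sizes used in the test-bed

Signature and scoring checks run at 500 cells per population (matching the
planted-screen defaults).  LOGO control checks use 10 genes × 3 phenotypes
at 60 cells per gene with labeled proportions graded 0.1–0.3 per phenotype,
and the shuffled-mode correlation is averaged over 4 shuffle seeds: the
rank-correlation estimator on 30 (gene, phenotype) rows has sampling SD
near 0.19, and the averaging brings the estimate's noise well inside the
decoupling band being asserted.  The replicate analysis runs on a 4-plate,
3-treatment planted screen (60 cells per group, 5 iterations) and a
2-plate label-free null screen over 5 seeds.

## Known limitations

- Per-feature univariate testing cannot see purely multivariate
  differences (it will miss a rotation that preserves all marginals);
  multivariate two-sample tests are out of scope.
- Exact EMD is O(n³)-ish in cell count; very large populations must be
  subsampled (the cap does this) or scored per-feature with the labeled
  1-D mode.
- The on-score measures distributional distance, not the fraction of cells
  rescued; a bimodal partial response and a uniform partial response can
  score identically.
- Signature quality is bounded by how separable the two control states
  are; with weak separation the on-signature shrinks and scores lose
  meaning (the package refuses to score when it is empty).
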