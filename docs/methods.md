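# Methods

## Decay model and preprocessing

A Mant-ATP chase trace is the mean fiber fluorescence sampled on an
acquisition grid (default: every 5 s for the first 90 s, every 10 s
thereafter to 300 s; 40 frames).  Preprocessing subtracts the mean
background frame-wise and divides by the background-subtracted intensity of
the final pre-washout frame, so the normalized value at t = 0 is exactly 1.
No correction is applied for the rapid washout of nonspecifically bound
Mant-ATP; the reported amplitudes therefore include that component, which is
the convention the rest of the analysis assumes.  Any strictly increasing
grid with at least 8 points is accepted — the standard grid is validated but
not required.

The normalized decay is modeled as

    F(t) = 1 − P1·(1 − e^(−t/T1)) − P2·(1 − e^(−t/T2))

with non-negative amplitudes (reported in percent; fitted internally as
fractions) and positive time constants, T1 < T2 enforced by post-fit
relabeling.  The plateau 1 − (P1+P2)/100 absorbs non-exchanging
fluorescence.

## Fitting

The model is linear in the amplitudes, so they are profiled out exactly:
for any (T1, T2) the optimal non-negative amplitudes solve a 2×2
non-negative least-squares problem in closed form (unconstrained normal
equations, falling back to the better single-component solution when the
optimum leaves the non-negative quadrant).  The remaining 2-parameter
problem over (log T1, log T2) is minimized by a Levenberg–Marquardt
iteration with numerical Jacobians, bound-clipped steps (time constants in
[10⁻², 10⁷] s), per-problem damping, and a step tolerance of 10⁻¹¹ in log
units.  The iteration is written batched so that whole cohorts (every trace
× every start) are optimized in a few vectorized passes; a scipy
`least_squares`/`curve_fit` route lands on the same optimum and is kept as
an independent cross-check in the test suite.

Because the amplitudes are profiled, multistart only needs to cover the
time constants: T1 ∈ {10, 30, 60} s × T2 ∈ {150, 250, 400} s (nine starts
spanning fast and slow phases of realistic fibers).  The start with the
lowest residual sum of squares wins; ties (within 10⁻⁹ relative) go to the
smaller fast time constant, which fixes the reported solution when the
surface has exchange-symmetric minima.  Amplitudes are bounded at zero
rather than left fully unconstrained: negative relaxed-state populations
are physically meaningless and the bound changes nothing for decays that
actually contain two phases.

Non-convergence is reported as a flag (`converged=False`), never an
exception, so cohort tables keep one row per fiber.  Degenerate single-phase
data (one true exponential) yields one near-zero amplitude; the active
phase may land in either slot depending on where the empty component
settles, so consumers should inspect amplitudes before interpreting a
collapsed fit.  Noiseless round-trip recovery is at machine precision;
at noise sd 0.01 on the 40-frame grid, per-fiber P1 estimates scatter with
sd ≈ 2–4 percentage points and the cohort-mean bias stays well under 1 pp
(measured by `scripts/acceptance.py`).

## Theoretical ATP consumption

Each relaxed population contributes amplitude × myosin concentration ×
turnover rate, with 220 μM assumed intrafiber myosin and 60 s·min⁻¹
converting to per-minute units.  The default (`corrected`) form divides
each term by its own time constant,

    ATP = P1/100·C·60/T1 + P2/100·C·60/T2,

treating T1 and T2 as the respective ATP turnover lifetimes of DRX and SRX.
A `verbatim` variant divides both terms by T1, reproducing the formula as
printed in the protocol this score originates from; the two differ by the
SRX term's time base, and both are exposed and tested because published
values may follow either convention.  The score is homogeneous of degree 1
in the myosin concentration and halving both time constants doubles the
corrected score.

For pharmacology designs (phosphatase / PKA vs. vehicle) the
relative-change transform divides every fiber's P1, P2, T1, T2 by the mean
of the vehicle group within its stratum (e.g. genotype), so the baseline
group maps to 1 by construction.  A paired same-fiber pre/post design would
be an alternative definition; the per-stratum vehicle mean was chosen
because it requires no fiber pairing and matches how grouped relative data
are usually presented.

## Group statistics

Two groups are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df); three or more with one-way ANOVA plus Tukey HSD;
genotype × treatment layouts with two-way ANOVA using type-II sums of
squares (the intended designs are balanced, where type I/II/III coincide)
plus Tukey HSD on cell means.  Every readout is analyzed at two levels:
pooling individual fibers, and after averaging fibers within subject.
Fiber-level pooling ignores the within-subject correlation of fibers — a
deliberate simplification matching field practice; a mixed-effects model
would be the rigorous alternative and is out of scope.  The significance
threshold defaults to 0.05 and is configurable.

## Fiber typing

MYH1/MYH2/MYH4/MYH7 abundances are summed and expressed as percentages; a
sample is a pure type (I, 2A, 2X, 2B) when one isoform reaches ≥ 80%
(inclusive threshold), otherwise a mixed type named by the two largest
contributors, highest first.  Ties are broken by the fixed order
MYH7 > MYH2 > MYH1 > MYH4 (slow to fast), which makes the label a
deterministic function of the composition.  The label is scale invariant.

## Proteomics pipeline

**Normalization.**  Isobaric-tag (reporter-intensity) matrices are rescaled
per sample so that every column carries the same total abundance.  The
common total is anchored at the largest column total by default (a "highest
channel" reference); the mean or a fixed value can be chosen instead.  Which
anchor is used changes only a global constant, not any fold change.

**Filtering.**  After log2 transform, proteins missing in *more than* half
the samples of any single group are removed (strict inequality; exactly 50%
survives).  The group-wise rule keeps proteins that are absent in one
condition but well measured in another — exactly the proteins MNAR
imputation is for.

**Mixed imputation.**  Per protein and per group: with ≥ 60% valid values in
the group, missing entries are filled by k-nearest-neighbour averaging
(k = 3 by default, Euclidean distance over proteins restricted to the
group's samples — neighbours are proteins with similar profiles in that
group).  Everything else is treated as left-censored and drawn from a
down-shifted Gaussian per sample: mean − 1.8·sd and width 0.3·sd of that
sample's observed values (a whole-matrix variant is available by flag).
Observed values are never modified, and the imputed-cell mask is returned
for audit.  The KNN detail (k, metric, neighbour universe) is a
convention choice; the defaults follow common Perseus-style practice and
are configurable.

**Differential abundance.**  Per-protein two-sided t-tests (Student's by
default, matching the Perseus convention for imputed matrices; Welch by
flag), BH adjustment across all tested proteins, and a joint gate:
significant iff q ≤ α (default 0.05) **and** |log2FC| ≥ log2(fc) (default
fc = 2).  At fc = 1 the gate reduces to pure FDR control.  The sign
convention is log2FC = mean(case) − mean(control); "up" means higher in the
case group.  A raw-p gate (p < α, no BH) is available for designs analyzed
that way.

**Restoration sets.**  Given a disease-vs-control contrast and a
treated-disease-vs-control contrast over the same universe, hits are
partitioned into: *maintained* (significant in both, same direction),
*restored* (significant only untreated — the treatment rescued them),
*emergent* (significant only treated), *discordant* (significant in both,
opposite directions).  The partition is exact: maintained ∪ restored ∪
discordant equals the untreated hit set, and the four sets are pairwise
disjoint.  An optional direction filter restricts both hit sets to down- or
upregulated proteins first, matching analyses that track one direction.

**Enrichment.**  Upper-tail hypergeometric tests per term against the full
identified-protein background, terms intersected with the background first;
terms overlapping the hit list in fewer than 5 proteins are excluded from
testing; BH across tested terms.

**PCA.**  Sample scores of the centered (optionally unit-scaled) complete
matrix, with explained-variance fractions — a compact check of group
separation and heterogeneity.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes — no more.

*Decay cohorts*: group means for (P1, P2, T1, T2) with Gaussian
between-subject and within-subject spread (defaults: control
20/45/25/230, disease 28/37/20/190; between-subject sd 2/2/2/15,
within-subject 3/3/2/15; 7 subjects × 10 fibers per group), sampled
hierarchically, clipped to the physical region (non-negative amplitudes
summing ≤ 98%, T2 ≥ 2·T1), and rendered as model curves plus i.i.d.
Gaussian noise (sd 0.01) on the standard grid.  The default parameter
separation (8 pp in P1, opposite in P2, faster time constants in disease)
mirrors a disease cohort with a DRX-shifted equilibrium.  Real traces have
correlated noise, photobleaching drift, and washout transients that this
does not emulate, so passing recovery tests demonstrate correctness of the
estimator, not robustness to every instrumental artifact.

*Abundance matrices*: per-protein baselines N(25, 2²) on the log2 scale,
within-group noise sd 0.3, a 4-group genotype × treatment design (n = 6),
50 effect proteins with ±2 log2-unit shifts in the knockout groups, a
configurable fraction (default 0.6) of effects attenuated to zero under
treatment, and MNAR missingness with dropout probability
expit(20 − x) in the true log2 abundance x — low-abundance entries censor
more, the left-censoring situation MinProb assumes.  Real data additionally
carry correlated protein modules and batch structure; calibration results
(FDR, sensitivity) are therefore statements about the independent-noise
regime.

*Annotations*: random term memberships over a given background with one
deliberately enriched term for calibration.

All generators are bit-reproducible given (spec, seed).

## Numerical and reporting choices

Report TSVs are rendered at 6 significant digits for diff-ability, with a
`*.full.tsv` companion at full precision; `manifest.json` records every
parameter, seed, and the package version.  Pipelines validate and compute
fully before writing, so a failed run leaves no partial outputs.  Problem
sizes in the verification scripts (200 traces / 200 cohort replicates /
100 matrix replicates, 1000-protein matrices) were chosen to pin Monte-Carlo
standard errors well below the assertion margins while keeping a full run in
the minutes range on one CPU.

## Known limitations

- Fiber-level tests pool fibers across subjects without modeling the
  within-subject correlation (subject-level averages are reported alongside
  as the conservative view).
- The biexponential fit assumes exactly two exchanging populations plus a
  plateau; nonspecific-binding washout is not modeled as a third component.
- The canine-style "data filtration" step that reduces a matrix to
  completely quantified proteins is intentionally exposed as configuration
  (complete-observation filter + raw-p gating) rather than hard-coded,
  because such criteria vary between cores.
- KNN imputation borrows across proteins, which slightly shrinks
  within-group variance; with the default 60% routing rule the affected
  fraction of cells is small.
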