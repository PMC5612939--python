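# Methods

## The trait model

The analysis treats the rRNA operon (rrn) copy number as a genus-level
growth-strategy trait. Copy numbers range from 1 to 15 on bacterial
genomes; low numbers mark slow-but-efficient (oligotrophic) strategists,
high numbers fast-but-inefficient (copiotrophic) ones. Because databases
report genus means over sequenced genomes, the unit of assignment is the
genus: every OTU of a genus receives the same integer copy number,
obtained by rounding the genus mean half-up and clamping into [1, 15].
Half-up rounding was chosen over ceiling because ceiling systematically
inflates copy numbers — genera with database means slightly above an
integer are conventionally reported at that integer. A `ceiling` switch
exists for sensitivity analyses.

Taxa are binned into LCN (rrn 1–3) and HCN (rrn 4–15); the two ranges
partition the biological range, so every assigned OTU falls in exactly
one bin. Per sample the pipeline computes, over assigned OTUs with
proportions p_i:

- `lcn_abund`, `hcn_abund` — summed bin proportions;
- `ratio_hcn_lcn = hcn_abund / lcn_abund`, flagged undefined (NaN) when
  the LCN abundance is zero, never +∞; downstream replicate averaging
  skips flagged values with reduced n and a warning;
- `cwm_rrn_abundance = Σ p_i · rrn_i` — the community-weighted mean;
- `mean_rrn_presence` — the unweighted mean over OTUs present
  (p_i > 0). Whether a presence-based community mean should average over
  OTUs or over genera is genuinely open — a database mean is a genus
  attribute, and OTU-level averaging weights genera by their OTU
  richness — so both are provided; the OTU-level mean is the default and
  `genus_collapse_presence=True` collapses to distinct genera first;
- distinct genus counts per bin, and their ratio via `genera_ratio`.
  Two estimators of a group-level genus-count ratio exist (ratio of
  replicate-mean counts, and mean of per-sample ratios); they differ in
  general and both are reported by the acceptance script, neither
  privileged.

**Renormalization.** Proportions are renormalized over the assigned
(optionally core-genus) OTUs before binning, so that
`lcn_abund + hcn_abund = 1` and the ratio is insensitive to the
unassignable fraction of the community. Whether to re-scale after
subsetting is not dictated by the problem; renormalization was chosen
because it makes the two bins a partition of unity and the ratio a pure
within-trait-axis quantity. `renormalize=False` gives whole-sample
denominators instead.

**Core genera.** Cross-dataset comparisons restrict to genera present in
every dataset ("typical biofilm formers"). Presence means: at least one
OTU of the genus reaching `min_count` reads (default 1) in at least
`min_prevalence` samples (default 1) of that dataset. The selection
returns the genus-set intersection plus, per dataset, the fraction of its
OTUs covered by the core.

**Succession phases.** Trait trajectories are replicate means ± sd per
time point, labeled *initial* when `time_days ≤ phase_cut` and *late*
otherwise. The cut defaults to 25 days and is inclusive, matching the
phrasing "up to 25 days" of the experimental design the package targets;
it is configurable.

## Rarefaction

Count tables are rarefied to a common depth by per-sample
multivariate-hypergeometric draws (subsampling reads without
replacement), the standard convention for count tables; the draw is
unbiased, so expected post-rarefaction proportions equal the source
proportions. Samples below the target depth are dropped with a warning
rather than padded — padding would fabricate reads. The depth is a
required parameter with no default, because no single depth is defensible
across datasets.

## Logistic growth model

Cell-count series are fitted with the Zwietering re-parameterized
logistic

    f(t) = A / (1 + exp(4 µ_max / A (L − t) + 2)),

chosen because its parameters are directly the reported quantities: A the
asymptote (count units), µ_max the maximum slope (count units per day),
and L the lag phase (days) — the time-axis intercept of the tangent at
the inflection point. Gompertz and Richards alternatives are out of
scope. Fitting is bounded nonlinear least squares (A > 0, µ_max > 0,
L ≥ 0; parameter/function tolerances 1e-10, at most 1500 function
evaluations) on the raw counts by default, matching the convention of
standard growth-fitting toolchains; a `log_transform` flag fits log1p
counts instead. Initialization: A₀ = max(y), µ₀ = the maximum
finite-difference slope, L₀ = the time of that slope minus A₀/(2µ₀),
clipped at 0; up to 5 seeded lognormal-jittered restarts, best residual
sum of squares wins. Non-convergence returns best-so-far parameters with
`converged=False`, never an exception. Two degenerate regimes are
flagged rather than reported as fits: µ_max at its lower bound (constant
series), and a fitted asymptote more than 10× above every observation —
the latter occurs when the curve never approaches saturation inside the
observation window, leaving (A, µ_max) unidentifiable.

Trait–growth relationships use closed-form OLS (statsmodels) with the
two-sided slope t-test and a 95% confidence band for the mean response.
Each regression point pairs one flume/treatment's time-averaged HCN:LCN
with that flume's fitted parameter; the grouping column is exposed
because the unit of replication is a design choice.

## Hypothesis tests

- **Migrant-pool null.** The observed community mean rrn is compared
  against means of random assemblies: each of `n_rep` (default 1000)
  replicates draws `n_draw` (default 150) copy numbers from the shared
  genus pool *without replacement* (a "sample of OTUs from a pool" reads
  as subset selection; a with-replacement switch exists). The empirical
  p is two-sided about the null mean with the add-one convention
  p = (1 + #{|draw − m| ≥ |obs − m|}) / (n_rep + 1), so p ∈ (0, 1] and
  is never zero. Under the null (observed assembled by the same process)
  the rejection rate at α is the lattice probability ⌈α(n_rep+1)−1⌉/(n_rep+1),
  slightly conservative, which the calibration test accounts for.
- **ANOVA + Tukey HSD.** One-way fixed-effects F from the explicit
  sum-of-squares decomposition (p from the F distribution), pairwise
  contrasts via the studentized-range distribution (scipy `tukey_hsd`).
  Zero within-group variance with distinct means yields the smallest
  representable positive p and a warning, not an exception.
- **Mann–Whitney U.** Exact enumeration when n₁+n₂ ≤ 12 and no ties
  (threshold keeps the exact path instantaneous); otherwise the normal
  approximation with midranks, tie-corrected variance and continuity
  correction. All values tied is handled as U = n₁n₂/2, p = 1.
- **Bonferroni.** p·m clipped at 1.

## Synthetic data generator

The generator emulates the structure of a flume succession experiment
and a multi-stream survey, not any particular dataset:

- **Community.** 60 genera, 3 OTUs per genus (180 OTUs), genus rank
  abundances from a geometric series (retention 0.92) with ranks assigned
  at random so abundance is not systematically tied to copy number; the
  copy-number spectrum is LCN-heavy and dominated by rrn-2 genera with a
  thin HCN tail to 15, mirroring stream biofilm communities.
- **Counts.** Dirichlet-multinomial per sample (concentration 200,
  depth 10^4): rarefied amplicon tables are overdispersed multinomials,
  and concentration 200 gives replicate ratio variation comparable to
  published succession error bars.
- **Succession.** Two regimes × 3 replicates × 7 time points (days 4–45).
  The boosted ("eutrophic") regime multiplies HCN genus abundances by
  1 + boost·exp(−decay·t) before renormalization; boost defaults to 1.0
  and decay to 1/25 per day, so the enrichment's e-folding time equals
  the initial succession phase (25 d): substantial throughout that phase,
  minor by day 45. Boost 0 is the null regime (no time–bin interaction).
- **Streams.** The same compositional machinery with a static HCN shift
  per habitat group and sample sizes 26 vs 50, the scale of a
  glacier-fed vs headwater comparison.
- **Growth curves.** The Zwietering logistic plus i.i.d. Gaussian noise
  truncated at zero.

Ground truth (expected bin proportions per sample, true copy number per
OTU, generating parameters) is always returned with the data; tests never
re-derive truth from generated tables. What the generator does **not**
emulate: phylogenetic structure among genera, sequence-level artifacts
(chimeras, clustering error), compositional correlations between taxa
beyond the Dirichlet, hydraulic treatment effects, or taxonomy
misassignment. Passing end-to-end tests therefore demonstrates that the
pipeline recovers trait dynamics from overdispersed compositional counts
with realistic replicate noise — not that it is robust to upstream
bioinformatic error.

## Problem sizes and numerics

The test suite and acceptance script run the succession experiment at its
default size (180 OTUs × 42 samples, depth 10^4), 50-seed Monte-Carlo
loops for recovery and end-to-end checks, and a 2000-run calibration of
the resampling null at n_rep = 200 — sizes at which every Monte-Carlo
interval used in an assertion is computed from the exact binomial or a
standard-error bound, not eyeballed. Proportion arithmetic is exact to
1e-12 against brute-force enumeration; sum-to-one invariants are enforced
at 1e-9 to absorb float accumulation. Ties in trajectory time points are
forbidden (strictly increasing); equal-mean degenerate inputs in the test
layer are handled as documented above rather than erroring.

## Known limitations

- Genus-level assignment inherits the database's averaging: within-genus
  copy-number variation is invisible, and unassignable OTUs are excluded
  (reported, with coverage) rather than imputed.
- The logistic fit assumes a single growth episode; diauxic or declining
  series will fit poorly (flagged by residuals, not detected
  automatically).
- Abundances are not copy-number-corrected: the pipeline analyzes trait
  distributions over 16S relative abundances as observed, which is the
  convention its target studies follow.
- The empirical p of the resampling null is lattice-valued with
  resolution 1/(n_rep+1); at the default 1000 replicates the smallest
  attainable p is ≈ 0.001.
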