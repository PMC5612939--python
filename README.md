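# rrntraits

Community-aggregated rRNA operon (rrn) copy-number trait analysis for
microbial communities, built for studies of stream biofilm succession.

Bacterial genomes carry 1–15 copies of the operon encoding the 5S, 16S and
23S ribosomal RNAs. The copy number is a growth-strategy trait: taxa with
few copies grow slowly but use resources efficiently, taxa with many copies
grow fast but inefficiently, with shorter lag times. `rrntraits` turns OTU
abundance tables into community-level trait statistics built on this axis
and provides the statistical machinery to compare them across succession
time series and habitats.

## What it computes

Given an OTU count table, an OTU→genus taxonomy, and a genus-level
copy-number lookup (an rrnDB-style export), the pipeline:

1. **Assigns copy numbers** per genus, rounding database means half-up to
   an integer clamped into [1, 15].
2. **Bins taxa** into LCN (low copy number, rrn 1–3) and HCN (high copy
   number, rrn 4–15) and computes, per sample over the assigned
   (optionally core-genus) OTUs with renormalized relative abundances
   p\_i:
   - summed bin abundances and their ratio **HCN:LCN**,
   - the community-weighted mean **CWM = Σ p_i · rrn_i**,
   - the unweighted mean rrn over taxa present,
   - distinct genus counts per bin and their ratio.
3. **Builds trait trajectories** (replicate mean ± sd per time point),
   split into an *initial* (≤ 25 d, inclusive, configurable) and a *late*
   succession phase.
4. **Fits logistic growth curves** (Zwietering parameterization
   `f(t) = A / (1 + exp(4·µ_max/A·(L − t) + 2))`) to cell-count series,
   yielding the asymptote A, the maximum growth rate µ_max and the lag
   phase L directly, and regresses trait ratios on these parameters (OLS
   with 95% confidence bands).
5. **Tests hypotheses**: a migrant-pool resampling null for the community
   mean rrn (150 OTUs drawn from the shared pool, 1000 times, two-sided
   add-one empirical p), one-way ANOVA with Tukey HSD contrasts,
   Mann–Whitney U (exact at small n, tie-corrected normal approximation
   otherwise) and Bonferroni correction.
6. **Simulates** all of the above: genus-structured Dirichlet-multinomial
   OTU tables with replicated succession time series, a two-habitat stream
   comparison, and noisy growth curves — always with ground truth emitted
   alongside.

## Worked example

Simulate the default two-regime succession experiment (oligotrophic null
regime, eutrophic regime with an initial HCN enrichment; 3 replicates,
7 time points over 45 days, 10^4 reads per sample), profile it, and test
the initial-phase regime contrast:

```python
import pandas as pd
import rrntraits as rt

tables, taxonomy, lookup, truth = rt.generate_succession(rt.SuccessionConfig(seed=42))
profiles = pd.concat([rt.trait_profiles(t, taxonomy, lookup) for t in tables])
traj = rt.trajectory(profiles[profiles.group == "eutrophic"], "ratio_hcn_lcn")
print(traj.to_string(index=False))
init = profiles[profiles.time_days <= 25]
res = rt.anova_tukey([
    (g, grp["ratio_hcn_lcn"].to_numpy()) for g, grp in init.groupby("group")
])
print(f"initial-phase Tukey HSD p = {res[1].p_value:.2e}")
print(f"genera ratio (oligotrophic worked value): {rt.genera_ratio(34.3, 97.4):.2f}")
```

prints

```
 time_days     mean       sd  n   phase
       4.0 0.688718 0.049552  3 initial
      11.0 0.685483 0.119187  3 initial
      18.0 0.648322 0.046908  3 initial
      25.0 0.643497 0.054661  3 initial
      32.0 0.481084 0.117390  3    late
      39.0 0.545076 0.069029  3    late
      45.0 0.495460 0.087833  3    late
initial-phase Tukey HSD p = 3.18e-08
genera ratio (oligotrophic worked value): 0.35
```

The eutrophic HCN:LCN ratio is elevated through the initial phase and
decays toward the oligotrophic baseline afterwards; the Tukey contrast of
the two regimes over the initial-phase samples is strongly significant;
and the ratio of the replicate-mean HCN and LCN genus counts of the
oligotrophic system (34.3 and 97.4 genera) is 0.35.

The same steps are available from the shell:

```sh
rrntraits simulate succession --seed 42 --outdir sim/
rrntraits traits --table sim/otu_table_eutrophic.tsv \
    --metadata sim/sample_meta_eutrophic.tsv \
    --taxonomy sim/taxonomy.tsv --lookup sim/rrn_lookup.tsv \
    --out profiles.tsv --trajectory-out trajectory.tsv
rrntraits compare --profiles profiles.tsv --groupby replicate --test anova --out tests.json
```

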