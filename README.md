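# connectocentric

Density-integrated centrality analysis of structural brain connectomes,
built for the question whether the piriform cortex — the three-layered
primary olfactory cortex at the frontotemporal junction, and a highly
seizure-prone structure — occupies a more central ("hub-like") position in
the white-matter network of patients with drug-resistant temporal lobe
epilepsy.

The package is aimed at researchers analyzing tractography-derived
connectomes: it takes per-subject streamline-count matrices with waytotals
plus a clinical table, and runs the complete analysis — matrix processing,
graph metrics, and the inferential layer — behind a statsmodels-style
`Model.fit() -> Results` API with a thin CLI. Because patient diffusion-MRI
data of this kind cannot be shared, a calibrated synthetic-cohort generator
(`connectocentric.synthetic`) reproduces the statistical structure of such
cohorts, so the whole pipeline is testable end to end.

## Method

For each subject with connectivity matrix W (entry W_ij = streamlines
seeded in parcel i reaching parcel j) and per-parcel waytotals w:

1. normalize rows, W_ij <- W_ij / w_i;
2. symmetrize, W <- (W + W^T)/2;
3. threshold proportionally at each network density d in {20%, ..., 40%}
   (1% steps): keep the k = round(d * n(n-1)/2) strongest connections,
   binarized;
4. on each of the 21 binary graphs compute node degree k_v and betweenness
   centrality BC(v) = sum_{s<t, s,t != v} sigma_st(v)/sigma_st (Brandes'
   algorithm, unnormalized);
5. sum each metric across the 21 densities — an AUC over the sweep —
   giving one threshold-independent value per node per subject.

Inference on the integrated metrics: two-sample permutation t-tests
(pooled t, 100,000 permutations, add-one two-tailed p, exhaustive
enumeration when feasible) for drug-resistant vs drug-sensitive at the
bilateral piriform ROIs (Bonferroni alpha = 0.05/4 = 0.0125); Spearman
correlations with epilepsy duration (age-at-MRI control); OLS covariate
adjustment; an exploratory whole-network scan with Benjamini-Hochberg FDR
across the 82 nodes; and a surgical-outcome subanalysis (ILAE class 1 vs
other, alpha = 0.05/10 = 0.005). See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

```python
import connectocentric as cc

cohort = cc.generate_cohort(cc.CohortSpec(seed=1))   # 64 synthetic subjects
config = cc.AnalysisConfig(n_permutations=10_000, seed=1)
results = cc.ConnectomeCentralityModel.from_cohort(cohort, config).fit()
print(results.summary())
```

prints (abridged):

```
Connectome centrality analysis
================================================================
subjects: 64 (resistant 43, responsive 19, resistance unknown 2)
densities: 20-40% step 1%; permutations: 10000

Primary tests (drug-resistant vs drug-sensitive), alpha = 0.0125
node                    metric               t       d         p  sig
lh_piriform             degree           3.136   0.864   0.00250  *
lh_piriform             betweenness      3.298   0.909   0.00200  *
rh_piriform             degree          -0.309  -0.085   0.75822
rh_piriform             betweenness     -0.332  -0.091   0.73153

Spearman correlations
node                    metric        covariate            rho         p
lh_piriform             degree        duration_years     0.343   0.00680
lh_piriform             degree        age_at_mri         0.244   0.05620
...
```

The cohort was generated with a planted left-piriform degree effect
(realized Cohen's d = 0.864 against a 0.85 target; the generator calibrates
per-subject scaling by bisection) and a duration coupling targeting
Spearman rho = 0.39 (realized 0.343 for this seed). The fitted results
recover exactly that structure: both left-piriform metrics are significant
at the corrected alpha while the right piriform shows nothing, duration —
but not age at MRI — correlates with left-piriform centrality, and the
resistance effect survives OLS adjustment for duration and the full
covariate set (`results.regressions`). `results.exploratory` holds the
per-node scan; `results.save(dir)` writes `report.json` and CSV tables.

The same analysis runs from files:

```sh
synth-cohort --out cohort/ --seed 1
connectocentric run --matrices cohort/ --clinical cohort/clinical.csv \
    --seed 1 --out report/
connectocentric metrics --subject cohort/sub-000_matrix.tsv \
    --waytotals cohort/sub-000_waytotals.tsv
```

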