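# circaclust

Behavioural circadian-rhythm profiling from wrist-accelerometer data.

Wrist accelerometers measure the bio-behavioural expression of the
circadian clock — the sleep–wake cycle — at scale. Most analyses reduce
it to a handful of rest-activity-rhythm summaries. `circaclust`
implements a fuller treatment for epidemiological cohorts: it derives
**36 epoch-level metrics across four circadian dimensions** and groups
participants into data-driven circadian profiles with a **two-step
PCA + k-means procedure**, then characterises the profiles with
multinomial covariate associations and survival-concordance comparisons.

The four dimensions and their metrics:

* **Rest-activity rhythm (6)** — cosinor mesor, amplitude and R² fitted
  to log(acceleration + 1); interdaily stability (IS), intradaily
  variability (IV); relative amplitude RA = (M10 − L5)/(M10 + L5).
* **Daytime activity (15)** — total duration, bout count and mean bout
  length for sedentary behaviour (SB, < 30 mg), light activity (LIPA)
  and moderate-to-vigorous activity (MVPA, ≥ 100 mg); mean waking
  acceleration; M10 mean; transition probabilities activity→rest
  (TPar,d) and rest→activity (TPra,d); intensity-gradient intercept and
  slope (OLS of ln time on ln intensity over 25-mg bins).
* **Sleep (10)** — sleep duration, efficiency, mean acceleration over
  the sleep period, L5 mean, sleep-bout count and mean length,
  TPsw,n / TPws,n, WASO, mean wake-bout length.
* **Chronotype (5)** — sleep onset and waking times, M10 and L5 start
  times, cosinor acrotime (noon-anchored hour scale, so times straddling
  midnight average correctly).

Participants enter the analysis with at least five *valid full day
windows* (a waking period plus its following sleep period, each with
wear time ≥ 2/3). The clustering step standardises the 36-metric matrix,
retains principal components by the joint rule *eigenvalue ≥ 1 and
cumulative explained variance ≥ 75 %*, sweeps k-means over K = 4…12 with
many restarts, and ranks candidate K by silhouette and Davies–Bouldin
index subject to a minimum cluster size; the final K stays
user-confirmable because cluster interpretability is a human judgement.

Because real cohort accelerometer records live behind restricted-access
portals, the package ships a first-class **synthetic cohort simulator**:
multi-day epoch ENMO traces with a diurnal cosinor envelope, a
semi-Markov SB/LIPA/MVPA waking process, scheduled sleep periods with
Poisson wake bouts and restlessness, chronotype offsets, non-wear gaps,
sleep diaries, covariates and survival times tied to a per-phenotype
hazard. Every pipeline stage is tested against this planted ground truth.

## Worked example

```python
import circaclust as cc
from sklearn.metrics import adjusted_rand_score

# 600 participants, 7 days of 60-s epochs, four planted phenotypes
cfg = cc.CohortConfig(n_participants=600,
                      archetypes=cc.default_archetypes(4), seed=11)
bundle = cc.simulate_cohort(cfg)

table = cc.MetricExtractor(sleep_mode="diary_guided").transform(bundle)
pipe = cc.CircadianClusterPipeline(n_start=100, min_size=30,
                                   random_state=0).fit(table)

print("components retained:", pipe.pca_.n_retained_,
      "cumulative variance: %.3f" % pipe.pca_.cumvar_)
print("recommended K:", pipe.k_)
truth = bundle.truth.loc[pipe.labels_.index]
print("ARI vs planted phenotypes: %.3f"
      % adjusted_rand_score(truth, pipe.labels_))
```

Output:

```
components retained: 4 cumulative variance: 0.896
recommended K: 4
ARI vs planted phenotypes: 0.996
```

The pipeline retains four components covering ~90 % of the variance of
the 36 metrics, recommends K = 4 (the silhouette-best eligible
solution), and the assignments agree almost perfectly with the planted
phenotype labels (adjusted Rand index 0.996; 1.0 is identity).

The same objects expose the downstream statistics: `choose_reference`
picks the reference profile (the one whose standardized metric means all
lie within one SD), `fit_multinomial` produces the odds-ratio table of
covariates against profile membership, and `metricset_comparison` fits
PCA + Cox mortality models on the full 36 metrics versus the common
10-metric subset and compares their Harrell C-indices with a paired
bootstrap.

A `circaclust` command-line interface wraps the same steps
(`simulate`, `metrics`, `cluster`, `associate`, `evaluate`); all inputs
and outputs are delimited text tables.

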