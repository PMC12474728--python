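# metabopanel

Matched case–control discovery of urinary metabolite markers for gestational
diabetes mellitus (GDM) in late pregnancy, packaged as a tested, reusable
pipeline. It is aimed at reproductive-metabolomics researchers who want to
run — or stress-test — the full analysis chain on their own cohorts or on
synthetic ones: case–control matching, urine-dilution normalization,
one-metabolite-at-a-time screening, consensus multivariate marker selection,
and a small classification-tree predictor.

## What it computes

Given a subject table (demographics + urine osmolality) and a samples ×
metabolites peak-area matrix with annotations:

1. **Matching.** Each GDM case is paired to one control from a larger pool by
   minimizing a weighted standardized dissimilarity score — a zero-covariance
   special case of the Mahalanobis distance in pooled-SD units:
   `score = (3·[(ΔGA1/SD + ΔGA2/SD)/2] + 2·ΔAge/SD + ΔBMI/SD)/6`
   (gestational ages at the two collections, maternal age, pre-pregnancy
   BMI). Selection is a min-cost bipartite assignment (greedy available).
2. **Normalization.** Endogenous metabolites only; peak areas divided by the
   per-sample dilution factor (osmolality over cohort median), scaled to the
   per-metabolite median, natural-log transformed.
3. **Bivariate screen.** Per metabolite: effect size
   d = (mean GDM − mean CON)/pooled SD on the log scale with nominal t-test
   P, plus an in-sample optimal-cutpoint ranking by unweighted accuracy
   ( = (sensitivity + specificity)/2 ).
4. **Consensus selection.** Metabolites ranked under random-forest
   permutation importance, random-forest Gini worsening, and
   gradient-boosting relative influence; candidates are the three-way
   intersection of the top-30 sets.
5. **Tree model.** A five-level (≤ 4 nested splits) CART-style tree on a
   candidate panel, evaluated by sensitivity, specificity, unweighted
   accuracy and ROC AUC; a fixed early-pregnancy seven-metabolite panel is
   fitted alongside for comparison.

A seeded synthetic-cohort generator reproduces the study design (46 cases,
138-control pool, 626 endogenous metabolites, eight marker metabolites
planted at their published log-scale effect sizes, log-normal urine
dilution), so every stage is testable without any data download. See
`docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import metabopanel as mp

cfg = mp.default_paper_config(seed=11)
subjects, matrix, truth = mp.generate_cohort(cfg)

matches = mp.match_cohort(subjects)                     # 46 pairs
print(f"match score {matches.mean:.2f} ± {matches.sd:.2f} SD units")

norm = mp.normalize(
    mp.filter_endogenous(matrix).subset_samples(matches.case_ids + matches.control_ids),
    subjects,
)
is_case = (subjects.loc[norm.sample_ids, "group"] == "GDM").to_numpy()

print(mp.effect_table(norm.values, is_case, norm.annotations).head(3).to_string(index=False))

clf = mp.fit_tree(norm.values, is_case, panel=list(mp.LATE_PANEL))
r = mp.evaluate(clf, norm.values, is_case)
print(f"sens {r.sensitivity:.1f}%  spec {r.specificity:.1f}%  "
      f"acc {r.unweighted_accuracy:.1f}%  AUC {r.auc:.3f}")
```

prints

```
match score 0.32 ± 0.10 SD units
               metabolite                             pathway        d  nominal_p
3-methylhexanoylcarnitine               Fatty acid metabolism 1.035725   0.000003
  3-hydroxydodecanedioate  Medium chain fatty acid catabolism 0.815875   0.000177
            acetylcholine Choline metabolism neurotransmitter 0.789527   0.000275
sens 87.0%  spec 89.1%  acc 88.0%  AUC 0.953
```

The mean pair score of 0.32 SD units says matched pairs differ by about a
third of a pooled SD across the weighted covariates. The top effect sizes
recover planted markers (3-methylhexanoylcarnitine planted at d = 0.673,
3-hydroxydodecanedioate at 0.759; estimates carry sampling noise at
n = 46/group), and the eight-metabolite tree separates GDM from controls
with 88.0% apparent unweighted accuracy on this draw.

The same flow is available from the shell:

```bash
metabopanel run --seed 11 --out results/run11
metabopanel simulate --out cohort --seed 11
metabopanel match --subjects cohort/subjects.csv --out results/match
```

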