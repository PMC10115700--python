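# cdmkit

Cognitive diagnosis modeling (diagnostic classification) for binary item
response data: G-DINA family measurement models, EM estimation over latent
attribute profiles, log-linear structural models, empirical Q-matrix
validation, model selection and fit, respondent classification, and
prior-sensitivity (lens / RMSD) analysis.

## Who this is for

Researchers who have item-level responses to a symptom inventory or skills
assessment — for example alcohol-related problem, anxiety, hostility, and
depression items from a college-student mental health screen — and who want
to classify respondents by *which* latent attributes (symptom clusters,
skills) they have, rather than score them on a single severity continuum.

## The model

Each respondent carries a binary attribute profile **α** ∈ {0,1}^K, one of
2^K latent classes. A J×K Q-matrix records which attributes each item
measures. The saturated G-DINA item response function gives item *j*, with
K_j required attributes, a free endorsement probability for each of its
2^{K_j} reduced attribute combinations:

    P(X_j = 1 | α*_j) = δ_j0 + Σ_k δ_jk α_k + Σ_{k<k'} δ_jkk' α_k α_k' + …

Setting interactions to zero on the identity, logit, or log scale gives the
reduced A-CDM, LLM, and RRUM; DINA and DINO are the two-parameter
conjunctive/disjunctive special cases. A monotonicity constraint ensures an
extra attribute never lowers the endorsement probability.

The joint distribution of the profiles (the structural component) is a
dummy-coded log-linear model; order 1 is attribute independence, order 2 the
homogeneous-association model, order K saturated. Marginal maximum
likelihood estimation runs EM over the 2^K classes; standard errors come
from the outer-product-of-gradients information.

Around the core fit the package provides:

- **Q-matrix validation** — GDI / PVAF and mesa plots per item, with
  advisory (never auto-applied) q-vector suggestions;
- **model selection** — item-level Wald tests of reduced vs saturated
  models, LRT for nested fits, AIC/BIC, and the limited-information
  M2 / RMSEA2 absolute fit statistic from univariate and bivariate margins;
- **classification** — MAP profiles, EAP attribute probabilities, and
  test-/attribute-level accuracy indices;
- **lens analysis** — posterior attribute probabilities under the fitted
  joint ("prevalence") prior vs the matched-marginal independence prior,
  summarized per attribute by RMSD_k = √(Σ_i (P_ik^(in) − P_ik^(pr))² / N);
- **simulation** — a generator whose default scenario mirrors a published
  40-item, 4-attribute mental-health inventory (35 single-attribute and 5
  two-attribute items, correlated attributes).

## Worked example

```python
import numpy as np
import cdmkit as ck
from cdmkit.classification import classify, lens_analysis
from cdmkit.structural import fit_loglinear, interaction_odds_ratio, marginals

scen = ck.mental_health_scenario(seed=3, N=719)
responses, profiles = ck.simulate_scenario(scen)

fitted = ck.fit_cdm(responses, scen.Q, structural="saturated", seed=3)
print(f"loglik = {fitted.loglik:.2f}, AIC = {fitted.fit['AIC']:.2f}")

item26 = fitted.items[25]          # an anxiety+depression item
print("item26 probs:", np.round(item26.probs, 2))

hom = fit_loglinear(fitted.structural.probs * responses.N, 2, scen.Q.attribute_names)
lam = dict(zip(hom.lambda_labels, hom.lambdas))
print(f"hostility x depression lambda = {lam['Hostility × Depression']:.2f}, "
      f"OR = {interaction_odds_ratio(lam['Hostility × Depression']):.2f}")

cls = classify(responses, fitted.items, fitted.structural)
print(f"test-level accuracy {cls.test_accuracy:.2f}")
lens = lens_analysis(responses, fitted.items, fitted.structural, scen.Q)
print("RMSD per attribute:", np.round(lens.rmsd, 2))
```

Output (N = 719 simulated respondents):

```
loglik = -9978.74, AIC = 20167.48
item26 probs: [0.04 0.22 0.29 0.87]
hostility x depression lambda = 2.85, OR = 17.27
test-level accuracy 0.91
RMSD per attribute: [0.01 0.1  0.15 0.06]
```

The four `item26` probabilities are the endorsement rates for respondents
with neither attribute, only depression, only anxiety, and both; their
spread (discrimination ≈ .8) shows the item separates profiles sharply. The
hostility×depression log-linear coefficient says those attributes co-occur
about 17 times more often than independence would predict in this draw. The
RMSD column shows classification of hostility borrows the most information
from the other attributes, and alcohol-related problems the least.

## Command line

```sh
cdmkit simulate --n 719 --seed 5 --outdir sim
cdmkit validate-q --responses sim/responses.csv --qmatrix sim/qmatrix.csv
cdmkit fit --responses sim/responses.csv --qmatrix sim/qmatrix.csv --out fit.json
cdmkit report --responses sim/responses.csv --qmatrix sim/qmatrix.csv --outdir results
```

`report` runs the whole pipeline (saturated fit → Q-validation → Wald
selection → structural comparison → final fit → classification → lens) and
writes CSV/JSON outputs plus a manifest. Q-matrix edits are only applied
through an explicit `--accept-suggestions item29` style flag.

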