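# steptraj

Latent-class trajectory analysis of roughly one year of daily step counts,
and its relation to clinically meaningful (≥3%) weight loss.

## The problem

Cross-sectional comparisons of average daily steps hide *how* activity
changes over time: two people averaging 7,500 steps/day may be steadily
increasing or steadily declining. `steptraj` is for epidemiologists and
health-data scientists who have long-format daily step records (e.g. from a
smartphone health app) linked to two annual health checkups and want to

1. clean the device data (merge dual-platform duplicates keeping the larger
   value, drop days with < 200 or > 50,000 steps, build complete weekly mean
   series between checkups, exclude high-variance recorders),
2. cluster the weekly series into latent trajectory classes,
3. label each class by its shape (UP, DOWN, UP/DOWN, DOWN/UP, FLAT), and
4. estimate adjusted odds ratios of ≥3% weight loss by trajectory class.

Because app-linked checkup data of this kind are typically not public, the
package ships a synthetic cohort generator with the same latent-class
structure, calibrated to published cohort summaries, so the entire pipeline
is testable end to end.

## The model

Weekly mean steps $Y_{ij}$ of participant $i$ at elapsed week $t_{ij}$
follow, conditional on latent class $g$,

$$Y_{ij}\mid g=\beta_{0g}+\beta_{1g}t_{ij}+\beta_{2g}t_{ij}^2+u_i+\epsilon_{ij},$$

with random intercept $u_i\sim N(0,\sigma_u^2)$ and residual
$\epsilon_{ij}\sim N(0,\sigma_\epsilon^2)$. Class membership has prior
$\pi_g=e^{\gamma_g}/\sum_l e^{\gamma_l}$ ($\gamma_G=0$). Marginally each
participant's series is multivariate normal with compound-symmetry
covariance $\sigma_u^2J+\sigma_\epsilon^2I$, and the mixture log-likelihood

$$\ell(\theta)=\sum_i\log\sum_g \pi_g\,L_g(Y_i\mid t_i,\theta)$$

is maximized by multi-start EM with a Marquardt-damped Newton polish.
Participants are assigned to their maximum-posterior class
$\hat\pi_{ig}$. The number of classes $G\in\{1,\dots,5\}$ must satisfy:
every class holds ≥ 5% of participants, every class's mean posterior among
assigned members is ≥ 0.90, and BIC $=-2\ell+k\ln N$ is minimal among the
admissible candidates.

## Worked example

```bash
steptraj run --seed 7 --n 400 --out run7
```

simulates the default 4-archetype cohort (400 participants, 52 weeks),
cleans it, searches G = 1..5, labels the chosen classes and fits the
outcome models. The same thing in Python:

```python
from steptraj import default_config, generate_population, preprocess
from steptraj import SeriesSet, select_G, label_classes

steps, shc, truth = generate_population(default_config(n_participants=400, seed=7))
prep = preprocess(steps, shc)
sel = select_G(prep.weekly, seed=7, n_starts=2)
print(sel.table[["G", "bic", "min_share", "min_mean_posterior", "admissible"]])
print(sel.n_classes, label_classes(sel.fit, T=52))
```

prints

```
 G           bic  min_share  min_mean_posterior  admissible
 1 339022.661847     1.0000            1.000000        True
 2 333761.052523     0.0675            1.000000        True
 3 327740.718825     0.0675            1.000000        True
 4 326970.057341     0.0675            0.996406        True
 5 326991.129694     0.0675            0.684578       False
4 ['UP_DOWN', 'UP', 'DOWN', 'FLAT']
```

The 4-class model is the smallest-BIC admissible model (the 5-class fit
fails the 0.90 mean-posterior rule), and the four recovered curves carry
the generating archetype labels — classes are listed by descending mean
level, so the order of labels varies with the fitted levels. `run7/report.json` additionally holds the
per-class ≥3%-weight-loss percentages and the adjusted odds ratios of each
class against FLAT, e.g. an UP-vs-FLAT odds ratio around 2–3 reflecting
the configured effect of a rising step trajectory on weight loss.

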