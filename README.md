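# affectmc

Covariate-dependent Markov chain (CDMC) analysis of emotional-valence
transitions in human–AI dialogue.

## The problem

During a multi-turn conversation with a generative AI system, a user's
emotional valence — discretized to *negative*, *neutral*, *positive* —
evolves turn by turn, and each AI response acts as a stimulus whose
perceived quality (*low*, *medium*, *high*) can push the next state up
or down. `affectmc` is for researchers in human–computer interaction,
learning analytics, and affective computing who have turn-level logs of
states and quality labels and want to model the transition dynamics
rather than static averages.

## The model

The next state is multinomial given the current state context and the
quality of the intervening response:

```
P(X_{t+1} = j | X_t = i, Z_t = z) = softmax_j( α_ij + β_ij[z] )
```

with the *neutral* next state as the reference outcome (its linear
predictor is fixed at 0) and *high* quality as the reference covariate
level (dummy coding).  Two parameterizations are first-class:

- **saturated** — one free logit per (context, quality, non-reference
  next state) cell: 3 × 2 × 3 = 18 free parameters at first order,
  9 × 2 × 3 = 54 at second order.  Its MLE is closed-form (empirical
  cell proportions); a Newton optimizer on the exact likelihood verifies
  it.
- **additive** — current-state dummies + quality dummies + constant per
  non-reference outcome (10 parameters at first order), the layout of a
  standard multinomial regression table.

Around the model sit: Markov order selection by AIC/BIC
(`select_order`), empirical transition matrices with optional Laplace
smoothing, Wald inference tables, data-driven participant grouping by
emotional stability (SVD projection of a five-dimension scale +
K-means, K = 2), group-difference statistics (Welch t, Cohen's d,
Mann–Whitney, chi-square screen), and a synthetic-data generator that
emulates the study design end to end.

## Worked example

Run the whole pipeline on a synthetic 46-participant study (23 per
stability group, ~19 transitions each):

```sh
printf 'out_dir: out\nseed: 5\n' > run.yaml
affectmc run --config run.yaml
```

which prints (abridged):

```
wrote 46 sequences (902 transitions) and 46 scale responses
clustered 46 participants (PC1: 65.7%, PC2: 12.6%, PC3: 9.6%)
# pooled: n=902 k=18 logL=-725.74 AIC=1487.48 BIC=1573.96
 order   n  k    logL     AIC     BIC  deltaBIC  preferred
     1 902 18 -725.74 1487.48 1573.96      0.00       True
     2 856 54 -643.33 1394.67 1651.29     77.33      False
preferred order: 1 (BIC, ties toward lower order)
Quality x next-state chi-square: statistic=323.92 df=4 p=7.47e-69
Mann-Whitney on total scores: U=26.0 p=1.76e-07
```

Reading this output: the first principal component of the stability
scale carries 65.7% of the variance and separates the two trait groups;
the first-order CDMC uses 18 free parameters on 902 transitions; BIC
prefers the first-order model over the second-order extension by 77
points (the 36 extra parameters do not pay for themselves); and response
quality is strongly associated with the next emotional state.  The run
directory also contains `model.json` (the fitted coefficients with their
Wald table printed to the terminal), per-group transition matrices
(`matrices.csv`), a flow table for Sankey-style rendering (`flows.csv`),
the per-dimension group comparison (`stats_dimensions.csv`), and a
`manifest.json` with checksums — rerunning the same config and seed
reproduces them byte for byte.

Each stage is also a subcommand (`simulate`, `cluster`, `fit`,
`select-order`, `matrices`, `stats`) and a plain library call:

```python
from affectmc import GeneratorConfig, simulate_sequences, extract_transitions, fit_cdmc

seqs = simulate_sequences(GeneratorConfig(seed=5))
fit = fit_cdmc(extract_transitions(seqs, order=1))
print(fit.k, round(fit.logL, 2), round(fit.bic, 2))   # 18 -725.74 1573.96
```

## Layout

- `src/affectmc/core_io.py` — domain types, CSV log I/O, transition
  extraction, JSON model artifacts
- `src/affectmc/cdmc.py` — the CDMC likelihood, fitting, matrices,
  information criteria, order selection, Wald tables
- `src/affectmc/grouping.py` — SVD + K-means stability grouping
- `src/affectmc/inference.py` — chi-square, effect sizes, rank tests
- `src/affectmc/synthetic_data.py` — the study-shaped generator
- `src/affectmc/cli.py` — the `affectmc` command
- `docs/methods.md` — modeling assumptions, defaults, and limitations
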