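# parityrrm

Bayesian threshold random-regression animal models for litter size across
parities in sheep.

Litter size is a categorical count trait recorded repeatedly over a ewe's
reproductive life. Treating every parity as the same trait (the classical
repeatability model) assumes unit genetic correlations across parities and
constant variances — assumptions that fail when different genes act at
different parities. `parityrrm` fits the model that relaxes them: a
**threshold (liability) animal model with random regressions on Legendre
polynomials of parity**, estimated by Gibbs sampling, for pedigreed flocks
such as the prolific and conventional lines of the Tunisian Barbarine breed.

## The model

For ewe *l* lambing in year *i* and month *j* at parity *t* (t = 1..6,
later parities collapsed into 6), the latent liability is

    y_ijlt = YL_i + ML_j + Σ_k β_k φ_k(x_t) + Σ_k α_lk φ_k(x_t)
             + Σ_k μ_lk φ_k(x_t) + e_ijlt ,      k = 0..2

where x_t maps parity linearly onto [−1, 1], φ_k are normalized Legendre
polynomials (φ_k = √((2k+1)/2)·P_k), β are fixed regression coefficients,
α_l ~ N(0, A ⊗ G) are additive-genetic and μ_l ~ N(0, I ⊗ P)
permanent-environment regression coefficients, and e has heterogeneous
variance across parity classes. A is the numerator relationship matrix
(its sparse inverse is built from the pedigree with Henderson's rules and
Meuwissen–Luo inbreeding). The observed category (1 / 2 / >2 lambs for a
prolific line; 1 / >1 for a conventional line) is the interval of the
liability between thresholds.

Per-parity genetic parameters follow from the covariance-function
expressions σ²(t) = φ(t)ᵀ M φ(t) and cov(t,s) = φ(t)ᵀ M φ(s):
heritability h²(t), permanent-environment fraction c²(t), and the 6×6
genetic (r_g) and phenotypic (r_p) correlation matrices, each summarized
per posterior draw with means, 95% HPD intervals, exceedance
probabilities P(h² > 0.10) and lower 95% credible limits.

## Worked example

```python
import parityrrm as prm

scenario = prm.line_scenario("prolific", n_ewes=300, seed=11)
data = prm.simulate_dataset(scenario)          # pedigree + records + truth
model = prm.ThresholdRRM(data.records, data.pedigree.to_dataframe(),
                         line="prolific", order=2)
result = model.fit(n_iter=20_000, burn_in=5_000, thin=10, seed=1)
print(result.summary().round(2).to_string(index=False))
```

prints (849 records from 300 ewes, 384 animals in the pedigree):

```
            model  parity  sigma2_a  sigma2_p  sigma2_e   h2  hpd_low  hpd_high    P    k   c2
random_regression       1      0.30      0.43      0.64 0.21     0.03      0.45 0.81 0.06 0.32
random_regression       2      0.11      0.09      0.78 0.11     0.01      0.24 0.50 0.02 0.09
random_regression       3      0.08      0.07      0.78 0.09     0.01      0.22 0.32 0.01 0.08
random_regression       4      0.09      0.09      0.78 0.09     0.01      0.26 0.30 0.01 0.10
random_regression       5      0.14      0.11      0.81 0.12     0.01      0.38 0.43 0.02 0.12
random_regression       6      0.38      0.35      0.81 0.23     0.03      0.52 0.82 0.06 0.22
```

Column by column: posterior-mean liability-scale variance components
(additive genetic, permanent environment, residual per parity class), the
posterior-mean heritability with its 95% HPD interval, the probability the
heritability exceeds 0.10, the lower limit k with P(h² ≥ k) = 0.95, and
the permanent-environment fraction. The U-shaped h² trajectory (higher at
first and last parities) reflects the generating parameters of this
simulated flock (true h²(t) = 0.11, 0.06, 0.05, 0.07, 0.09, 0.15 — inside
every HPD above). `result.correlation_table()` prints the genetic (above
diagonal) and phenotypic (below diagonal) correlations between parities,
and `result.dic()` / `result.aic_analogue()` support polynomial-order
comparison.

The same pipeline is scriptable from a shell:

```bash
parityrrm simulate --line conventional --seed 3 --out sim/
parityrrm fit sim/pedigree.csv sim/records.csv --line conventional \
    --n-iter 500000 --burn-in 100000 --thin 100 --out run/
parityrrm compare-orders sim/pedigree.csv sim/records.csv \
    --line conventional --orders 1,2,3 --n-iter 50000 --burn-in 10000
```

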