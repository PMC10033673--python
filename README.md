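# ratiocv

Robust measures of relative variation for **ratio-type traits** — traits
defined as the quotient of two organ measurements, such as specific leaf
area (SLA = leaf area / leaf dry mass) or specific root length. For such
traits the reciprocal (e.g. LMA = 1/SLA) is an equally meaningful trait,
and a sensible measure of within-species relative variation should give
(nearly) the same answer for both orientations. The classical
coefficient of variation does not: a single extreme record can move
CV(SLA) and CV(LMA) far apart and reshuffle species rankings built on
them.

`ratiocv` is aimed at ecologists and biostatisticians comparing
intraspecific trait variation (ITV) across species, sites or traits. It
implements four measures for a positive sample x₁,…,xₙ:

| measure | formula | reciprocal-invariant | outlier-robust |
|---|---|---|---|
| ĈV | s / m (sample SD over mean) | no | no |
| ĈV_L | √(exp(θ̂²) − 1), θ̂² = Σ(zᵢ − z̄)²/(n−1), zᵢ = ln xᵢ | exactly | no |
| GCV | exp(θ̂) − 1 (Kirkwood's geometric CV) | exactly | no |
| CV_Q | (Q₃ − Q₁) / (Q₃ + Q₁) | in-sample up to quantile interpolation; exactly when n ≡ 1 (mod 4) | yes |

Supporting theory included: closed-form log-normal moments
(μ = exp(ν + θ²/2), σ = μ·√(exp(θ²) − 1), CV = √(exp(θ²) − 1),
independent of ν), and second-order Taylor approximations to the mean
and SD of a ratio x/y of two random variables, which show that the
approximate CVs of x/y and y/x agree only when the two organs have equal
CVs (for independent organs the discrepancy factor is
(1 + CV_x²)/(1 + CV_y²)).

The package also ships the group-wise analysis pipeline (load a
long-format CSV, filter species by minimum sample size, compute all
measures for the trait and its reciprocal, rank species, exclude Tukey
outliers, correlate with/without exclusion) and a seeded synthetic-data
generator with per-species log-normal ground truth and multiplicative
outlier contamination.

## Worked example

Simulate a small contaminated survey (5 species, 30 records each, 5% of
records multiplied by 10) and compare each measure between the trait and
its reciprocal:

```sh
ratiocv simulate --n-groups 5 --n-per-group 30 --rate 0.05 --seed 7 --out-dir sim
# -> wrote 150 records in 5 groups (8 contaminated) to sim
ratiocv compare-inverse --input sim/dataset.csv --group-col group \
    --value-col value --min-n 10 --outliers tukey --out-dir cmp
# -> compared 5 groups; reports in cmp
```

`cmp/report.json` then contains, per measure, the largest absolute
trait-vs-reciprocal difference and rank agreement across species:

```json
"cv_hat":   {"max_abs_diff": 0.8738924726700595, "n_same_rank": 5, ...},
"cv_l_hat": {"max_abs_diff": 0.0,                "n_same_rank": 5, ...},
"gcv":      {"max_abs_diff": 0.0,                "n_same_rank": 5, ...},
"cv_q":     {"max_abs_diff": 0.020180650059476,  "n_same_rank": 5, ...}
```

Reading: swapping numerator and denominator moves the plain CV of one
contaminated species by 0.87 — the same order as the measure itself —
while ĈV_L and GCV are bit-for-bit identical in both orientations and
CV_Q moves by at most 0.02 (a finite-sample quantile-interpolation
effect; it vanishes for n ≡ 1 mod 4). With outlier exclusion enabled the
command also writes `with_vs_without.csv`, the per-measure correlation
between species values computed with and without exclusion.

The same workflow is available as library functions
(`ratiocv.load_trait_table`, `group_measures`, `compare_with_inverse`,
`correlation_table`, …) for use on real trait tables.

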