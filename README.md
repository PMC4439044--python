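# otoscape

Phenotype-resolved outmigrant abundance and outmigrant-to-spawner survival
for juvenile salmon, by pairing rotary-screw-trap (RST) sampling with
otolith ⁸⁷Sr/⁸⁶Sr life-history reconstructions in returning adults.

Juvenile Chinook salmon leave their natal river as **fry** (fork length
FL ≤ 55 mm), **parr** (55 < FL ≤ 75 mm) or **smolt** (FL > 75 mm). A screw
trap samples a small, flow-dependent fraction of the migrants, and adult
otoliths record both where a fish was born (the strontium-isotope ratio of
its natal water) and how large it was when it left (the otolith radius at
the natal-exit point). Combining the two data streams yields, per
migratory phenotype *i* and outmigration cohort:

* **J_i** — outmigrant abundance: daily catches are apportioned to
  phenotype from the measured-fish subsample, missing trap days filled
  with a triangular weighted mean, and counts expanded through a logistic
  trap-efficiency model (binomial GLM in log-flow and phenotype with
  quasibinomial dispersion φ = Pearson χ²/df). Uncertainty is propagated
  with Monte-Carlo draws (n = 2000) of the coefficient vector and
  beta-binomial re-simulation of the daily catch; the CI is the 2.5/97.5
  percentile of the seasonal totals.
* **β_i** — the share of the spawning escapement that outmigrated as
  phenotype *i*: adults are assigned to natal source by a 1-D linear
  discriminant trained on a known-origin ⁸⁷Sr/⁸⁶Sr isoscape (equal
  priors); strays are removed; the natal-exit radius (last natal spot,
  found where the focal-site posterior drops by > 0.3 to below 0.5) is
  converted to exit FL through an OLS calibration FL = a·OR + b, and the
  calibration residuals are resampled (n = 5000) for CIs.
* **S_i** — survival: with natural escapement E_n (total escapement minus
  adclipped and unmarked strays, split by return-age distribution),
  E_i = E_n·β_i and S_i = E_i/J_i, with the log-scale delta-method CI

      SE(log S_i)² ≅ (SE(J_i)/J_i)² + (SE(β_i)/β_i)²,
      CI = exp(log S_i ± 1.96·SE(log S_i)).

A first-class synthetic-data module generates every input table with known
ground truth (flow-pulse-driven passage, beta-binomial trap, three-plateau
isotope profiles, linear OR–FL calibration, escapement bookkeeping), so the
whole chain is testable end to end.

## Worked example

Survival arithmetic for one cohort-phenotype (parr, from a seasonal
outmigrant estimate of 212,042 and 3,781 reconstructed parr spawners):

```python
>>> from otoscape.survival import survival
>>> est = survival(E_i=3781, J_i=212042, se_J=0.205 * 212042,
...                se_beta=0.059, beta=0.64, phenotype="parr")
>>> print(f"{est.percent:.2f}% ({100 * est.lo95:.2f}-{100 * est.hi95:.2f}%)")
1.78% (1.15-2.77%)
```

The point estimate is E/J = 1.78% of parr outmigrants surviving to spawn;
the CI combines the trap-expansion and proportion uncertainties on the log
scale.

A complete synthetic run from the command line:

```bash
otoscape simulate --out-dir world --seed 5
otoscape run-all --config config.yaml   # paths to the world's tables
```

which prints, for one seeded world whose true survivals are
0.07%/1.78%/0.77%:

```
   fry: S = 0.08% (0.03-0.17%)
  parr: S = 1.79% (1.35-2.37%)
 smolt: S = 0.86% (0.47-1.59%)
```

Each line is the estimated outmigrant-to-spawner survival of that
phenotype with its 95% CI; all three intervals cover the generating truth.

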