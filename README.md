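# sccbounds

Sharp bounds on **sufficient-cause (mechanistic) interactions** between two
categorical exposures, computed from ordinary cohort or case-control
contingency tables.

## The problem

In Rothman's sufficient-component-cause model, disease occurs when all
components of some "causal pie" are completed. Two exposures *interact
mechanistically* when they co-participate in one pie. With exposures
`X1 ∈ {1..L1}` and `X2 ∈ {1..L2}` there are `(L1+1)(L2+1)` causal-pie
classes (a `*` label meaning a factor is not involved), but the data offer
only `L1·L2` profile risks — the model is non-identifiable, so the
completion risk of an interaction class can be *tested* but never
*estimated*. Under the **no-redundancy assumption** (at most one class of
sufficient causes can be completed in any infinitesimally short interval),
it can however be sharply *bounded* by observable quantities.

`sccbounds` implements those bounds for epidemiologists and biostatisticians:

* **specific class (i, j)** — with `R_ij = Pr(D=1 | X1=i, X2=j)`:

  ```
  LB_ij = 1 − min over i'≠i, j'≠j of min{ (1−R_ij) / ((1−R_i'j)(1−R_ij')), 1 }
  UB_ij = R_ij
  ```

  and relative prevalence (completion risk ÷ profile risk) bounded below by
  `LB_ij / R_ij`, above by 1;

* **global (any interaction class)** — minimising a signed product of
  survival probabilities over all balanced contrast-coefficient vectors
  `(u_1..u_L1)`, `(v_1..v_L2)` with entries in `{−1, 0, +1}`:

  ```
  LB = 1 − min over (u, v) of min{ ∏_ij (1−R_ij)^(u_i·v_j), 1 }
  UB = 1 − ∏_ij (1−R_ij)
  ```

  For 2×2 designs `LB = 1 − min(PRISM, 1/PRISM)` with PRISM the
  cross-ratio of survival probabilities;

* **case-control data (rare disease)** — the relative-prevalence lower
  bounds linearise into odds-ratio expressions, e.g. the global bound
  `max(u,v) max{Σ u_i v_j OR_ij, 0} / Σ OR_ij`, reducing for 2×2 designs to
  `|RERI| / (OR_22 + OR_21 + OR_12 + 1)`;

* **percentile-bootstrap confidence limits** (one-sided 95% by default):
  a lower limit for every lower bound, an upper limit for every upper bound;

* a **causal-pie simulator** that generates cohorts from a fully specified
  model so the bounds can be checked against known truth.

The specific lower bound provably dominates the assumption-free bound
`max{R_ij − R_i'j − R_ij', 0}` of Sjölander et al., which is also provided
for comparison.

## Worked example

The package bundles a 2×2 hypertension cohort (BMI × age, 4,897 subjects).
`python examples/cohort_bounds.py` prints:

```
Profile        Cases  Total    Risk  95% LCL      LB      UB  95% UCL  RP 95% LCL   RP LB
-------------  -----  -----  ------  -------  ------  ------  -------  ----------  ------
(low, young)      79   1810  0.0436   0.0000  0.0000  0.0436   0.0519      0.0000  0.0000
(low, old)       100    681  0.1468   0.0000  0.0000  0.1468   0.1689      0.0000  0.0000
(high, young)    153   1385  0.1105   0.0000  0.0000  0.1105   0.1242      0.0000  0.0000
(high, old)      278   1021  0.2723   0.0000  0.0411  0.2723   0.2948      0.0000  0.1509
Global           610   4897  0.1246   0.0408  0.0830  0.4718   0.4946      0.0871  0.1758
```

Reading the Global row: between 8.3% and 47.2% of this population would
complete a causal pie requiring both high BMI and older age; the lower
bound remains positive at its 95% lower confidence limit, so *some*
mechanistic BMI–age interaction is supported. The (high, old)-specific
class has completion risk between 0.0411 and 0.2723 (relative prevalence at
least 0.1509), but its confidence limit reaches 0, so that specific class
alone is not statistically established.

The same workflow from a shell:

```
sccbounds cohort src/sccbounds/datasets/hypertension_cohort.csv --seed 1
sccbounds casecontrol src/sccbounds/datasets/lung_cancer_casecontrol.csv --seed 1
```

`examples/casecontrol_bounds.py` runs the bundled 3×3 lung-cancer
case-control study (ADPRT × XRCC1 genotypes): the (Ala/Ala, Gln/Gln)
relative-prevalence lower bound is 0.5221 and the global bound 0.2471 with
a positive 95% lower confidence limit — evidence of a gene–gene
sufficient-cause interaction. `examples/simulate_and_validate.py` shows the
bounds trapping the true completion risks of a known causal-pie model.

Input is a CSV with columns `x1, x2, cases, total` (cohort) or
`x1, x2, cases, controls` (case-control), one row per exposure profile; the
first level seen on each axis is the odds-ratio reference.

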