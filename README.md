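# bnpcea

Cost-effectiveness analysis of B-type natriuretic peptide (BNP) guided care
versus standard clinical assessment for outpatients with heart failure with
reduced ejection fraction (HFrEF), from a societal perspective.

The package is for health economists and modellers who want a tested,
fully-scripted re-implementation of this analysis: a five-state monthly
Markov cohort model (states by prior rehospitalization count: NRH, RH1,
RH2, RH3, dead) with lifetime horizon, incremental cost-effectiveness
analytics, deterministic and probabilistic sensitivity analysis, and a
synthetic patient-level module standing in for the study's 400-patient
dataset (EQ-5D-3L utilities, bottom-up itemized costs, bootstrap CIs).

## The model in brief

Each month a patient in alive state *s* at age *a* dies with probability

```
p_death(s, a) = 1 − (1 − p_hf(s)) (1 − p_bg(a)),   p_bg monthly from an
                                                   age-banded life table
```

is rehospitalized (moves one state up) with probability `RR · p_hosp(s)`
(RR = 0.81 under BNP guidance, 1 otherwise — the treatment effect acts on
hospitalization only), or stays. Per-patient discounted totals

```
C = Σ_t d_c(t) Σ_s π_t(s) c(s),   E = Σ_t d_e(t) Σ_s π_t(s) u(s)/12
```

(costs at 5.8 %/yr, QALYs at 3 %/yr) feed ΔC = C_BNP − C_std,
ΔE = E_BNP − E_std, the ICER ΔC/ΔE with dominance classification, and the
net monetary benefit λΔE − ΔC at λ = 20 800 USD/QALY. Parameter
uncertainty is propagated by Monte Carlo with method-of-moments Beta /
Gamma / log-normal fits. See `docs/methods.md` for assumptions, semantics
flags, and known reproducibility caveats.

## Worked example

```python
from bnpcea import default_bundle
from bnpcea.cea import run_base_case

res = run_base_case(default_bundle())
print(f"BNP      {res.bnp.cost:7.0f} USD  {res.bnp.qaly:.3f} QALYs")
print(f"standard {res.standard.cost:7.0f} USD  {res.standard.qaly:.3f} QALYs")
print(f"{res.classification}: dC {res.delta_cost:+.0f} USD, dE {res.delta_qaly:+.3f} QALYs")
```

prints

```
BNP         6201 USD  0.840 QALYs
standard    7791 USD  0.820 QALYs
dominant: dC -1590 USD, dE +0.020 QALYs
```

BNP-guided care costs less and yields more QALYs than standard assessment
— it *dominates*, so no ICER is reported; the saving comes from slower
progression into the expensive, low-utility rehospitalization states at
the price of the monthly BNP test.

The same model is available from the shell:

```sh
bnpcea base-case --out-dir out
bnpcea psa --seed 2021 --out-dir out        # CE plane + acceptability curve
bnpcea tornado --out-dir out                # one-way sensitivity, 20 inputs
bnpcea synth --seed 0 --out-dir out         # synthetic patient-level cohort
```

Every command writes CSV/JSON tables plus a `manifest.json` (resolved
parameter bundle, seeds, flags) that reproduces the run exactly. The
numbered scripts under `analysis/` drive the full study sequence —
`01_base_case.py`, `02_subgroups_scenarios.py`, `03_sensitivity.py`,
`04_synthetic_cohort.py` — writing their tables to `results/`.

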