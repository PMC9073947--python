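# fetalkpuu

Maternal–fetal PBPK estimation of **K<sub>p,uu,fetal</sub>** — the
fetal-to-maternal unbound steady-state plasma concentration ratio — for
drugs that are substrates of the placental efflux transporters P-gp and
BCRP.

## The problem

Fetal drug exposure can only be measured at delivery, when umbilical-vein
(UV) and maternal plasma (MP) can be sampled simultaneously. Because each
delivery yields a single time point, exposure must be reconstructed by
pooling UV/MP concentration pairs from many maternal–fetal dyads sampled at
different times after the last maternal dose. For a drug crossing the
placenta purely passively (and with negligible placental/fetal metabolism),
K<sub>p,uu,fetal</sub> = 1; apical efflux transport back into maternal blood
pushes it below 1, and the deficit f<sub>efflux</sub> = 1 −
K<sub>p,uu,fetal</sub> is the fraction of drug kept out of the fetal
compartment.

This package implements that estimation workflow for three case-study
drugs — nelfinavir (P-gp substrate), efavirenz (BCRP substrate) and
imatinib (dual substrate) — as open, testable code:

* a reduced maternal disposition model (one compartment, first-order
  absorption, pathway-resolved clearance) with pregnancy applied through
  hepatic CYP activity multipliers and a pregnancy volume of distribution,
  validated with the standard 0.80–1.25-fold rule against observed PK;
* a permeability-limited placenta–fetal extension: bidirectional passive
  diffusion clearance calibrated against midazolam
  (CL<sub>PD,x</sub> = 500 l/h × P<sub>app,x</sub>/489.9 nm/s), plus an
  apical efflux clearance acting placenta → maternal blood only;
* the estimator: the single free parameter CL<sub>int,efflux,placenta</sub>
  is adjusted until predicted UV/MP ratios match the pooled observations in
  the fold-error sense. At steady state the closed form is

  K<sub>p,uu,fetal</sub> = CL<sub>int,PD</sub> / (CL<sub>int,PD</sub> + CL<sub>int,efflux</sub>),

  independent of placental volume, fetal volume and plasma binding;
* gestational-age extrapolation: the term efflux clearance is scaled by the
  relative placental abundance R(GW) of the transporter, giving
  K(GW) = CL<sub>PD</sub> / (CL<sub>PD</sub> + R(GW)·CL<sub>efflux,term</sub>);
* a synthetic-data module (virtual trials with lognormal between-subject
  variability; pooled dyads with heavy multiplicative scatter) so the whole
  pipeline is testable without any clinical data download.

Fit quality is reported with the average fold error (AFE, signed — the fit
criterion) and the absolute average fold error
(AAFE = 10^(mean |log10 pred/obs|) ≥ 1 — the scatter diagnostic).

## Worked example

```python
import fetalkpuu as fk

drug, placenta = fk.fixture_parameters("nelfinavir")
regimen = fk.default_regimen("nelfinavir")   # 1250 mg twice daily, fed

# pooled synthetic delivery dyads (n = 40, heavy lognormal scatter)
dyads = fk.generate_dyads(drug, regimen, true_kpuu=0.41, n=40,
                          sigma_log10=0.3, seed=12)

model = fk.PlacentalTransferModel(dyads, drug, regimen,
                                  placenta=placenta.with_efflux(0.0))
results = model.fit(bootstrap=1000, seed=12)
print(results.summary())
for gw in (15, 25, 38):
    print(f"Kp,uu,fetal at GW{gw}: {results.predict_at_gw(gw):.2f}")
```

prints

```
Placental transfer estimate
============================================================
drug:                      nelfinavir
gestational week:          38.0
n dyads:                   40
objective:                 AFE = 1
CL_int,PD,placenta:            240.00 ul/min/ml
CL_int,efflux,placenta:        333.99 ul/min/ml
AAFE at optimum:                1.680
AFE at optimum:                 1.000
AUC_fetal,u/AUC_m,u:            0.418
AUC_fetal/AUC_m (total):        0.418
Kp,uu,fetal:                     0.42
f_efflux = 1 - Kp,uu:            0.58
95% CI Kp,uu (bootstrap):  [0.340, 0.507]  (1000 resamples)

Kp,uu,fetal at GW15: 0.24
Kp,uu,fetal at GW25: 0.35
Kp,uu,fetal at GW38: 0.42
```

The fitted efflux clearance (334 µl/min/ml here) recovers the generating
K<sub>p,uu,fetal</sub> of 0.41 within the sampling noise: AFE = 1.000 says
the predictions are centred on the observations, while AAFE = 1.68 measures
the residual scatter of the pooled dyads. The extrapolation rows show fetal
exposure falling at earlier gestational ages, when relative transporter
abundance per term-normalised unit is higher.

The same steps are available from the shell:

```bash
fetalkpuu generate  --config scenario.yaml --kind dyads --out out/
fetalkpuu estimate  --config scenario.yaml --dyads out/dyads.csv --out out/
fetalkpuu extrapolate --config scenario.yaml --term-estimate out/estimate.json \
                      --gw 15 --gw 25 --gw 38 --out out/
```

where `scenario.yaml` is as small as `{drug: nelfinavir, seed: 12}`.

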