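# dmintake

Dry-matter-intake (DMI) prediction for lactating dairy cows: the KFSD
equation (the empirical intake model of the Korean feeding standards for
dairy cattle), the published comparator equations, and the full machinery
around them — literature-database curation, two-phase model development,
precision/accuracy/bias evaluation and Latin-hypercube sensitivity analysis —
with synthetic-data generators so every experiment is reproducible without
any external dataset.

The package is for ration-formulation and animal-nutrition modelling work:
predicting how much feed dry matter a cow will eat is the first step of diet
formulation, and the difference between a biased and an unbiased intake
equation is the difference between under- and over-feeding a herd.

## The model

The central equation predicts DMI (kg/d) from metabolic body weight
(MBW = BW^0.75, kg^0.75), 4% fat-corrected milk (FCM, kg/d) and the dietary
neutral detergent fibre content (NDF, % of DM):

    DMI = 4.103 + 0.112·MBW + 0.284·FCM − 0.119·NDF

optionally multiplied by the early-lactation lag
`Lag[2] = 1 − exp(−0.316·(WOL + 2.36))` (WOL = week of lactation).
Comparators on the same inputs: NRC 2001 `(0.372·FCM + 0.0968·MBW)·Lag[3]`,
CNCPS `(0.0185·BW + 0.305·FCM)·Lag[2]`, and the parity-specific Japanese
feeding standard (JFS).  Evaluation follows the standard residual analysis:
R² of observed on predicted, RMSPE, and mean/slope bias from regressing
residuals on mean-centred predictions.  See `docs/methods.md` for the full
account.

## Worked example

```python
from dmintake import CowState, DietComposition, predict_kfsd, predict_nrc

cow = CowState(bw=640, my=33.0, fat_pct=3.8, wol=20, parity="multiparous")
diet = DietComposition(ndf_pct=33.4, cp_pct=16.9, fpdm_pct=53.0)
print(f"KFSD {predict_kfsd(cow, diet):.2f}  NRC {predict_nrc(cow):.2f} kg/d")
```

prints `KFSD 23.47  NRC 23.97 kg/d` — a 640-kg cow producing 33 kg/d of
3.8%-fat milk (FCM 32.0 kg/d) on a 33.4%-NDF ration is predicted to eat
about 23.5 kg of feed dry matter per day; the half-kilogram spread between
equations is typical of empirical intake models.

The `examples/` directory holds one short script per capability
(prediction, curation, development, evaluation, sensitivity, seasonal farm
evaluation).  For instance `python examples/sensitivity_tornado.py` prints

    converged: True after 6000 samples
    tornado (standardized regression coefficients):
      fcm  +0.898  ####################################
      mbw  +0.388  ################
      ndf  -0.249  ##########

i.e. a one-SD change in fat-corrected milk moves predicted intake by ~0.9
output SDs — more than twice the influence of body size — and fibre is the
only input that pushes intake down.

A thin CLI mirrors the library for shell pipelines
(`dmintake simulate|filter|split|develop|evaluate|sensitivity|predict`),
writing a JSON manifest next to every artifact.

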