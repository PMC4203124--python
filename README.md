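# headcast

Prediction of heading date in bread wheat (*Triticum aestivum* L.) from
weather, sowing date and — for genotypes never grown in a trial — from
their genetic markers alone.

Heading date is the backbone of wheat adaptation: it decides whether a
cultivar escapes late frost, summer drought and heat, and it anchors crop
management (e.g. the last nitrogen application). It is controlled by
three earliness components — vernalization requirement, photoperiod
sensitivity and earliness *per se* — whose major genes (*Vrn-1*, *Ppd-1*)
are known and assayable. `headcast` links the two worlds: an
ecophysiological model whose genotype-specific parameters represent those
components, and additive marker models that predict the parameters from
allele calls, so that the phenology of an untested genotype can be
simulated in any environment with a weather record.

The package is for quantitative geneticists and crop modellers; it
provides the simulator, the brute-force calibrator, the sensitivity
analysis, the marker pipeline (imputation, structure-corrected
association with permutation p-values, LD blocking, backward-elimination
models), a seeded synthetic-data generator for testing, and a CLI.

## The model

Daily development is thermal time modified by vernalization and
photoperiod factors. With `TM` the daily mean temperature and `Ph` the
day length (sun above 6° below the horizon):

    FT  : bilinear in TM over (T_base, T_opt, T_max) = (1, 26, 37) °C
    Tt  = FT × T_opt                          daily thermal time, °C·d
    Veff: trapezoid in TM over (−4, 3, 10, 17) °C;  VDD = Σ Veff
    FV  = clip((VDD − V_base)/(V_sat − V_base), 0, 1)
    FP  = clip((Ph − P_base)/(P_opt − P_base), 0, 1),   P_opt = 20 h
    PVTt = Tt × FV × FP                       modified thermal time

Sowing → emergence takes 148 °C·d of plain `Tt`; emergence → heading
takes `TT_emhe` modified °C·d (default 500). `V_sat` (days), `P_base`
(hours) and optionally `TT_emhe` are genotype-specific ("genetic")
parameters.

Calibration is an exhaustive grid search (101 × 131 = 13 231 vectors for
the `V_sat` × `P_base` strategy, 101 × 131 × 41 = 542 471 with `TT_emhe`
free) minimizing the RMSEP between observed and predicted heading dates
across experiments; winter genotypes (those that never head after spring
sowing) are calibrated on autumn sowings and their tied vectors filtered
with the spring no-heading information. Marker models are multiple
regressions of calibrated parameters on allele classes, built by
association scanning with population-structure covariates, collinearity
(LD) blocking, and backward elimination. See `docs/methods.md` for the
full account.

## Worked example

Predict `V_sat` from markers with the bundled reference model, then
calibrate a small synthetic panel:

```python
from headcast import SynthConfig, gen_dataset, HeadingModel
from headcast.markers import load_bundled_model, predict_parameter

mv = load_bundled_model("v_sat")
calls = {t["marker"]: t["reference"] for t in mv.terms}
calls["Vrn.A1ex7"] = "22"            # spring allele at Vrn-A1
calls["vern.5B.Sins.8761"] = "ins"   # insertion at Vrn-B1
print(predict_parameter(mv, calls))

data = gen_dataset(SynthConfig(seed=0, n_genotypes=6, n_markers=20))
fit = HeadingModel(data["observations"], data["experiments"],
                   data["sites"], data["weather"]).fit()
print(fit.summary())
```

prints `38.9` — the all-reference intercept of 53.9 days shifted by
−28.3 d (spring allele at *Vrn-A1*) and +13.3 d (*Vrn-B1* insertion): a
facultative rather than obligate-winter vernalization requirement — and
then

```
Grid calibration of genotype parameters
  genotypes calibrated : 6
  grid strategy        : 2p (13231 vectors)
  experiments          : 5
  median min RMSEP     : 0.76 d
  winter-filtered      : 1

             v_sat  p_base  tt_emhe  min_rmsep  n_vectors  n_experiments  filtered
genotype_id
G000          15.0     0.3    500.0   1.414214         13              5     False
G001         104.0     1.3    500.0   0.000000          1              3      True
...
```

Each row is one genotype's selected parameter vector: `min_rmsep` is its
prediction error in days across the experiments used, `n_vectors` the
size of the RMSEP-minimizing tie set (a width, i.e. how identifiable the
parameters are), and `filtered` marks winter genotypes whose vectors were
screened against the spring no-heading records. G001 is a winter type:
high `V_sat`, calibrated on the 3 autumn sowings only.

The same stages are available from the shell, driven by one YAML config:

```
headcast synth --outdir fixtures/
headcast optimize --config config.yaml --out calib.csv
headcast sensitivity --config config.yaml --out src.csv
headcast associate --config config.yaml --params calib.csv --out assoc.csv
headcast fit-markers --config config.yaml --params calib.csv --outdir models/
headcast predict --config config.yaml --out predictions.csv
headcast evaluate --config config.yaml --predictions predictions.csv --out report.csv
```

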