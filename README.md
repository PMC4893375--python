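# mcti — Monte-Carlo-trained inversion of multispectral tissue images

`mcti` estimates tissue **oxygenation** `s` (fraction of oxygen-bound
hemoglobin) and **blood volume fraction** `v_hb` from multispectral
reflectance, per pixel and fast enough for intra-operative use. It is aimed
at researchers in biophotonics and surgical imaging who need a complete,
testable in-silico pipeline: forward simulation, camera adaptation, inverse
regression, and image processing.

## How it works

1. **Forward model.** Tissue is a stack of plane-parallel layers
   `{v_hb, s, a_mie, b, g, n, d}`. Hemoglobin is the only absorber,
   `mu_a = v_hb (c_hb/M_hb)(s eps_HbO2 + (1-s) eps_Hb) ln 10`, and reduced
   scattering follows `mu_s' = a_mie (lambda/500nm)^-b`. Diffuse reflectance
   spectra are computed with a multi-layer Monte Carlo photon-packet walk
   (MCML-style: Henyey–Greenstein scattering, Fresnel boundaries, Russian
   roulette), validated against published adding-doubling slab tables.
2. **Camera adaptation.** Spectra are integrated over a band system
   (22 boxcar bands 470–680 nm in silico; an 8-band laparoscopic camera
   model for images), perturbed with signal-proportional Gaussian noise
   (`std = r_k/SNR`), and normalized `l1 -> -log -> l2`, making features
   invariant to illumination and gain changes.
3. **Inversion.** A 10-tree random forest (depth 9, min 10 samples/leaf)
   jointly predicts `(s, v_hb)` from the features; SVR and k-NN are
   comparators, and a training-free modified Beer–Lambert least-squares
   unmixing (`A_k ~ x1 eps_HbO2_k + x2 eps_Hb_k + x3`, `s = x1/(x1+x2)`) is
   the linear baseline.
4. **Imaging.** Dark-current subtraction, flatfield division, specular
   masking and block downsampling feed the trained model per pixel;
   synthetic phantoms exercise the whole path against known ground truth.

## Worked example

Simulate a labeled colon-model dataset, train a random forest, and apply it
to a synthetic phantom:

```bash
mcti simulate --model colon --n-samples 500 --photons 10000 --seed 1 \
              --out colon.csv
mcti train --data colon.csv --bands boxcar22 --snr 10 --seed 1 --out rf.bin
mcti phantom --seed 2 --snr 10 --out phantom.tif
mcti estimate --stack phantom.tif --dark phantom_dark.tif \
              --flat phantom_flat.tif --model rf.bin --bands camera8 \
              --step-nm 10 --out maps.tif
```

Or in Python, reproducing a miniature noise-robustness experiment:

```python
from mcti import experiments as exp
from mcti.tissue_model import load_parameter_ranges

config = exp.ExperimentConfig.desk_scale(seed=1, n_train=200, n_test=80)
colon = load_parameter_ranges("colon")
train = exp.generate_dataset(colon, config.n_train, config, role="train")
test = exp.generate_dataset(colon, config.n_test, config, role="test")
report = exp.noise_sweep(config, train, test, test_snrs=(10.0, float("inf")))
print(report.rows[["method", "snr_test", "target", "median_abs_error_pp"]])
```

which prints (medians in percentage points; 200 training samples is tiny,
so oxygenation errors are far above what larger training sets reach):

```
         method  snr_test target  median_abs_error_pp
0            rf      10.0      s            14.261695
1            rf      10.0   v_hb             1.425253
2  beer_lambert      10.0      s             9.777676
3            rf       inf      s             5.942240
4            rf       inf   v_hb             1.376226
5  beer_lambert       inf      s             5.517069
```

The key readings: the random forest recovers blood volume fraction to
~1.4 pp even under 10% band noise, its oxygenation error drops sharply as
noise vanishes, and the training-free Beer–Lambert baseline estimates only
oxygenation.

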