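# enosesim

A virtual gas-sensor-array data generator for machine olfaction.

Electronic-nose research lives and dies by the robustness of its signal
and data processing, yet public benchmark data for gas sensor arrays are
nearly nonexistent. `enosesim` fills that gap with a parameterized
simulator: you define a measurement scenario (which gases, at which
concentrations, how many pulses), configure a virtual array of
conducting-polymer-style sensors, and generate transient or steady-state
sensor data with controllable nonlinearity, diversity and noise — then
benchmark your classifier or regressor on data whose difficulty you set
yourself.

The core models:

* **Competitive Langmuir sorption** — the sorbed fraction of analyte *j*
  on a sensor with affinities *K* is
  `x_j = K_j c_j / (1 + Σ_k K_k c_k)`: nonlinear, saturating, and
  competitive in mixtures. The `alpha` slot scales all affinities
  (default 2.25) and thereby the nonlinearity.
* **Calibration + transients** — the steady-state signal is
  `y_ss = b0 + Σ_j b_j x_j`; transient signals relax toward it with a
  first-order step per time unit (`tau_rise`/`tau_decay` per sensor).
  The `beta` slot (default 2) draws replica coefficients from uniform
  distributions around each prototype, controlling array diversity.
* **Three noise models** — concentration noise (`csd`), sensor
  (coefficient) noise (`ssd`) and low-rank random-walk drift (`dsd`),
  each scaled so 0 is noise-free and 1 the reference level
  (defaults 0.1).

Sensors are assembled from a seeded bank of 17 prototypes with a
documented selectivity structure (types 1–3 favour n-butanol "C",
types 13/14/17 favour ammonia "A" and are noisy on that channel). See
`docs/methods.md` for the full model description and design choices.

## Worked example

Three 60-unit pulses of ammonia at increasing concentration, measured by
a four-sensor array, reduced to one steady-state row per pulse:

```python
import enosesim as es

sc = es.Scenario(train=[("A 0.01", 1), ("A 0.02", 1), ("A 0.05", 1)], tunit=60)
conc = es.build_concentration_matrix(sc)          # 360 annotated samples
sa = es.SensorArray(num=(1, 5, 9, 13), tunit=60, seed=7)
sdata = sa.predict(conc)                          # 360 x 4 signal matrix
feats = es.extract_features(conc, sdata, "ss")
print(feats.round(3).to_string(index=False))
```

```
   A   B   C    S1    S2    S3    S4    lab   set  pulse
0.01 0.0 0.0 1.145 1.630 1.880 1.685 A 0.01 train      1
0.02 0.0 0.0 1.302 2.222 2.616 2.124 A 0.02 train      2
0.05 0.0 0.0 1.654 3.358 3.646 2.655 A 0.05 train      3
```

Each row is the signal at the end of one exposition phase (time units
120, 240, 360). Responses rise with concentration but sub-linearly —
S3 gains 0.74 from 0.01→0.02 vol.% but only 1.03 over the much larger
0.02→0.05 step — the Langmuir saturation at work. The baseline (air)
level is 1.0.

Benchmarking a classifier on the easiest two-class scenario
(A 0.02 vs C 0.5), with a 17-sensor array at full reference noise:

```python
bank = es.generate_profile_bank(1)
arr = es.SensorArray(num=tuple(range(1, 18)), csd=1, ssd=1, dsd=1,
                     seed=2, bank=bank)
scn = es.difficulty_scenario(1, n_per_class=100, seed=3)
res = es.run_classification_benchmark(arr, scn, seed=4)
print(f"best k = {res.best_k}, train CV accuracy = {res.acc_train:.2f}, "
      f"test accuracy = {res.acc_test:.2f}")
```

```
best k = 3, train CV accuracy = 1.00, test accuracy = 1.00
```

The two mixtures are so dissimilar that a 3-nearest-neighbour model on
PCA scores separates them perfectly despite reference-level noise;
harder levels (2, 3) move the class mixtures closer together and the
accuracy drops accordingly.

The same workflows are available from the shell:

```sh
enosesim simulate --config run.yaml --out out/     # conc/sdata/features CSVs + manifest
enosesim bench --level 1,2,3 --seed 1 --out bench.csv
enosesim profiles --bank-seed 0 --out bank/
```

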