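# peptrack

Positron emission particle tracking (PEPT) for pre-clinical PET: locate and
follow a **single** positron-emitting particle from list-mode coincidence
data, rather than reconstructing an image from it.

When a sub-micrometre radiolabelled particle (e.g. a ~950 nm silica sphere
carrying kBq-level ⁶⁸Ga) moves through a small animal inside a cylindrical
PET scanner, every detected annihilation defines a *line of response* (LoR)
joining two crystals — and every true LoR passes close to the particle.
`peptrack` implements the **Birmingham method**: for a subset of
time-consecutive LoRs it computes the *minimum distance point* (MDP), the
point **p** minimising the summed squared perpendicular distances to the
lines,

```
[ Σᵢ (I − d̂ᵢd̂ᵢᵀ) ] p = Σᵢ (I − d̂ᵢd̂ᵢᵀ) aᵢ
```

(with `d̂ᵢ` the unit direction and `aᵢ` an endpoint of line *i*), then
iteratively discards the LoRs farthest from the current MDP — scatter,
randoms and scintillator background do not pass near the particle — until a
fraction *f* (the *f-factor*) of the subset remains. Sample size trades
temporal resolution against positional precision, so a schedule can use
small samples while the particle moves fast after injection and large ones
once it settles. From the tracked trajectory the package derives speed
(√(vₓ²+v_y²+v_z²) from forward differences), static positioning scatter,
and the respiratory-motion envelope; a radiometrics module covers decay
correction, particles-per-mass, counting-bead absolute counts, %ID/g and a
stochastic model of the four-tube fractionation protocol used to isolate a
single particle.

The package is aimed at physicists and imaging scientists prototyping
in vivo PEPT analyses: it includes a Monte-Carlo list-mode simulator (point
source with exponential decay, positron-range blur, crystal discretization,
scatter/randoms/intrinsic background) so every algorithm can be exercised
against known ground truth.

## Worked example

Track a simulated injection transit: a 1.5 kBq ⁶⁸Ga point source crossing
the bore at 48 mm/s (lower abdomen → heart → lung, ~3 s), detected at 9%
sensitivity with 10% scatter, 2% randoms and crystal discretization, then
located from 150-LoR samples with f = 0.1:

```python
>>> from peptrack import transit_speed_study
>>> res = transit_speed_study(seed=1)
>>> print(res["trajectory"].to_dataframe().round(3).to_string(index=False))
  t_s   x_mm    y_mm    z_mm  n_initial  n_final  rms_residual_mm  error_estimate_mm
0.605  0.273 -35.719 -29.142        150       15            1.333              0.344
1.587  0.281   3.282  -2.900        150       15            1.681              0.434
2.510 -1.397  37.870  24.342        116       12            1.551              0.448
>>> round(res["mean_speed_mm_s"], 2)
47.82
```

Three tracked points span the ~147 mm transit; each is the MDP of the 15
LoRs surviving the f = 0.1 trimming of one 150-LoR sample (the last sample
is a kept partial). The duration-weighted mean segment speed over the first
30 s, 47.82 mm/s, recovers the set 48 mm/s to within half a percent even
though each point individually is only ~1 mm accurate.

The same machinery is scriptable from the shell:

```bash
pept simulate  --config sim.json  --output run.csv            # + ground truth
pept track     --input run.csv --dialect crystal \
               --geometry geom.json --config track.json --output traj.csv
pept kinematics --input traj.csv --output report.json
pept radiocalc decay --elapsed-s 4062.6                        # {"decay_factor": 2.0}
```

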