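# eitptx

Synthetic electrical impedance tomography (EIT) pipeline for pneumothorax
(PTX) detection studies: a pig-thorax conductivity phantom with pleural air
lesions, a 16-electrode adjacent-drive forward model, linearized
time-difference image reconstruction, a pooled-healthy-reference detection
algorithm with segment localization, spike-potential waveform analysis, and
the agreement / diagnostic-accuracy statistics used to evaluate it.

## Layout

| module | contents |
| --- | --- |
| `eitptx.phantom` | thorax phantom, lung segment map (1–10), PTX lesions, relevance rules (trans20 / cc3 / transcc), partial-volume weighting, time-resolved conductivity series with respiratory/cardiac dynamics |
| `eitptx.forward` | finite-difference forward solver, electrode belt, 208-measurement adjacent-drive acquisition |
| `eitptx.recon` | adjoint-method Jacobian, one-step Tikhonov difference reconstruction onto a 32×32 circular mask, breath detection, tidal images, quadrant ROI waveforms, per-pixel phase maps |
| `eitptx.detect` | pooled healthy reference (pixelwise mean/SD of unit-sum tidal images), ventilation-deficit z-maps, connected-component detection, segment localization |
| `eitptx.spikes` | spike-potential detection (median detrend + k·MAD threshold + refractory merge) and cardiac-frequency matching |
| `eitptx.stats` | 2×2 tables from marginals, Cohen's kappa with null-SE p-values and interpretation bands, sensitivity/specificity/PPV/NPV, integer percentage convention |
| `eitptx.harness` | end-to-end synthetic study: reference building, case simulation, missed-lesion summary tables |
| `eitptx.io` | HDF5 recordings, JSON truth/reference/detection, CSV waveforms, PGM/PPM image export |

Conventions: images are indexed `[row, col]` with row 0 ventral, viewed from
caudal, the animal's right on the image left. Electrode 0 sits on the ventral
midline; numbering increases counterclockwise (toward image right).

## CLI

```sh
eitptx simulate --config case.cfg --out out/          # recording.h5, truth.json, waveforms.csv, tidal.csv/.pgm
eitptx detect --tidal out/tidal.csv --reference ref.json --out det.json --overlay marked.ppm
eitptx spikes --waveform out/waveforms.csv --heart-rate 90 --out spikes.json
eitptx evaluate --config study.cfg --seed 1 --out study/   # summary.csv, accuracy.csv, per_case.csv
eitptx reproduce-stats                                 # printed agreement statistics, PASS/FAIL
```

Config files are plain `key = value` text; `simulate` accepts all dynamics
fields (`frame_rate`, `duration`, `respiratory_rate`, `tidal_modulation`,
`heart_rate`, `spike_enabled`, `spike_magnitude`,
`lesion_ventilation_fraction`, `lesion_phase_lag`, `noise_sd_frac`, `seed`)
plus `lesion_segment`, `lesion_trans_frac`, `lesion_cc_cm`; `evaluate`
accepts the study fields (`n_none`, `n_cc3`, `n_trans20`, `n_transcc`,
`n_reference`, `z_threshold`, `min_area_pixels`, `frame_rate`, `duration`,
`seed`).

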