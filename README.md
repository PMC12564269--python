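# psqakit

Balanced multimodal multi-task learning for patient-specific radiotherapy
QA (PSQA), with a fully synthetic PSQA simulator and a gamma-index engine,
so that every stage is testable without clinical data.

A PSQA sample couples two modalities per beam — a planned fluence map
(image) and a 33-element plan-complexity vector (tabular) — with two
targets: Gamma Passing Rates (GPR) at the 1%/1 mm, 2%/2 mm and 2%/3 mm
criteria, and a dose-difference (DD) map.  The model encodes both
modalities, fuses them with softmax attention for GPR regression and with
channel-wise spatial concatenation for DD prediction, and balances the two
tasks dynamically: after each epoch a two-modality Shapley decomposition
of the validation GPR error quantifies each modality's contribution, and
tabular dominance inflates the DD loss weight
`lambda = 1 + max(phi_tab - phi_img, 0) * r / 2` (with `r` the modality
balance factor, default 16; `r = 0` recovers plain unbalanced training).

Everything — including the neural network and its training loop — runs on
numpy (a small built-in reverse-mode autograd engine); no GPU or deep
learning framework is required.

## Layout

| Module | Purpose |
|---|---|
| `psqakit.data_model` | Domain types, validation, HDF5 persistence, CSV index |
| `psqakit.synth` | MLC-aperture simulator: fluence maps, complexity metrics, delivery perturbations, dataset generation |
| `psqakit.gamma` | Gamma-index maps and GPR under the QA protocol, plus an exhaustive verification oracle |
| `psqakit.nn` | numpy autograd, encoders, task-specific fusion, decoders, multi-subset forward |
| `psqakit.balance` | Subset value function, Shapley decomposition (+ enumeration oracle), lambda rule, total loss |
| `psqakit.train` | Balanced per-epoch training loop (`fit`, `train_epoch`) |
| `psqakit.metrics` | MAE/RMSE/R2, global-statistics SSIM, GPR-interval-stratified reports |
| `psqakit.split` | Stratified 7:1:2 split by GPR bin x lesion site |
| `psqakit.cli` / `psqakit.config` | `psqakit` command line and YAML experiment configuration |

## CLI

```bash
# write a config (all keys optional; see psqakit.config)
cat > config.yaml <<EOF
sim: {n_samples: 200, seed: 1}
train: {epochs: 10, lr: 3e-3, seed: 1}
network:
  grid: [64, 64]
  encoder_channels: [8, 16, 24, 32]
  fused_width: 64
  decoder_channels: [24, 16, 12, 8, 6]
dataset_path: data.h5
split_path: split.csv
run_dir: run
EOF

psqakit simulate -c config.yaml                 # dataset + provenance JSON
psqakit split -d data.h5 -o split.csv --seed 1  # stratified 7:1:2 split
psqakit train -c config.yaml                    # checkpoint + history.jsonl
psqakit train -c config.yaml -o sweep --sweep-r 0,8,16,24
psqakit report -r run -d data.h5 -s split.csv   # JSON + Markdown metrics
psqakit gamma -d data.h5 --sample s00000 --criterion 2/2
```

Any config key can be overridden on the command line, e.g.
`--set train.r=0`.  `history.jsonl` records per-epoch losses, subset
values `v(S)`, the Shapley contributions `phi_img`/`phi_tab` and the
lambda trajectory (the contribution-curve data); `report` also exports
them as `contributions.csv`.

## Notes

- The delivery-perturbation family in the simulator (gain, blur, shift,
  noise, localized error blobs) is a synthetic stand-in for portal
  dosimetry physics, calibrated so the GPR distribution populates the
  <85 / 85–90 / 90–95 / >95 bins and so that modality informativeness is
  controllable (`rho_tab`, `rho_img`).
- Gamma analysis is discrete (no sub-pixel interpolation), global
  absolute-dose mode, 10% global-max threshold, pass rule `gamma <= 1`
  (with a 1e-9 numeric slack); the measured grid hosts the evaluation
  points by default.
- `NetworkConfig.full_scale()` gives the clinical-resolution preset
  (512x512, Linear(512, 3) GPR head, decoder channels
  [768, 384, 192, 128, 32]); tests and examples use desk-scale variants
  that train in minutes on one CPU.
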