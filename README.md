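# homeodbm

Layered (deep) Boltzmann machines with homeostatic regulation of unit
excitability, built to study how a generative network's internal imagery
changes when its sensory input is degraded.

A stack of binary unit layers is trained pair-by-pair with contrastive
divergence on a synthetic corpus of simple shapes (squares and triangles in
two sizes, at every image position). After training, each hidden unit records
its average activity during inference over the training data as a set-point.
When the input is then blanked, corrupted, fixed, half-blanked, or an early
hidden layer is clamped, a per-unit homeostatic rule nudges each bias toward
its set-point between blocks of inference trials. The package measures what
the adapting network "sees" by decoding hidden states through a deterministic
doubled-weight top-down pass and scoring the decoded images against the
training templates (normalized cross-correlation) or a label-augmented
classifier. A balance factor on intermediate layers trades feedforward
against feedback drive, modelling cholinergic gain control; mean-field
inference supports contour-completion experiments.

## Layout

| module                 | contents                                                              |
| ---------------------- | --------------------------------------------------------------------- |
| `homeodbm.core`        | network/state types, block Gibbs + mean-field sweeps, energies, exact enumeration oracle, balance factor, checkpoints |
| `homeodbm.training`    | receptive-field masks, CD/PCD updates, layer-wise pre-training, exact small-RBM oracles |
| `homeodbm.decoder`     | doubled-weight top-down decoding, traces, montages                    |
| `homeodbm.homeostasis` | target/current activity measurement, bias adaptation, traces          |
| `homeodbm.data`        | shapes corpus, degradation operators (pepper/salt/blank/half-field), trial providers, optional MNIST IDX loader |
| `homeodbm.quality`     | template matching, label-augmented classifier, classification error   |
| `homeodbm.experiments` | deprivation scenarios, suppression/realignment probes, balance-factor fluctuation, contour completion, localization statistics |

## CLI

```bash
# train a shapes model (per-epoch reconstruction error goes to a CSV log)
homeodbm train --dataset shapes --seed 0 --out model.npz

# run a deprivation scenario on a checkpoint
homeodbm experiment --scenario blindness --checkpoint model.npz --seed 0 --out runs/blind

# regenerate the summary figure from a stored run
homeodbm report --run runs/blind
```

Scenarios: `robustness_pepper`, `blindness`, `noise_input`, `fixed_input`,
`half_field`, `lesion_h1`, `ach_fluctuation`. Both commands accept a YAML
config overriding geometry, training and adaptation parameters; defaults sit
in `homeodbm.cli`.

## Notes on conventions

- Layer states may be batched; sampling sweeps update unclamped layers
  bottom-up, block-sampling each layer in parallel (no lateral connections).
- "Activity" is always the activation probability at an update, not the
  binary sample.
- Decoding doubles weights at every step into a hidden layer and not at the
  final step into the visible layer; the bottom-up feature pass mirrors this.
- Decoded probability images in which no pixel reaches grey level 0.5 count
  as empty percepts (quality 0) in experiment scoring; the raw template
  measure itself stays affine-invariant.
- The top half of an image is rows `0 .. ceil(H/2)-1`, everywhere.
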