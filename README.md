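# msatnet

Motor-imagery EEG decoding built from three blocks:

- **Multi-scale feature extraction (MSFE)** — parallel temporal convolution
  branches with different kernel lengths (frequency filters), a depthwise
  convolution across the full channel axis (spatial filter), concatenation
  fusion and a post-fusion convolution, with batch-norm/ELU/average-pooling/
  dropout throughout.
- **Temporal decoder + multi-head attention (ATT)** — a stack of
  dilated-causal residual blocks (TCN-style; receptive field
  `1 + m(K−1)(bⁿ−1)/(b−1)`) followed by scaled dot-product multi-head
  self-attention over the time axis.
- **Subject adapter (SA)** — a residual bottleneck
  (down-project → ELU → up-project) that is exactly the identity at
  insertion; cross-subject transfer pre-trains on source subjects, then
  fine-tunes *only* adapter parameters on half the target subject's trials.

Everything runs on a small numpy reverse-mode autodiff engine
(`msatnet.nn`) — no deep-learning framework required.  A synthetic
ERD/ERS EEG generator (`msatnet.synthetic_eeg`) provides labelled
multi-subject data with controllable class separability and subject
shift, so the full pipeline is testable offline.

## Library quick start

```python
import numpy as np
from msatnet import (
    MSATConfig, MSFEConfig, TrainConfig,
    generate_cohort, run_cross_subject, train_within_subject,
)
from msatnet.synthetic_eeg import DEFAULT_EFFECTS_4CLASS
from msatnet.data_io import SPLIT_2A, split_by_session

# synthetic 9-subject cohort with subject shift
cohort = generate_cohort(
    9, DEFAULT_EFFECTS_4CLASS(0.85), shift_scale=1.0, seed=7,
    n_per_class=16, T=250, channel_names=["C3", "Cz", "C4", "Fz"],
)

cfg = MSATConfig(msfe=MSFEConfig(spatial_kernel_channels=4), n_classes=4)
tc = TrainConfig(max_epochs=100, early_stop_patience=30, seed=0)

# within-subject: session 1 trains, session 2 tests
train, test = split_by_session(cohort[0], SPLIT_2A)

# cross-subject: pretrain on 8 subjects, adapter-fine-tune on the 9th
model, report = run_cross_subject(cohort, target_index=3, model_cfg=cfg, tc=tc, seed=0)
print(report.baseline_accuracy, report.test_accuracy)
```

Defaults follow the reference configuration: two MSFE branches (kernels
64/16, 16 filters, pools 8 and 7, dropout 0.3), decoder with 2 residual
blocks × 2 layers, kernel 4, dilation base 2 (receptive field 19),
2 attention heads, Adam at 0.0008 with batch 64, Glorot initialization,
and a 0.25 max-norm constraint on the final dense layer.

## CLI

```bash
msatnet simulate --subjects 9 --classes 4 --n-per-class 72 --seed 7 --out cohort/
msatnet import-gdf A01T.gdf --layout 2a --window 0:4 --out epochs.h5   # needs mne
msatnet train --config exp.yaml --train train.h5 --test test.h5 --out report.json
msatnet pretrain --cohort cohort/ --target 3 --out run/
msatnet finetune --run run/ --out report.json
msatnet eval --model run/model-finetuned --data test.h5
```

The YAML experiment file mirrors the config dataclasses, e.g.

```yaml
msfe: {branch_kernel_lengths: [64, 16], spatial_kernel_channels: 22}
decoder: {n_blocks: 2, layers_per_block: 2, kernel_length: 4, dilation_base: 2}
model: {n_classes: 4, ablation: full}
train: {batch_size: 64, learning_rate: 0.0008, max_epochs: 1000}
```

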