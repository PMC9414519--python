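# mvha

Hybrid attentive CNN–BiLSTM classification of multichannel physiological
time series, for researchers studying early prediction of acute-care
interventions from bedside monitor data.

Given a 15-minute observation window of one high-frequency waveform (an
ECG-like channel, reference rate 125 Hz) and several 1 Hz vital signs (HR,
Pulse, Resp, SpO2), the model predicts a binary label: does an intravenous
rescue intervention follow immediately after this window?  Windows are cut
from the 30 minutes before each recorded intervention — first half
negative, second half positive — and split into M = 15 one-minute segments
s₁…s_M per channel.

The model (MVHA, Multi-Variable Hybrid Attentive model) composes per
channel: a 1-D CNN segment encoder (O ∈ R^{U×M}, activations summed over
positions), a **fluctuant attention** α = softmax(Vᵀ(Wᵀ[O; A_fl] ⊕ b))
whose knowledge row A_fl holds each segment's standard deviation, a 3-layer
Bi-LSTM whose outputs sum to z ∈ R^J; channels are stacked (Z ∈ R^{J×CH}),
transformed (X = W_zᵀZ ⊕ b_z) and fused by a **trend attention**
β = softmax(Vᵀ(Wᵀ[X; A_tr] ⊕ b)) whose knowledge row A_tr holds each
channel's range of scaled segment means, giving d = Σ_c β_c x_c.  The
softmax head reads d together with the consecutive-segment differences
tr(kt) = |ρ(s_{k+1}) − ρ(s_k)|.  The α and β weights are exported as
interpretability tables.  Five ablation variants (CNN (ECG), CNN-LSTM,
CNN-FAttn, CLSTM-FAttn, CLSTM-TAttn) isolate each ingredient.

The network and its training loop run on a small numpy reverse-mode
autodiff core shipped with the package (`mvha.autodiff`); no deep-learning
framework is required.  A seeded generator of ICU-like records with planted
variance bursts and level shifts provides ground truth for testing whether
the attentions recover what was planted.

## Worked example

```python
import numpy as np
from mvha import (SynthConfig, generate_dataset, build_dataset, split_dataset,
                  build_model, train, evaluate, attention_recovery,
                  ModelConfig, TrainConfig, ChannelSpec)

channels = [ChannelSpec("ECG", "high_frequency", 8.0),   # reduced-rate stand-in
            ChannelSpec("HR", "numeric", 1.0),
            ChannelSpec("SpO2", "numeric", 1.0)]
windows, truth = generate_dataset(SynthConfig(n_events=50, channels=channels,
                                              missing_rate=0.01, seed=7))
ds = build_dataset(windows, truth=truth)
tcfg = TrainConfig(epochs=6, batch_size=16, seed=0)
tr, val, te = split_dataset(ds, tcfg)
model = build_model(ModelConfig(seed=1), ds.channel_specs, n_segments=15)
train(model, tr, val, tcfg)
print(evaluate(model, te))
print(attention_recovery(model, te))
```

Output:

```
Metrics(accuracy=1.0, roc_auc=1.0, f1=1.0)
{'alpha_localization_rate': 1.0, 'beta_top_channel': 'HR',
 'beta_trend_channel_is_top': True, 'mean_beta':
 {'ECG': 1.1012530835084088e-11, 'HR': 0.9999999999889864,
  'SpO2': 9.321560451178488e-16}}
```

With the generator's default anomalies (noise SD ×4 in segments 11–13 of
every positive window, a level shift of half the channel range in HR) the
task is cleanly separable, so the test metrics reach 1.0; the interesting
part is the recovery report: on every held-out positive window the largest
α falls inside the planted segment set, and HR — the planted trend channel
— ends up holding essentially all of the trend attention mass, i.e. the
attention weights point back at the anomalies that caused the label.

## Command line

```bash
mvha synth --config config.yaml --seed 1 --out data/      # dataset + truth
mvha train --config config.yaml --data data/ --out model.npz
mvha evaluate --config config.yaml --checkpoint model.npz --data data/
mvha ablate --config config.yaml --data data/ --out results.csv
mvha explain --checkpoint model.npz --data data/ --out attn/
```

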