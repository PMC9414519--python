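"""Straight-line, loop-based reference of the composed forward pass.

Written independently of mvha.model: plain Python loops over segments,
filters, timesteps and channels, consuming the same parameter arrays.
Assumes the simplified oracle configuration — stride 1, no batch
normalization, pool width 1 (identity) — so the comparison isolates the
model algebra: conv encode + column sum, knowledge attention, Bi-LSTM
recursion with sigmoid gates / tanh candidate, summed outputs, linear
transform with broadcast bias, trend fusion, covariate head, softmax.
"""

import math

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def conv_encode_ref(segments, w, b):
    """segments (M, n); w (U, 1, K); b (U,) -> O (U, M), summing conv output."""
    m, n = segments.shape
    u, _, k = w.shape
    out = np.zeros((u, m))
    for seg in range(m):
        for f in range(u):
            total = 0.0
            for j in range(n - k + 1):
                acc = b[f]
                for t in range(k):
                    acc += w[f, 0, t] * segments[seg, j + t]
                total += max(acc, 0.0)  # ReLU after conv
            out[f, seg] = total
    return out


def attention_ref(feats, knowledge, w, b, v):
    """feats (F, L), knowledge (L,) -> (weights (L,), attended (F, L))."""
    f, l = feats.shape
    scores = np.zeros(l)
    for col in range(l):
        column = np.concatenate([feats[:, col], [knowledge[col]]])
        hidden = w.T @ column + b
        scores[col] = float(v @ hidden)
    e = np.exp(scores - scores.max())
    weights = e / e.sum()
    attended = feats * weights[None, :]
    return weights, attended


def lstm_direction_ref(xs, wx, wh, b, hidden):
    """One LSTM direction, step by step; xs list of (in,) vectors."""
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    outs = []
    for x in xs:
        gates = wx.T @ x + wh.T @ h + b
        ig = np.array([sigmoid(g) for g in gates[0:hidden]])
        fg = np.array([sigmoid(g) for g in gates[hidden:2 * hidden]])
        cand = np.tanh(gates[2 * hidden:3 * hidden])
        og = np.array([sigmoid(g) for g in gates[3 * hidden:4 * hidden]])
        c = fg * c + ig * cand
        h = og * np.tanh(c)
        outs.append(h.copy())
    return outs


def bilstm_ref(of_cols, params, prefix, hidden, layers):
    """of_cols: list of M input vectors -> H (2*hidden, M) after stacked BiLSTM."""
    xs = [np.asarray(x, dtype=float) for x in of_cols]
    for layer in range(layers):
        base = f"{prefix}/lstm{layer}"
        fw = lstm_direction_ref(xs, params[f"{base}/fw/Wx"], params[f"{base}/fw/Wh"],
                                params[f"{base}/fw/b"], hidden)
        bw = lstm_direction_ref(xs[::-1], params[f"{base}/bw/Wx"],
                                params[f"{base}/bw/Wh"], params[f"{base}/bw/b"],
                                hidden)[::-1]
        xs = [np.concatenate([f, b]) for f, b in zip(fw, bw)]
    return np.stack(xs, axis=1)


def forward_ref(batch_one, params, channel_names, channel_kinds, cfg):
    """Full composed forward for ONE window; returns (probs, alpha, beta).

    batch_one: dict with 'segments' {name: (M, n)}, 'fluct' (CH, M),
    'trend' (CH,), 'tr' (n_tr,).  cfg: dict with num_filters, lstm_hidden,
    lstm_layers, fc_out.
    """
    hidden = cfg["lstm_hidden"]
    zs, alphas = [], {}
    for name in channel_names:
        o = conv_encode_ref(batch_one["segments"][name],
                            params[f"{name}/conv0/w"], params[f"{name}/conv0/b"])
        a_fl = batch_one["fluct"][channel_names.index(name)]
        alpha, of = attention_ref(o, a_fl, params[f"{name}/fluct/W"],
                                  params[f"{name}/fluct/b"], params[f"{name}/fluct/V"])
        alphas[name] = alpha
        h = bilstm_ref([of[:, k] for k in range(of.shape[1])], params, name,
                       hidden, cfg["lstm_layers"])
        zs.append(h.sum(axis=1))
    z_stack = np.stack(zs, axis=1)                       # (J, CH)
    x = params["fc/Wz"].T @ z_stack + params["fc/bz"][:, None]
    beta, attended = attention_ref(x, batch_one["trend"], params["trend/W"],
                                   params["trend/b"], params["trend/V"])
    d = attended.sum(axis=1)
    logits = params["head/Whd"].T @ d + params["head/Wtr"].T @ batch_one["tr"] \
        + params["head/b"]
    e = np.exp(logits - logits.max())
    return e / e.sum(), alphas, beta
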