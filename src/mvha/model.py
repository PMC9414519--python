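"""The hybrid attentive CNN–BiLSTM model and its ablation variants.

Per channel: a kind-specific stack of 1-D convolutions encodes each
1-minute segment and sums activations over positions, giving one feature
vector per segment (O ∈ R^{U×M}); a *fluctuant attention* scores each
segment from its CNN features concatenated with the segment's standard
deviation and rescales the columns; a Bi-LSTM encodes the attended segment
sequence and its outputs are summed over time into z ∈ R^J.  The per-channel
z vectors are stacked (Z ∈ R^{J×CH}), linearly transformed (X ∈ R^{I×CH}),
fused across channels by a *trend attention* driven by each channel's
scaled trend range (d = Σ_c β_c x_c), and classified by a softmax head that
also receives the consecutive-segment difference covariates tr(kt).

Attention scorers use a two-layer form: score = Vᵀ(Wᵀ·col + b), softmax
over segments (α) or channels (β).  The row of W that multiplies the
knowledge feature is initialized positive ("knowledge-primed") so the
domain prior is active from the first epoch; all weights remain trainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .records import HIGH_FREQUENCY, ChannelSpec, ValidationError

VARIANTS = ("MVHA", "CNN (ECG)", "CNN-LSTM", "CNN-FAttn", "CLSTM-FAttn", "CLSTM-TAttn")

#: initialization scale of the attention scorers (see module docstring)
_ATTN_FEATURE_SD = 0.01
_ATTN_KNOWLEDGE_W = 0.5
_ATTN_V = 0.5


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    num_filters: int = 8                       # U
    conv_kernels_highfreq: tuple[int, ...] = (10, 5, 3)
    conv_kernels_numeric: tuple[int, ...] = (5, 2)
    conv_stride: int = 1
    pool_width: int = 2                        # non-overlapping max pool per layer
    use_batchnorm: bool = True
    lstm_layers: int = 3
    lstm_hidden: int = 16                      # per direction; J = 2*lstm_hidden
    attn_hidden_fl: int = 8                    # D_fl
    attn_hidden_tr: int = 8                    # D_tr
    fc_out: int = 16                           # I
    dropout: float = 0.5
    statistic_set: tuple[str, ...] = ("mean",)
    seed: int = 0

    def __post_init__(self):
        for name in ("num_filters", "lstm_layers", "lstm_hidden",
                     "attn_hidden_fl", "attn_hidden_tr", "fc_out"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")
        if self.conv_stride not in (1, 2):
            raise ValidationError("conv_stride must be 1 or 2")


@dataclass
class ForwardOutput:
    probs: Tensor                      # (B, 2) simplex rows
    logits: Tensor                     # (B, 2)
    alpha: dict[str, np.ndarray]       # per channel (B, M); empty if no fluct path
    beta: np.ndarray | None            # (B, CH)

    @property
    def labels(self) -> np.ndarray:
        # tie at exactly 0.5/0.5 resolves to class 0 (argmax lower index)
        return np.argmax(self.probs.data, axis=1)


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[0] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _ConvBranch:
    """Stacked conv → (batchnorm) → ReLU → maxpool layers for one channel."""

    def __init__(self, name: str, kernels: tuple[int, ...], cfg: ModelConfig,
                 seg_len: int, rng: np.random.Generator):
        self.name = name
        self.kernels = kernels
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self.running: list[dict] = []
        n = seg_len
        c_in = 1
        for l, k in enumerate(kernels):
            if (n - k) // cfg.conv_stride + 1 < 1:
                raise ValidationError(
                    f"channel {name!r}: segment length {n} shorter than kernel {k} "
                    f"at conv layer {l + 1}")
            w = Tensor(_glorot(rng, cfg.num_filters, c_in, k) / np.sqrt(k),
                       requires_grad=True)
            b = Tensor(np.zeros(cfg.num_filters), requires_grad=True)
            self.params[f"{name}/conv{l}/w"] = w
            self.params[f"{name}/conv{l}/b"] = b
            if cfg.use_batchnorm:
                self.params[f"{name}/bn{l}/gamma"] = Tensor(np.ones(cfg.num_filters),
                                                            requires_grad=True)
                self.params[f"{name}/bn{l}/beta"] = Tensor(np.zeros(cfg.num_filters),
                                                           requires_grad=True)
            self.running.append({"mean": np.zeros(cfg.num_filters),
                                 "var": np.ones(cfg.num_filters)})
            n = (n - k) // cfg.conv_stride + 1
            if n // cfg.pool_width >= 1:
                n = n // cfg.pool_width
            c_in = cfg.num_filters
        self.out_len = n  # J_conv

    def forward(self, x: Tensor, training: bool) -> Tensor:
        """(B*, 1, n) -> (B*, U, J_conv)."""
        cfg = self.cfg
        for l in range(len(self.kernels)):
            x = ad.conv1d(x, self.params[f"{self.name}/conv{l}/w"],
                          self.params[f"{self.name}/conv{l}/b"], stride=cfg.conv_stride)
            if cfg.use_batchnorm:
                x = ad.batchnorm(x, self.params[f"{self.name}/bn{l}/gamma"],
                                 self.params[f"{self.name}/bn{l}/beta"],
                                 self.running[l], training)
            x = x.relu()
            if x.shape[2] // cfg.pool_width >= 1:
                x = ad.maxpool1d(x, cfg.pool_width)
        return x

    def encode_segments(self, segs: np.ndarray, training: bool) -> Tensor:
        """(B, M, n) raw segments -> O (B, U, M), summing conv maps over positions."""
        b, m, n = segs.shape
        x = Tensor(segs.reshape(b * m, 1, n))
        p = self.forward(x, training)               # (B*M, U, J_conv)
        o = p.sum(axis=2)                           # column sum over positions
        return o.reshape(b, m, self.cfg.num_filters).transpose(0, 2, 1)


class _KnowledgeAttention:
    """Two-layer scorer over the columns of a feature matrix plus one knowledge row."""

    def __init__(self, prefix: str, n_features: int, hidden: int,
                 rng: np.random.Generator):
        w = rng.normal(0.0, _ATTN_FEATURE_SD, size=(n_features + 1, hidden))
        w[-1, :] = _ATTN_KNOWLEDGE_W  # knowledge-primed row (positive pass-through)
        self.params = {
            f"{prefix}/W": Tensor(w, requires_grad=True),
            f"{prefix}/b": Tensor(np.zeros(hidden), requires_grad=True),
            f"{prefix}/V": Tensor(np.full(hidden, _ATTN_V), requires_grad=True),
        }
        self.prefix = prefix

    def forward(self, feats: Tensor, knowledge: np.ndarray) -> tuple[Tensor, Tensor]:
        """feats (B, F, L), knowledge (B, L) -> (weights (B, L), attended (B, F, L))."""
        know = Tensor(knowledge[:, None, :])
        cols = ad.concat([feats, know], axis=1)       # (B, F+1, L)
        h = cols.transpose(0, 2, 1) @ self.params[f"{self.prefix}/W"]  # (B, L, D)
        h = h + self.params[f"{self.prefix}/b"]
        scores = h @ self.params[f"{self.prefix}/V"]  # (B, L)
        weights = ad.softmax(scores, axis=-1)
        attended = feats * weights.reshape(weights.shape[0], 1, weights.shape[1])
        return weights, attended


class _BiLSTM:
    """Stacked bidirectional LSTM; gate order (input, forget, candidate, output)."""

    def __init__(self, prefix: str, in_dim: int, hidden: int, layers: int,
                 rng: np.random.Generator):
        self.prefix = prefix
        self.hidden = hidden
        self.layers = layers
        self.params: dict[str, Tensor] = {}
        for l in range(layers):
            d_in = in_dim if l == 0 else 2 * hidden
            for direction in ("fw", "bw"):
                base = f"{prefix}/lstm{l}/{direction}"
                self.params[f"{base}/Wx"] = Tensor(_glorot(rng, d_in, 4 * hidden),
                                                   requires_grad=True)
                self.params[f"{base}/Wh"] = Tensor(_glorot(rng, hidden, 4 * hidden),
                                                   requires_grad=True)
                self.params[f"{base}/b"] = Tensor(np.zeros(4 * hidden),
                                                  requires_grad=True)

    def _run_direction(self, xs: list[Tensor], base: str) -> list[Tensor]:
        wx, wh, b = (self.params[f"{base}/Wx"], self.params[f"{base}/Wh"],
                     self.params[f"{base}/b"])
        bsz = xs[0].shape[0]
        h = Tensor(np.zeros((bsz, self.hidden)))
        c = Tensor(np.zeros((bsz, self.hidden)))
        hh = self.hidden
        outs = []
        for x in xs:
            gates = x @ wx + h @ wh + b
            ig = gates[:, 0:hh].sigmoid()
            fg = gates[:, hh:2 * hh].sigmoid()
            cand = gates[:, 2 * hh:3 * hh].tanh()
            og = gates[:, 3 * hh:4 * hh].sigmoid()
            c = fg * c + ig * cand
            h = og * c.tanh()
            outs.append(h)
        return outs

    def forward(self, x: Tensor) -> Tensor:
        """(B, M, in) -> H sequence (B, M, 2*hidden)."""
        m = x.shape[1]
        xs = [x[:, t, :] for t in range(m)]
        for l in range(self.layers):
            fw = self._run_direction(xs, f"{self.prefix}/lstm{l}/fw")
            bw = self._run_direction(xs[::-1], f"{self.prefix}/lstm{l}/bw")[::-1]
            xs = [ad.concat([f, b], axis=1) for f, b in zip(fw, bw)]
        return ad.stack(xs, axis=1)


class MVHAModel:
    """The full hybrid model, parameterized by `variant` for ablations.

    Variant semantics:

    - ``MVHA``: both attentions active.
    - ``CNN-LSTM``: α and β replaced by uniform weights (1/M, 1/CH).
    - ``CLSTM-FAttn``: fluctuant attention only; β uniform.
    - ``CLSTM-TAttn``: trend attention only; α uniform.
    - ``CNN-FAttn``: no LSTM; attended CNN features of all channels are
      flattened into a linear softmax head (no tr(kt) covariates).
    - ``CNN (ECG)``: the high-frequency branch alone, flattened into a
      linear softmax head.
    """

    def __init__(self, config: ModelConfig, channel_specs: list[ChannelSpec],
                 n_segments: int, step_seconds: float = 60.0, variant: str = "MVHA"):
        if variant not in VARIANTS:
            raise ValidationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.config = config
        self.variant = variant
        self.m = n_segments
        self.step_seconds = step_seconds
        rng = np.random.default_rng(config.seed)
        self.rng_dropout = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])

        if variant == "CNN (ECG)":
            hf = [c for c in channel_specs if c.kind == HIGH_FREQUENCY]
            if not hf:
                raise ValidationError("CNN (ECG) variant needs a high-frequency channel")
            self.channel_specs = [hf[0]]
        else:
            self.channel_specs = list(channel_specs)
        self.channel_names = [c.name for c in self.channel_specs]

        self.use_lstm = variant not in ("CNN (ECG)", "CNN-FAttn")
        self.use_fluct = variant in ("MVHA", "CNN-FAttn", "CLSTM-FAttn")
        self.use_trend = variant in ("MVHA", "CLSTM-TAttn")
        self.use_tr_covariates = self.use_lstm  # covariate head only on LSTM variants

        self.params: dict[str, Tensor] = {}
        self.branches: dict[str, _ConvBranch] = {}
        self.fluct_attn: dict[str, _KnowledgeAttention] = {}
        u = config.num_filters
        for spec in self.channel_specs:
            kernels = (config.conv_kernels_highfreq if spec.kind == HIGH_FREQUENCY
                       else config.conv_kernels_numeric)
            seg_len = int(round(step_seconds * spec.sampling_rate))
            branch = _ConvBranch(spec.name, kernels, config, seg_len, rng)
            self.branches[spec.name] = branch
            self.params.update(branch.params)
            if self.use_fluct:
                attn = _KnowledgeAttention(f"{spec.name}/fluct", u,
                                           config.attn_hidden_fl, rng)
                self.fluct_attn[spec.name] = attn
                self.params.update(attn.params)

        ch = len(self.channel_specs)
        if self.use_lstm:
            j = 2 * config.lstm_hidden
            self.lstms = {}
            for spec in self.channel_specs:
                lstm = _BiLSTM(spec.name, u, config.lstm_hidden, config.lstm_layers, rng)
                self.lstms[spec.name] = lstm
                self.params.update(lstm.params)
            self.params["fc/Wz"] = Tensor(_glorot(rng, j, config.fc_out),
                                          requires_grad=True)
            self.params["fc/bz"] = Tensor(np.zeros(config.fc_out), requires_grad=True)
            if self.use_trend:
                self.trend_attn = _KnowledgeAttention("trend", config.fc_out,
                                                      config.attn_hidden_tr, rng)
                self.params.update(self.trend_attn.params)
            n_tr = (n_segments - 1) * ch * len(config.statistic_set)
            self.n_tr_covariates = n_tr
            # zero-init head: logits start at 0 so no random initial class
            # orientation on label-correlated covariates; gradients still flow
            self.params["head/Whd"] = Tensor(np.zeros((config.fc_out, 2)),
                                             requires_grad=True)
            self.params["head/Wtr"] = Tensor(np.zeros((n_tr, 2)),
                                             requires_grad=True)
            self.params["head/b"] = Tensor(np.zeros(2), requires_grad=True)
        else:
            self.n_tr_covariates = 0
            d_in = u * n_segments * ch
            self.params["head/Wflat"] = Tensor(np.zeros((d_in, 2)), requires_grad=True)
            self.params["head/b"] = Tensor(np.zeros(2), requires_grad=True)

    # ------------------------------------------------------------------ forward
    def forward(self, batch: dict, training: bool = False) -> ForwardOutput:
        """Run the composed network.

        ``batch`` carries ``segments`` (name -> (B, M, n) float array),
        ``fluct`` (B, CH, M), ``trend`` (B, CH) and ``tr`` (B, n_tr) arrays
        in the channel order of the full channel list used at build time.
        """
        cfg = self.config
        names = self.channel_names
        all_names: list[str] = batch["channel_order"]
        b = next(iter(batch["segments"].values())).shape[0]
        alphas: dict[str, np.ndarray] = {}
        per_channel_feats: list[Tensor] = []
        for name in names:
            segs = batch["segments"][name]
            o = self.branches[name].encode_segments(segs, training)  # (B, U, M)
            if self.use_fluct:
                a_fl = batch["fluct"][:, all_names.index(name), :]
                alpha, of = self.fluct_attn[name].forward(o, a_fl)
                alphas[name] = alpha.data.copy()
            else:
                of = o * (1.0 / self.m)  # uniform α
            per_channel_feats.append(of)

        if self.use_lstm:
            zs = []
            for name, of in zip(names, per_channel_feats):
                h_seq = self.lstms[name].forward(of.transpose(0, 2, 1))  # (B, M, J)
                zs.append(h_seq.sum(axis=1))                             # (B, J)
            z_stack = ad.stack(zs, axis=2)                               # (B, J, CH)
            wz, bz = self.params["fc/Wz"], self.params["fc/bz"]
            x = wz.transpose(1, 0) @ z_stack                             # (B, I, CH)
            x = x + bz.reshape(1, cfg.fc_out, 1)
            if self.use_trend:
                a_tr = np.stack([batch["trend"][:, all_names.index(n)] for n in names],
                                axis=1)
                beta_t, attended = self.trend_attn.forward(x, a_tr)
                beta = beta_t.data.copy()
                d = attended.sum(axis=2)                                 # (B, I)
            else:
                beta = np.full((b, len(names)), 1.0 / len(names))
                d = x.sum(axis=2) * (1.0 / len(names))
            d = ad.dropout(d, cfg.dropout, self.rng_dropout, training)
            logits = d @ self.params["head/Whd"] + self.params["head/b"]
            if self.n_tr_covariates:
                logits = logits + Tensor(batch["tr"]) @ self.params["head/Wtr"]
        else:
            flat = ad.concat([f.reshape(b, -1) for f in per_channel_feats], axis=1)
            flat = ad.dropout(flat, cfg.dropout, self.rng_dropout, training)
            logits = flat @ self.params["head/Wflat"] + self.params["head/b"]
            beta = None
        probs = ad.softmax(logits, axis=-1)
        return ForwardOutput(probs=probs, logits=logits, alpha=alphas, beta=beta)

    # ------------------------------------------------------------------- utils
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param:{k}": v.data for k, v in self.params.items()}
        for name, branch in self.branches.items():
            for l, r in enumerate(branch.running):
                out[f"running:{name}/bn{l}/mean"] = r["mean"]
                out[f"running:{name}/bn{l}/var"] = r["var"]
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in arrays.items():
            kind, _, name = k.partition(":")
            if kind == "param":
                self.params[name].data = np.array(v, dtype=float)
            elif kind == "running":
                chan, bn, stat = name.rsplit("/", 2)
                self.branches[chan].running[int(bn[2:])][stat] = np.array(v, dtype=float)


def count_parameters(model_or_tensors) -> int:
    """Total scalar parameter count of a model or an iterable of arrays."""
    if isinstance(model_or_tensors, MVHAModel):
        items = model_or_tensors.parameters()
    else:
        items = list(model_or_tensors)
    total = 0
    for t in items:
        total += int(np.asarray(t.data if isinstance(t, Tensor) else t).size)
    return total


def ce_loss(probs: Tensor, labels: np.ndarray, reduction: str = "sum") -> Tensor:
    """Cross-entropy −Σ_i y_i·log ŷ_i over a batch of simplex rows.

    ``reduction="sum"`` is the textbook batch sum; ``"mean"`` divides by the
    batch size (the form handed to the optimizer).  Probabilities are
    clipped at 1e-12 before the log.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros((labels.size, 2))
        onehot[np.arange(labels.size), labels.astype(int)] = 1.0
    else:
        onehot = labels.astype(float)
    if onehot.shape != probs.shape:
        raise ValidationError(f"label shape {onehot.shape} != probs {probs.shape}")
    nll = -(Tensor(onehot) * probs.clamp_min(1e-12).log()).sum()
    if reduction == "mean":
        return nll * (1.0 / onehot.shape[0])
    if reduction == "sum":
        return nll
    raise ValidationError(f"unknown reduction {reduction!r}")


def ce_loss_logits(logits: Tensor, labels: np.ndarray,
                   reduction: str = "mean") -> Tensor:
    """Cross-entropy straight from logits via log-softmax.

    Identical in value to ``ce_loss(softmax(logits), labels)`` but keeps a
    usable gradient for confidently-wrong instances (probability-space CE
    clips at 1e-12, whose flat region would silence them); the optimizer
    consumes this form.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros((labels.size, 2))
        onehot[np.arange(labels.size), labels.astype(int)] = 1.0
    else:
        onehot = labels.astype(float)
    shift = logits.data.max(axis=-1, keepdims=True)
    lse = (logits - shift).exp().sum(axis=-1, keepdims=True).log() + shift
    log_probs = logits - lse
    nll = -(Tensor(onehot) * log_probs).sum()
    if reduction == "mean":
        return nll * (1.0 / onehot.shape[0])
    return nll


def build_model(config: ModelConfig, channel_specs: list[ChannelSpec],
                n_segments: int, step_seconds: float = 60.0) -> MVHAModel:
    """Construct the full MVHA network; wiring and shapes validated at build."""
    return MVHAModel(config, channel_specs, n_segments, step_seconds, variant="MVHA")


def ablation_variant(name: str, config: ModelConfig,
                     channel_specs: list[ChannelSpec], n_segments: int,
                     step_seconds: float = 60.0) -> MVHAModel:
    """One of the five baseline/ablation models (or MVHA itself by name)."""
    return MVHAModel(config, channel_specs, n_segments, step_seconds, variant=name)


# -------------------------------------------------------------- checkpoints

def save_checkpoint(model: MVHAModel, path: str | Path,
                    channel_specs: list[ChannelSpec] | None = None) -> None:
    """Archive config + variant + every parameter tensor, with a text sidecar."""
    path = Path(path)
    meta = {
        "variant": model.variant,
        "n_segments": model.m,
        "step_seconds": model.step_seconds,
        "config": asdict(model.config),
        "channels": [asdict(c) for c in (channel_specs or model.channel_specs)],
    }
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    sidecar = path.with_suffix(path.suffix + ".txt") if path.suffix != ".npz" \
        else path.with_suffix(".txt")
    with open(sidecar, "w") as fh:
        for k in sorted(arrays):
            fh.write(f"{k}\t{tuple(np.asarray(arrays[k]).shape)}\n")


def load_checkpoint(path: str | Path) -> MVHAModel:
    with np.load(Path(path), allow_pickle=False) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_d = meta["config"]
    for key in ("conv_kernels_highfreq", "conv_kernels_numeric", "statistic_set"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = ModelConfig(**cfg_d)
    specs = [ChannelSpec(**c) for c in meta["channels"]]
    model = MVHAModel(cfg, specs, meta["n_segments"], meta["step_seconds"],
                      variant=meta["variant"])
    model.load_state_arrays(arrays)
    return model
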