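"""Training, evaluation, ablation comparison and attention export.

Ties the pieces together: labeled windows are imputed, segmented and
featurized into a `WindowDataset`; datasets are split at *window-pair*
granularity (the negative and positive halves of one event always travel
together, so no event leaks across splits); models are trained with
mean-reduced cross-entropy and best-validation-loss checkpointing; metrics
are accuracy at the 0.5 threshold, ROC-AUC (midrank ties) and the positive
class F1; attention weights are exported as long-form tables with the
high/medium/low highlight categories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from . import autodiff as ad
from .features import fluct_knowledge, segment_diffs, trend_knowledge
from .model import (MVHAModel, ModelConfig, VARIANTS, ablation_variant,
                    ce_loss_logits)
from .records import (ChannelSpec, LabeledWindow, ValidationError,
                      impute_missing, segment_window)
from .synthgen import SynthTruth, WindowTruth

_EVAL_CHUNK = 64  # forward-pass chunk during evaluation (memory bound)


@dataclass
class TrainConfig:
    optimizer: str = "adam"          # adam | sgd | adagrad
    learning_rate: float = 0.002
    batch_size: int = 128
    epochs: int = 30
    split: tuple[float, float, float] = (0.70, 0.10, 0.20)
    patience: int = 5                # early stopping on validation loss
    grad_clip: float = 5.0           # global gradient-norm clip (0 disables)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd", "adagrad"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class Metrics:
    accuracy: float
    roc_auc: float
    f1: float


@dataclass
class WindowDataset:
    """Featurized windows ready for the model.

    ``segments[name]`` is (N, M, n_name); ``fluct`` (N, CH, M); ``trend``
    (N, CH); ``tr`` (N, (M-1)*CH*|stats|) channel-major per statistic;
    ``labels`` (N,).  Sibling windows of one event sit at positions 2i
    (negative) and 2i+1 (positive).
    """

    channel_specs: list[ChannelSpec]
    segments: dict[str, np.ndarray]
    fluct: np.ndarray
    trend: np.ndarray
    tr: np.ndarray
    labels: np.ndarray
    window_ids: list[str]
    truth: list[WindowTruth] | None = None

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def channel_order(self) -> list[str]:
        return [c.name for c in self.channel_specs]

    def batch(self, idx: np.ndarray) -> dict:
        return {
            "segments": {k: v[idx] for k, v in self.segments.items()},
            "fluct": self.fluct[idx],
            "trend": self.trend[idx],
            "tr": self.tr[idx],
            "channel_order": self.channel_order,
        }

    def subset(self, idx: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            channel_specs=self.channel_specs,
            segments={k: v[idx] for k, v in self.segments.items()},
            fluct=self.fluct[idx], trend=self.trend[idx], tr=self.tr[idx],
            labels=self.labels[idx],
            window_ids=[self.window_ids[i] for i in idx],
            truth=None if self.truth is None else [self.truth[i] for i in idx])


def build_dataset(windows: list[LabeledWindow], step_seconds: float = 60.0,
                  statistic_set: tuple[str, ...] = ("mean",),
                  truth: SynthTruth | None = None) -> WindowDataset:
    """Impute, segment and featurize labeled windows into model-ready arrays.

    Knowledge features and tr(kt) covariates are computed on the raw
    (imputed) values.  The segment arrays handed to the CNN are standardized
    per window and channel (zero mean, unit SD): raw vital-sign levels sit
    far from zero, where ordinary weight drift during training shifts
    pre-normalization activations by many batch SDs and wrecks the running
    statistics that evaluation-mode batch normalization relies on.
    """
    if not windows:
        raise ValidationError("no windows to build a dataset from")
    specs = windows[0].channels
    names = [c.name for c in specs]
    seg_arrays: dict[str, list[np.ndarray]] = {n: [] for n in names}
    fl, tr_k, diffs, labels = [], [], [], []
    for w in windows:
        series = []
        for c, s in zip(w.channels, w.series):
            series.append(impute_missing(s, c.sampling_rate) if np.isnan(s).any() else s)
        w = LabeledWindow(channels=w.channels, series=series, label=w.label,
                          source_event_time=w.source_event_time, half=w.half,
                          window_seconds=w.window_seconds)
        seg = segment_window(w, step_seconds)
        for n in names:
            x = seg.segments[n]
            sd = x.std()
            seg_arrays[n].append((x - x.mean()) / (sd if sd > 0 else 1.0))
        fl.append(fluct_knowledge(seg).values)
        tr_k.append(trend_knowledge(seg).values)
        diffs.append(segment_diffs(seg, statistic_set).flatten())
        labels.append(w.label)
    return WindowDataset(
        channel_specs=list(specs),
        segments={n: np.stack(v) for n, v in seg_arrays.items()},
        fluct=np.stack(fl), trend=np.stack(tr_k), tr=np.stack(diffs),
        labels=np.asarray(labels, dtype=int),
        window_ids=[f"w{i:05d}" for i in range(len(windows))],
        truth=None if truth is None else list(truth.windows))


# ------------------------------------------------------------------ split

def split_dataset(dataset: WindowDataset, config: TrainConfig
                  ) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Seeded 70/10/20 split at window-pair granularity (no sibling leakage)."""
    if dataset.n < 10:
        raise ValidationError(f"need at least 10 windows to split, got {dataset.n}")
    if dataset.n % 2:
        raise ValidationError("dataset must consist of sibling window pairs")
    pairs = dataset.n // 2
    expect = np.tile([0, 1], pairs)
    if not np.array_equal(dataset.labels, expect):
        raise ValidationError("windows must alternate negative/positive sibling pairs")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(pairs)
    n_tr = int(pairs * config.split[0])
    n_val = max(1, int(pairs * config.split[1]))  # every split gets >= 1 pair
    n_tr = min(n_tr, pairs - n_val - 1)
    chunks = (order[:n_tr], order[n_tr:n_tr + n_val], order[n_tr + n_val:])
    out = []
    for pair_idx in chunks:
        win_idx = np.sort(np.concatenate([2 * pair_idx, 2 * pair_idx + 1]))
        out.append(dataset.subset(win_idx))
    return tuple(out)


# ------------------------------------------------------------------ training

def _make_optimizer(params, cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return ad.Adam(params, lr=cfg.learning_rate)
    if cfg.optimizer == "adagrad":
        return ad.Adagrad(params, lr=cfg.learning_rate)
    return ad.SGD(params, lr=cfg.learning_rate)


def _dataset_loss(model: MVHAModel, ds: WindowDataset) -> float:
    total = 0.0
    for lo in range(0, ds.n, _EVAL_CHUNK):
        idx = np.arange(lo, min(lo + _EVAL_CHUNK, ds.n))
        out = model.forward(ds.batch(idx), training=False)
        total += float(ce_loss_logits(out.logits, ds.labels[idx],
                                      reduction="sum").data)
    return total / ds.n


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params
                        if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def train(model: MVHAModel, train_ds: WindowDataset, val_ds: WindowDataset,
          config: TrainConfig) -> dict:
    """Minimize mean cross-entropy; return history, restoring the best-val state."""
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(model.parameters(), config)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, best_epoch, since_best = np.inf, None, -1, 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_ds.n)
        epoch_loss = 0.0
        for lo in range(0, train_ds.n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            out = model.forward(train_ds.batch(idx), training=True)
            loss = ce_loss_logits(out.logits, train_ds.labels[idx], reduction="mean")
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: loss={loss.data!r} at epoch {epoch}, "
                    f"lr={config.learning_rate}, optimizer={config.optimizer}")
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                _clip_grad_norm(model.parameters(), config.grad_clip)
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        history["train_loss"].append(epoch_loss / train_ds.n)
        val_loss = _dataset_loss(model, val_ds)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val, best_epoch, since_best = val_loss, epoch, 0
            best_state = copy.deepcopy(model.state_arrays())
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return history


def predict_proba(model: MVHAModel, ds: WindowDataset) -> np.ndarray:
    """Positive-class probability per window (chunked eval forward)."""
    out = np.empty(ds.n)
    for lo in range(0, ds.n, _EVAL_CHUNK):
        idx = np.arange(lo, min(lo + _EVAL_CHUNK, ds.n))
        fwd = model.forward(ds.batch(idx), training=False)
        out[idx] = fwd.probs.data[:, 1]
    return out


def compute_metrics(labels: np.ndarray, p1: np.ndarray) -> Metrics:
    """ACC at the 0.5 threshold, midrank ROC-AUC, positive-class F1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("empty test set")
    if len(np.unique(labels)) < 2:
        raise ValidationError("test set must contain both classes (AUC undefined)")
    pred = (np.asarray(p1) > 0.5).astype(int)  # tie at 0.5 resolves to class 0
    return Metrics(accuracy=float(accuracy_score(labels, pred)),
                   roc_auc=float(roc_auc_score(labels, p1)),
                   f1=float(f1_score(labels, pred)))


def evaluate(model: MVHAModel, test_ds: WindowDataset) -> Metrics:
    """Score a trained model on a held-out set."""
    return compute_metrics(test_ds.labels, predict_proba(model, test_ds))


def run_ablation_suite(dataset: WindowDataset, model_config: ModelConfig,
                       train_config: TrainConfig) -> pd.DataFrame:
    """Train and evaluate the five baselines plus MVHA on one split/seed."""
    train_ds, val_ds, test_ds = split_dataset(dataset, train_config)
    rows = []
    for variant in VARIANTS:
        model = ablation_variant(variant, model_config, dataset.channel_specs,
                                 n_segments=dataset.fluct.shape[2],
                                 step_seconds=_step_seconds(dataset))
        train(model, train_ds, val_ds, train_config)
        m = evaluate(model, test_ds)
        rows.append({"model": variant, "accuracy": m.accuracy,
                     "roc_auc": m.roc_auc, "f1": m.f1})
    return pd.DataFrame(rows)


def _step_seconds(ds: WindowDataset) -> float:
    spec = ds.channel_specs[0]
    return ds.segments[spec.name].shape[2] / spec.sampling_rate


# --------------------------------------------------------------- attention

HIGH_THRESHOLD = 0.15   # category "high": weight strictly above
MEDIUM_THRESHOLD = 0.10  # "medium": in [0.10, 0.15] inclusive


def attention_category(weight: float) -> str:
    if weight > HIGH_THRESHOLD:
        return "high"
    if weight >= MEDIUM_THRESHOLD:
        return "medium"
    return "low"


@dataclass
class AttentionReport:
    alpha_table: pd.DataFrame  # window_id, channel, k, alpha, category
    beta_table: pd.DataFrame   # window_id, channel, beta, category


def export_attention(model: MVHAModel, ds: WindowDataset) -> AttentionReport:
    """Forward every window and tabulate α per segment and β per channel."""
    a_rows, b_rows = [], []
    for lo in range(0, ds.n, _EVAL_CHUNK):
        idx = np.arange(lo, min(lo + _EVAL_CHUNK, ds.n))
        fwd = model.forward(ds.batch(idx), training=False)
        for j, i in enumerate(idx):
            wid = ds.window_ids[i]
            for name, alpha in fwd.alpha.items():
                for k in range(alpha.shape[1]):
                    a_rows.append({"window_id": wid, "channel": name, "k": k + 1,
                                   "alpha": float(alpha[j, k]),
                                   "category": attention_category(float(alpha[j, k]))})
            if fwd.beta is not None:
                for c, name in enumerate(model.channel_names):
                    b_rows.append({"window_id": wid, "channel": name,
                                   "beta": float(fwd.beta[j, c]),
                                   "category": attention_category(float(fwd.beta[j, c]))})
    return AttentionReport(alpha_table=pd.DataFrame(a_rows),
                           beta_table=pd.DataFrame(b_rows))


def attention_recovery(model: MVHAModel, ds: WindowDataset) -> dict:
    """Check α localization and β channel ranking against synthetic ground truth.

    Over the positive windows of ``ds`` (which must carry truth), returns the
    fraction whose α-argmax (averaged over burst channels) falls inside the
    injected segment set, and whether the injected-trend channel attains the
    highest mean β.
    """
    if ds.truth is None:
        raise ValidationError("dataset carries no ground truth")
    hit = total = 0
    betas = []
    trend_channel = None
    for lo in range(0, ds.n, _EVAL_CHUNK):
        idx = np.arange(lo, min(lo + _EVAL_CHUNK, ds.n))
        fwd = model.forward(ds.batch(idx), training=False)
        for j, i in enumerate(idx):
            t = ds.truth[i]
            if t.label != 1:
                continue
            total += 1
            injected = {k - 1 for k in t.fluct_segments}
            votes = [int(np.argmax(fwd.alpha[name][j])) in injected
                     for name in fwd.alpha if name in t.fluct_channels]
            if votes and np.mean(votes) >= 0.5:
                hit += 1
            if fwd.beta is not None:
                betas.append(fwd.beta[j])
                trend_channel = t.trend_channel
    out = {"alpha_localization_rate": hit / total if total else float("nan")}
    if betas and trend_channel is not None:
        mean_beta = np.mean(betas, axis=0)
        ranking = [model.channel_names[i] for i in np.argsort(mean_beta)[::-1]]
        out["beta_top_channel"] = ranking[0]
        out["beta_trend_channel_is_top"] = ranking[0] == trend_channel
        out["mean_beta"] = {n: float(b) for n, b in
                            zip(model.channel_names, mean_beta)}
    return out
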