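"""Bidirectional-LSTM sequence classifier for whole-night sleep staging.

The network maps a night's feature sequence (epochs x 132) to per-epoch
posteriors over (W, R, N1N2, N3): a sigmoid projection to 32 units, a stack
of bidirectional LSTM layers (outputs of the two directions concatenated
between layers), a second 32-unit sigmoid layer and a 4-way softmax.  It is
trained with RMSprop on the soft-label categorical cross-entropy, i.e. the
targets are annotator fractions rather than one-hot labels.

The implementation is plain NumPy: forward pass, backpropagation through
time, inverted dropout (element-wise on inputs and LSTM outputs,
variational per-sequence masks on the recurrent connections) and masked
losses for padded batches.  Everything is driven by explicit seeded
generators, so training is reproducible on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Hypnogram, RecordingMeta, SoftLabelMatrix
from .registry import N_FEATURES

_GATES = 4  # input, forget, cell, output


@dataclass
class ModelConfig:
    input_dim: int = N_FEATURES
    pre_dense_units: int = 32
    n_lstm_layers: int = 3
    lstm_units_per_direction: int = 64
    post_dense_units: int = 32
    n_classes: int = 4
    dropout_input: float = 0.2
    dropout_output: float = 0.5
    dropout_recurrent: float = 0.5
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_lstm_layers <= 6:
            raise ValueError("n_lstm_layers must be in 1..6")
        if self.lstm_units_per_direction not in (16, 32, 64, 128):
            raise ValueError("lstm_units_per_direction must be one of 16/32/64/128")
        for rate in (self.dropout_input, self.dropout_output, self.dropout_recurrent):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")


@dataclass
class TrainConfig:
    k_folds: int = 4
    patience: int = 100
    max_passes: int = 300
    batch_nights: int = 8
    inner_val_fraction: float = 0.1
    seed: int = 0
    monitor_test_fold: bool = False  # early stopping monitored on the test fold
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    clip_norm: float = 5.0


@dataclass
class Night:
    """One recording: a feature sequence plus its soft labels."""

    recording_id: str
    participant_id: str
    features: np.ndarray          # (T, input_dim), NaN = missing
    soft_labels: np.ndarray       # (T, 4)
    meta: RecordingMeta | None = None

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.soft_labels.shape[0]:
            raise ValueError("features and labels must cover the same epochs")


# ---------------------------------------------------------------------------
# Parameters


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, orthogonal-free; forget-gate bias = 1."""
    params: dict[str, np.ndarray] = {}

    def glorot(shape: tuple[int, int]) -> np.ndarray:
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    u = config.lstm_units_per_direction
    params["dense_in.W"] = glorot((config.input_dim, config.pre_dense_units))
    params["dense_in.b"] = np.zeros(config.pre_dense_units)
    d_in = config.pre_dense_units
    for layer in range(config.n_lstm_layers):
        for dirn in ("fw", "bw"):
            p = f"lstm{layer}.{dirn}"
            params[f"{p}.Wx"] = glorot((d_in, _GATES * u))
            params[f"{p}.Wh"] = glorot((u, _GATES * u))
            b = np.zeros(_GATES * u)
            b[u:2 * u] = 1.0  # forget gate bias
            params[f"{p}.b"] = b
        d_in = 2 * u
    params["dense_post.W"] = glorot((d_in, config.post_dense_units))
    params["dense_post.b"] = np.zeros(config.post_dense_units)
    params["dense_out.W"] = glorot((config.post_dense_units, config.n_classes))
    params["dense_out.b"] = np.zeros(config.n_classes)
    return params


def count_parameters(config: ModelConfig) -> int:
    """Exact number of trainable weights and biases of the network."""
    rng = np.random.default_rng(0)
    return int(sum(p.size for p in _init_params(config, rng).values()))


# ---------------------------------------------------------------------------
# Losses


def soft_cross_entropy(labels: np.ndarray | SoftLabelMatrix,
                       preds: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Soft-label categorical cross-entropy, natural log, mean per epoch.

    H = -(1/N) sum_i sum_c P(Y_i = C_c) log Phat(Y_i = C_c); masked epochs
    are excluded from N.  Raises on non-positive predictions: clipping is
    the trainer's responsibility.
    """
    P = labels.fractions if isinstance(labels, SoftLabelMatrix) else np.asarray(labels, float)
    Q = np.asarray(preds, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("label and prediction shapes differ")
    if np.any(Q <= 0):
        raise ValueError("predicted probabilities must be strictly positive")
    contrib = -(P * np.log(Q)).sum(axis=-1)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.sum() == 0:
            raise ValueError("no unmasked epochs")
        return float(contrib[m].mean())
    return float(contrib.mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# The model


class LSTMStager:
    """A built network plus its standardization statistics."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params = _init_params(config, self.rng)
        self.impute_medians: np.ndarray | None = None
        self.scale_mean: np.ndarray | None = None
        self.scale_std: np.ndarray | None = None

    # -- standardization ----------------------------------------------------

    def fit_standardizer(self, feature_stack: np.ndarray) -> None:
        """Store per-feature medians (imputation) and z-scoring statistics
        from the training portion only."""
        med = np.nanmedian(feature_stack, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        filled = np.where(np.isnan(feature_stack), med, feature_stack)
        mean = filled.mean(axis=0)
        std = filled.std(axis=0)
        std = np.where(std > 1e-12, std, 1.0)
        self.impute_medians, self.scale_mean, self.scale_std = med, mean, std

    def standardize(self, features: np.ndarray) -> np.ndarray:
        if self.impute_medians is None:
            raise RuntimeError("standardizer not fitted")
        if features.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim} feature columns, "
                f"got {features.shape[-1]}")
        x = np.where(np.isnan(features), self.impute_medians, features)
        return (x - self.scale_mean) / self.scale_std

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, mask: np.ndarray, *, training: bool,
                 rng: np.random.Generator | None = None):
        """Forward pass on a padded batch.

        X: (B, T, F); mask: (B, T) with 1 for real epochs.  Returns the
        posterior array (B, T, 4) and, when training, the cache needed for
        backpropagation.
        """
        cfg = self.config
        P = self.params
        B, T, _ = X.shape
        u = cfg.lstm_units_per_direction
        cache: dict = {"X": X, "mask": mask}

        if training and cfg.dropout_input > 0:
            keep = 1.0 - cfg.dropout_input
            dmask = (rng.random(X.shape) < keep) / keep
            X = X * dmask
            cache["in_drop"] = dmask
        cache["X_drop"] = X

        a1 = X @ P["dense_in.W"] + P["dense_in.b"]
        h1 = _sigmoid(a1)
        cache["h1"] = h1

        inp = h1
        cache["layers"] = []
        for layer in range(cfg.n_lstm_layers):
            lcache: dict = {"input": inp}
            outs = []
            for dirn in ("fw", "bw"):
                p = f"lstm{layer}.{dirn}"
                Wx, Wh, b = P[f"{p}.Wx"], P[f"{p}.Wh"], P[f"{p}.b"]
                if training and cfg.dropout_recurrent > 0:
                    keep = 1.0 - cfg.dropout_recurrent
                    rmask = (rng.random((B, u)) < keep) / keep
                else:
                    rmask = np.ones((B, u))
                order = range(T) if dirn == "fw" else range(T - 1, -1, -1)
                h = np.zeros((B, u))
                c = np.zeros((B, u))
                gates_i = np.zeros((B, T, u)); gates_f = np.zeros((B, T, u))
                gates_g = np.zeros((B, T, u)); gates_o = np.zeros((B, T, u))
                cs = np.zeros((B, T, u)); hs = np.zeros((B, T, u))
                xz = inp @ Wx + b  # (B, T, 4u), precomputed input drive
                for t in order:
                    z = xz[:, t] + (h * rmask) @ Wh
                    i = _sigmoid(z[:, :u]); f = _sigmoid(z[:, u:2 * u])
                    g = np.tanh(z[:, 2 * u:3 * u]); o = _sigmoid(z[:, 3 * u:])
                    c_new = f * c + i * g
                    h_new = o * np.tanh(c_new)
                    m = mask[:, t][:, None]
                    c = m * c_new + (1 - m) * c
                    h = m * h_new + (1 - m) * h
                    gates_i[:, t] = i; gates_f[:, t] = f
                    gates_g[:, t] = g; gates_o[:, t] = o
                    cs[:, t] = c; hs[:, t] = h
                lcache[dirn] = {"i": gates_i, "f": gates_f, "g": gates_g,
                                "o": gates_o, "c": cs, "h": hs, "rmask": rmask}
                outs.append(hs)
            out = np.concatenate(outs, axis=-1)
            if training and cfg.dropout_output > 0:
                keep = 1.0 - cfg.dropout_output
                dmask = (rng.random(out.shape) < keep) / keep
                out = out * dmask
                lcache["out_drop"] = dmask
            lcache["output"] = out
            cache["layers"].append(lcache)
            inp = out

        a2 = inp @ P["dense_post.W"] + P["dense_post.b"]
        h2 = _sigmoid(a2)
        cache["h2"] = h2
        logits = h2 @ P["dense_out.W"] + P["dense_out.b"]
        post = _softmax(logits)
        cache["post"] = post
        return post, cache

    # -- backward -----------------------------------------------------------

    def _backward(self, cache: dict, soft_labels: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the masked soft cross-entropy w.r.t. every parameter."""
        cfg = self.config
        P = self.params
        mask = cache["mask"]
        B, T, _ = cache["X"].shape
        u = cfg.lstm_units_per_direction
        n_valid = max(mask.sum(), 1.0)
        grads = {k: np.zeros_like(v) for k, v in P.items()}

        # softmax + CE
        dlogits = (cache["post"] - soft_labels) * mask[..., None] / n_valid
        h2 = cache["h2"]
        grads["dense_out.W"] = np.tensordot(h2, dlogits, axes=([0, 1], [0, 1]))
        grads["dense_out.b"] = dlogits.sum(axis=(0, 1))
        dh2 = dlogits @ P["dense_out.W"].T
        da2 = dh2 * h2 * (1 - h2)
        last_out = cache["layers"][-1]["output"]
        grads["dense_post.W"] = np.tensordot(last_out, da2, axes=([0, 1], [0, 1]))
        grads["dense_post.b"] = da2.sum(axis=(0, 1))
        dout = da2 @ P["dense_post.W"].T

        for layer in range(cfg.n_lstm_layers - 1, -1, -1):
            lc = cache["layers"][layer]
            if "out_drop" in lc:
                dout = dout * lc["out_drop"]
            d_fw = dout[..., :u]
            d_bw = dout[..., u:]
            dinp = np.zeros_like(lc["input"])
            for dirn, dh_seq in (("fw", d_fw), ("bw", d_bw)):
                p = f"lstm{layer}.{dirn}"
                Wx, Wh = P[f"{p}.Wx"], P[f"{p}.Wh"]
                g = lc[dirn]
                rmask = g["rmask"]
                order = range(T) if dirn == "fw" else range(T - 1, -1, -1)
                idx = list(order)
                dh_next = np.zeros((B, u))
                dc_next = np.zeros((B, u))
                gWx = grads[f"{p}.Wx"]; gWh = grads[f"{p}.Wh"]; gb = grads[f"{p}.b"]
                inp = lc["input"]
                for step in range(T - 1, -1, -1):
                    t = idx[step]
                    t_prev = idx[step - 1] if step > 0 else None
                    m = mask[:, t][:, None]
                    i = g["i"][:, t]; f = g["f"][:, t]
                    gg = g["g"][:, t]; o = g["o"][:, t]
                    c = g["c"][:, t]
                    c_prev = g["c"][:, t_prev] if t_prev is not None else np.zeros((B, u))
                    h_prev = g["h"][:, t_prev] if t_prev is not None else np.zeros((B, u))
                    dh = dh_next + dh_seq[:, t]
                    tanh_c = np.tanh(c)
                    # mask gating: for padded steps state passed through
                    dh_eff = dh * m
                    dc = dc_next * m + dh_eff * o * (1 - tanh_c ** 2)
                    do = dh_eff * tanh_c
                    di = dc * gg
                    df = dc * c_prev
                    dg = dc * i
                    dz = np.concatenate([
                        di * i * (1 - i), df * f * (1 - f),
                        dg * (1 - gg ** 2), do * o * (1 - o)], axis=1)
                    x_t = inp[:, t]
                    gWx += x_t.T @ dz
                    gWh += (h_prev * rmask).T @ dz
                    gb += dz.sum(axis=0)
                    dinp[:, t] += dz @ Wx.T
                    dh_next = (dz @ Wh.T) * rmask + dh * (1 - m)
                    dc_next = dc * f + dc_next * (1 - m)
            dout = dinp

        # first dense + input dropout
        h1 = cache["h1"]
        da1 = dout * h1 * (1 - h1)
        Xd = cache["X_drop"]
        grads["dense_in.W"] = np.tensordot(Xd, da1, axes=([0, 1], [0, 1]))
        grads["dense_in.b"] = da1.sum(axis=(0, 1))
        return grads

    # -- inference ----------------------------------------------------------

    def predict_posteriors(self, features: np.ndarray) -> np.ndarray:
        """Per-epoch class posteriors for one night (features raw, with NaN)."""
        x = self.standardize(features)[None, ...]
        mask = np.ones((1, x.shape[1]))
        post, _ = self._forward(x, mask, training=False)
        return post[0]

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, Hypnogram]:
        post = self.predict_posteriors(features)
        return post, Hypnogram.from_indices(np.argmax(post, axis=1))

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.config), "format_version": 1}
        arrays = dict(self.params)
        arrays["_impute_medians"] = self.impute_medians
        arrays["_scale_mean"] = self.scale_mean
        arrays["_scale_std"] = self.scale_std
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LSTMStager":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        model = cls(ModelConfig(**meta["config"]))
        for k in model.params:
            model.params[k] = data[k]
        model.impute_medians = data["_impute_medians"]
        model.scale_mean = data["_scale_mean"]
        model.scale_std = data["_scale_std"]
        return model


# ---------------------------------------------------------------------------
# Fold assignment


def assign_folds(metas: Sequence[RecordingMeta], k: int, seed: int) -> dict[str, int]:
    """Participant-level fold map: shuffle participants, deal round-robin.

    All recordings of a participant share a fold; recordings never split.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    participants = sorted({m.participant_id for m in metas})
    if len(participants) < k:
        raise ValueError(f"{len(participants)} participants < {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    return {participants[j]: int(pos % k) for pos, j in enumerate(order)}


# ---------------------------------------------------------------------------
# Training


def _batch(nights: Sequence[Night], model: LSTMStager) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    T = max(n.features.shape[0] for n in nights)
    B = len(nights)
    X = np.zeros((B, T, model.config.input_dim))
    Y = np.zeros((B, T, 4))
    mask = np.zeros((B, T))
    for b, night in enumerate(nights):
        L = night.features.shape[0]
        X[b, :L] = model.standardize(night.features)
        Y[b, :L] = night.soft_labels
        mask[b, :L] = 1.0
    return X, Y, mask


def _dataset_loss(model: LSTMStager, nights: Sequence[Night]) -> float:
    """Mean per-epoch loss over a set of nights, dropout disabled."""
    total, count = 0.0, 0
    for night in nights:
        post = model.predict_posteriors(night.features)
        post = np.clip(post, 1e-7, 1 - 1e-7)
        total += -(night.soft_labels * np.log(post)).sum()
        count += night.features.shape[0]
    return total / max(count, 1)


def prior_baseline_loss(nights: Sequence[Night]) -> float:
    """Loss of the trivial predictor that always emits the pooled label
    fractions of the given nights (the class-prior posterior)."""
    Y = np.concatenate([n.soft_labels for n in nights], axis=0)
    prior = np.clip(Y.mean(axis=0), 1e-12, 1.0)
    prior = prior / prior.sum()
    return float(-(Y * np.log(prior)).sum(axis=1).mean())


def train(train_nights: Sequence[Night], mconfig: ModelConfig, tconfig: TrainConfig,
          monitor_nights: Sequence[Night] | None = None,
          ) -> tuple[LSTMStager, "list[dict]"]:
    """Fit the network with RMSprop + early stopping.

    By default early stopping is monitored on an inner validation split of
    the training participants.  When ``tconfig.monitor_test_fold`` is set and
    ``monitor_nights`` is given, those nights (the test fold) are monitored
    instead.
    """
    if not train_nights:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tconfig.seed)

    if tconfig.monitor_test_fold and monitor_nights is not None:
        fit_nights = list(train_nights)
        val_nights = list(monitor_nights)
    else:
        participants = sorted({n.participant_id for n in train_nights})
        n_val = max(1, int(round(tconfig.inner_val_fraction * len(participants))))
        val_p = set(p for p in
                    np.array(participants)[rng.permutation(len(participants))][:n_val])
        fit_nights = [n for n in train_nights if n.participant_id not in val_p]
        val_nights = [n for n in train_nights if n.participant_id in val_p]
        if not fit_nights:  # degenerate tiny cohorts: fall back to no split
            fit_nights, val_nights = list(train_nights), list(train_nights)

    model = LSTMStager(mconfig)
    model.fit_standardizer(np.concatenate([n.features for n in fit_nights], axis=0))

    rms: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in model.params.items()}
    history: list[dict] = []
    best_loss = np.inf
    best_pass = -1
    best_params = {k: v.copy() for k, v in model.params.items()}
    lr = mconfig.learning_rate

    for pass_i in range(tconfig.max_passes):
        order = rng.permutation(len(fit_nights))
        train_loss_acc, train_epochs = 0.0, 0
        for start in range(0, len(order), tconfig.batch_nights):
            batch = [fit_nights[j] for j in order[start:start + tconfig.batch_nights]]
            X, Y, mask = _batch(batch, model)
            post, cache = model._forward(X, mask, training=True, rng=rng)
            post_c = np.clip(post, 1e-7, 1 - 1e-7)
            cache["post"] = post_c
            loss = soft_cross_entropy(
                Y.reshape(-1, 4), post_c.reshape(-1, 4), mask.reshape(-1))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            grads = model._backward(cache, Y)
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if tconfig.clip_norm and gnorm > tconfig.clip_norm:
                scale = tconfig.clip_norm / gnorm
                for g in grads.values():
                    g *= scale
            for k, g in grads.items():
                rms[k] = tconfig.rmsprop_rho * rms[k] + (1 - tconfig.rmsprop_rho) * g * g
                model.params[k] -= lr * g / (np.sqrt(rms[k]) + tconfig.rmsprop_eps)
            n_ep = int(mask.sum())
            train_loss_acc += loss * n_ep
            train_epochs += n_ep
        val_loss = _dataset_loss(model, val_nights)
        history.append({"pass": pass_i,
                        "train_loss": train_loss_acc / max(train_epochs, 1),
                        "val_loss": val_loss})
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_pass = pass_i
            best_params = {k: v.copy() for k, v in model.params.items()}
        elif pass_i - best_pass >= tconfig.patience:
            break
    model.params = best_params
    return model, history


def cross_validate(nights: Sequence[Night], mconfig: ModelConfig, tconfig: TrainConfig,
                   ) -> tuple[dict[str, tuple[np.ndarray, Hypnogram]], list[LSTMStager]]:
    """Participant-level k-fold cross-validation.

    Every night is predicted exactly once, by the model whose training folds
    never contained its participant; standardization statistics come from
    each fold's training portion only.
    """
    metas = [n.meta or RecordingMeta(n.recording_id, n.participant_id)
             for n in nights]
    folds = assign_folds(metas, tconfig.k_folds, tconfig.seed)
    predictions: dict[str, tuple[np.ndarray, Hypnogram]] = {}
    models: list[LSTMStager] = []
    for fold in range(tconfig.k_folds):
        test = [n for n in nights if folds[n.participant_id] == fold]
        tr = [n for n in nights if folds[n.participant_id] != fold]
        model, _ = train(tr, mconfig, tconfig, monitor_nights=test)
        models.append(model)
        for night in test:
            predictions[night.recording_id] = model.predict(night.features)
    return predictions, models
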