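from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..metrics import binary_report
from ..nn import Adam, BiLSTM, Conv1d, Dense, Module, Tensor, bce_with_logits

# channel order: A C G U pad
_CHANNELS = {c: i for i, c in enumerate("ACGU")}
_PAD = 4


def one_hot_sequence(seq: str) -> np.ndarray:
    """(n, 5) one-hot encoding (pad channel unused inside sequences)."""
    out = np.zeros((len(seq), 5))
    for i, c in enumerate(seq):
        out[i, _CHANNELS[c]] = 1.0
    return out


def encode_windows(seq: str, w: int) -> np.ndarray:
    """(n, w, 5) sliding windows, symmetric padding with the pad symbol."""
    if w % 2 != 1:
        raise ValueError("window size must be odd")
    n = len(seq)
    half = w // 2
    padded = np.zeros((n + 2 * half, 5))
    padded[:, _PAD] = 1.0
    padded[half : half + n] = one_hot_sequence(seq)
    return np.lib.stride_tricks.sliding_window_view(
        padded, w, axis=0
    ).transpose(0, 2, 1).copy()


@dataclass(frozen=True)
class PairednessModelSpec:
    """Architecture selector for the paired/unpaired task."""

    family: str  # FFN | CNN | BLSTM
    window: int = 15  # FFN/CNN only
    layers: int = 1  # BLSTM only
    hidden: int = 40  # BLSTM units / FFN,CNN hidden width

    def __post_init__(self):
        if self.family not in ("FFN", "CNN", "BLSTM"):
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class TrainingProtocol:
    """Training configuration; model selection by max validation MCC."""

    max_epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    select_by: str = "mcc"
    pos_weight: float = 1.0


class _WindowModel(Module):
    """Shared driver for window-based models (FFN / CNN)."""

    window: int

    def predict_sequences(self, seqs) -> list[np.ndarray]:
        out = []
        for s in seqs:
            wins = encode_windows(s, self.window)
            probs = self.forward(Tensor(wins)).sigmoid().data.ravel()
            out.append(probs)
        return out

    def batch_logits(self, seqs):
        wins = np.concatenate([encode_windows(s, self.window) for s in seqs])
        return self.forward(Tensor(wins))


class FFNPairedness(_WindowModel):
    def __init__(self, spec: PairednessModelSpec, rng):
        self.window = spec.window
        h = spec.hidden
        self.fc1 = Dense(spec.window * 5, h, rng)
        self.fc2 = Dense(h, h, rng)
        self.out = Dense(h, 1, rng)

    def forward(self, wins: Tensor) -> Tensor:
        B = wins.data.shape[0]
        x = wins.reshape(B, -1)
        return self.out(self.fc2(self.fc1(x).relu()).relu())


class CNNPairedness(_WindowModel):
    def __init__(self, spec: PairednessModelSpec, rng):
        self.window = spec.window
        c = max(8, spec.hidden // 4)
        self.conv1 = Conv1d(5, c, 5, rng)
        self.conv2 = Conv1d(c, c, 5, rng)
        self.out = Dense(c * spec.window, 1, rng)
        self._c = c

    def forward(self, wins: Tensor) -> Tensor:
        B, w, _ = wins.data.shape
        x = wins.transpose(0, 2, 1)  # (B, 5, w)
        x = self.conv2(self.conv1(x).relu()).relu()
        return self.out(x.reshape(B, -1))


class BLSTMPairedness(Module):
    def __init__(self, spec: PairednessModelSpec, rng):
        h = spec.hidden
        self.stack = []
        n_in = 5
        for _ in range(spec.layers):
            self.stack.append(BiLSTM(n_in, h, rng))
            n_in = 2 * h
        self.out = Dense(2 * h, 1, rng)

    def forward(self, x: Tensor) -> Tensor:  # (T, B, 5)
        for layer in self.stack:
            x = layer(x)
        return self.out(x)

    def predict_sequences(self, seqs) -> list[np.ndarray]:
        out = []
        for group, idx in _group_by_length(seqs):
            x = np.stack([one_hot_sequence(s) for s in group], axis=1)
            probs = self.forward(Tensor(x)).sigmoid().data[:, :, 0]
            for k, i in enumerate(idx):
                out.append((i, probs[:, k]))
        return [p for _, p in sorted(out, key=lambda t: t[0])]

    def batch_logits(self, seqs):
        # caller guarantees equal lengths within a batch
        x = np.stack([one_hot_sequence(s) for s in seqs], axis=1)
        return self.forward(Tensor(x))


def _group_by_length(seqs):
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(len(s), []).append(i)
    for n, idx in sorted(groups.items()):
        yield [seqs[i] for i in idx], idx


def build_pairedness_model(spec: PairednessModelSpec, seed: int = 0):
    rng = np.random.default_rng(seed)
    cls = {
        "FFN": FFNPairedness,
        "CNN": CNNPairedness,
        "BLSTM": BLSTMPairedness,
    }[spec.family]
    model = cls(spec, rng)
    model.spec = spec
    return model


def _labels(bundle) -> list[np.ndarray]:
    return [
        (pt.partner != -1).astype(float) for _, pt in bundle
    ]


def train_pairedness(model, train, val, protocol: TrainingProtocol):
    """Fit with per-epoch validation trace and best-MCC model selection.

    Returns (model restored to its best epoch, trace) where trace is a list
    of dicts with keys epoch/accuracy/f1/loss/mcc.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty dataset bundle")
    rng = np.random.default_rng(protocol.seed)
    opt = Adam(model.parameters(), lr=protocol.lr)
    train_seqs = list(train.sequences)
    train_labels = _labels(train)
    val_labels = _labels(val)
    is_blstm = isinstance(model, BLSTMPairedness)
    trace = []
    best = (-np.inf, None, -1)
    for epoch in range(1, protocol.max_epochs + 1):
        order = rng.permutation(len(train_seqs))
        if is_blstm:  # keep equal lengths within a batch
            order = sorted(order, key=lambda i: len(train_seqs[i]))
        for k in range(0, len(order), protocol.batch_size):
            idx = list(order[k : k + protocol.batch_size])
            if is_blstm and len({len(train_seqs[i]) for i in idx}) > 1:
                idx = [i for i in idx
                       if len(train_seqs[i]) == len(train_seqs[idx[0]])]
            seqs = [train_seqs[i] for i in idx]
            y = np.concatenate([train_labels[i] for i in idx])
            logits = model.batch_logits(seqs)
            if is_blstm:
                y = np.stack([train_labels[i] for i in idx], axis=1)[..., None]
            loss = bce_with_logits(
                logits, y if is_blstm else y.reshape(-1, 1)
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
        probs = predict_pairedness(model, val.sequences)
        rep = binary_report(
            np.concatenate(probs), np.concatenate(val_labels)
        )
        trace.append(
            {
                "epoch": epoch,
                "accuracy": rep.accuracy,
                "f1": rep.f1,
                "loss": rep.loss,
                "mcc": rep.mcc,
            }
        )
        if rep.mcc > best[0]:
            best = (rep.mcc, model.state_dict(), epoch)
    if best[1] is not None:
        model.load_state_dict(best[1])
        model.selected_epoch = best[2]
    return model, trace


def predict_pairedness(model, seqs) -> list[np.ndarray]:
    """Per-position paired probabilities for each sequence."""
    return model.predict_sequences(list(seqs))
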