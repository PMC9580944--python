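from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..metrics import binary_report
from ..nn import Adam, Conv2d, Dense, LSTM, Module, Tensor, bce_with_logits, concat
from ..pairedness.models import TrainingProtocol, one_hot_sequence
from ..structures import pairtable_to_matrix


def encode_pair_input(seq: str) -> np.ndarray:
    """(8, n, n) tensor: entry (i, j) = one-hot(res i) ++ one-hot(res j)."""
    oh = one_hot_sequence(seq)[:, :4]  # (n, 4)
    n = len(seq)
    rows = np.broadcast_to(oh[:, None, :], (n, n, 4))
    cols = np.broadcast_to(oh[None, :, :], (n, n, 4))
    return np.concatenate([rows, cols], axis=2).transpose(2, 0, 1).copy()


@dataclass(frozen=True)
class MatrixModelSpec:
    """Variant selector; only variant 3 contains the recurrent block."""

    variant: int = 0
    channels: int = 12
    n_blocks: int = 2
    lstm_hidden: int = 8

    def __post_init__(self):
        if self.variant not in (0, 1, 3):
            raise ValueError("variant must be 0, 1 or 3")


class _ResBlock(Module):
    def __init__(self, c, rng):
        self.c1 = Conv2d(c, c, 3, rng)
        self.c2 = Conv2d(c, c, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x).relu()) + x


class _RowColBiLSTM(Module):
    """Recurrent block: bidirectional LSTMs along rows and columns."""

    def __init__(self, c, hidden, rng):
        self.row_f = LSTM(c, hidden, rng)
        self.row_b = LSTM(c, hidden, rng, reverse=True)
        self.col_f = LSTM(c, hidden, rng)
        self.col_b = LSTM(c, hidden, rng, reverse=True)
        self.mix = Conv2d(4 * hidden, c, 1, rng)

    def forward(self, x):  # (B, C, n, n)
        B, C, n, _ = x.data.shape
        rows = x.transpose(3, 0, 2, 1).reshape(n, B * n, C)
        cols = x.transpose(2, 0, 3, 1).reshape(n, B * n, C)
        rf = self.row_f(rows)
        rb = self.row_b(rows)
        cf = self.col_f(cols)
        cb = self.col_b(cols)
        H = rf.data.shape[2]
        row_feat = concat([rf, rb], axis=2).reshape(n, B, n, 2 * H)
        col_feat = concat([cf, cb], axis=2).reshape(n, B, n, 2 * H)
        feats = concat(
            [row_feat.transpose(1, 3, 2, 0), col_feat.transpose(1, 3, 0, 2)],
            axis=1,
        )
        return self.mix(feats).relu()


class MatrixModel(Module):
    def __init__(self, spec: MatrixModelSpec, rng):
        c = spec.channels
        self.stem = Conv2d(8, c, 3, rng)
        self.blocks = [_ResBlock(c, rng) for _ in range(spec.n_blocks)]
        self.fc = Conv2d(c, c, 1, rng) if spec.variant in (1, 3) else None
        self.rec = (
            _RowColBiLSTM(c, spec.lstm_hidden, rng) if spec.variant == 3 else None
        )
        self.head = Conv2d(c, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:  # (B, 8, n, n) -> (B, 1, n, n)
        h = self.stem(x).relu()
        for blk in self.blocks:
            h = blk(h).relu()
        if self.rec is not None:
            h = h + self.rec(h)
        if self.fc is not None:
            h = self.fc(h).relu()
        return self.head(h)


def build_matrix_model(spec: MatrixModelSpec, seed: int = 0) -> MatrixModel:
    model = MatrixModel(spec, np.random.default_rng(seed))
    model.spec = spec
    return model


def predict_matrix(model: MatrixModel, seq: str) -> np.ndarray:
    """Raw n x n pairing scores in [0, 1] (no postprocessing)."""
    x = Tensor(encode_pair_input(seq)[None])
    return model.forward(x).sigmoid().data[0, 0]


def count_predicted_pairs(
    m: np.ndarray, threshold: float = 0.5, full_matrix: bool = False
) -> int:
    """Entries strictly above threshold (upper triangle by default)."""
    m = np.asarray(m)
    if full_matrix:
        return int(np.sum(m > threshold))
    iu = np.triu_indices(m.shape[0], k=1)
    return int(np.sum(m[iu] > threshold))


def _val_mcc(model, val, max_eval: int | None = None) -> float:
    preds, truths = [], []
    items = list(val)[:max_eval] if max_eval else list(val)
    for seq, pt in items:
        preds.append(predict_matrix(model, seq))
        truths.append(pairtable_to_matrix(pt))
    iu_cache = {}
    ps, ts = [], []
    for p, t in zip(preds, truths):
        n = p.shape[0]
        iu = iu_cache.setdefault(n, np.triu_indices(n, k=1))
        ps.append(p[iu])
        ts.append(t[iu])
    return binary_report(
        np.concatenate(ps), np.concatenate(ts), granularity="per-entry"
    )


def train_matrix_model(
    model: MatrixModel,
    train,
    val,
    protocol: TrainingProtocol,
    init_state=None,
    max_val_eval: int | None = None,
):
    """Per-entry BCE training with best-epoch selection by validation MCC.

    ``init_state`` may hold a pre-trained checkpoint (``model.state_dict()``
    output) to start from.  Batches bucket sequences of equal length.
    Returns (model at its best epoch, trace of per-epoch dicts).
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty dataset bundle")
    if init_state is not None:
        model.load_state_dict(init_state)
    rng = np.random.default_rng(protocol.seed)
    opt = Adam(model.parameters(), lr=protocol.lr)
    items = list(train)
    for seq, pt in items:
        if len(seq) != pt.n:
            raise ValueError("sequence/matrix size mismatch")
    trace = []
    best = (-np.inf, None, -1)
    for epoch in range(1, protocol.max_epochs + 1):
        order = rng.permutation(len(items))
        order = sorted(order, key=lambda i: len(items[i][0]))
        epoch_loss, n_batches = 0.0, 0
        k = 0
        while k < len(order):
            n0 = len(items[order[k]][0])
            idx = []
            while (
                k < len(order)
                and len(items[order[k]][0]) == n0
                and len(idx) < protocol.batch_size
            ):
                idx.append(order[k])
                k += 1
            x = np.stack([encode_pair_input(items[i][0]) for i in idx])
            y = np.stack(
                [pairtable_to_matrix(items[i][1])[None] for i in idx]
            )
            logits = model.forward(Tensor(x))
            loss = bce_with_logits(logits, y, pos_weight=protocol.pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.data.item()
            n_batches += 1
        rep = _val_mcc(model, val, max_val_eval)
        trace.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(1, n_batches),
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
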