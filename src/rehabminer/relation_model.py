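"""BiGRU + attention-pooling + softmax relation classifier.

The classifier reads an ``L x D`` token-feature matrix, runs forward and
backward GRU layers (``u`` hidden units each), concatenates their per-token
outputs into ``H in R^(L x 2u)``, pools H into a single sentence vector with
a learned attention distribution

    M = tanh(H),    alpha = softmax(omega^T M),    c = sum_t alpha_t H_t,

and classifies c through a fully connected layer with softmax.  Attention
lets the model up-weight the (usually short) relation-bearing clause and
down-weight the surrounding noise typical of consultation text.

The network and its gradients are implemented directly in NumPy:
backpropagation-through-time for both GRU directions, the attention
softmax, inverted dropout on H, and the cross-entropy head, optimised with
mini-batch Adam (or plain SGD).  Gradients are verified against central
finite differences in the test suite.

Default hyperparameters: batch 16, 40 epochs, learning rate 5e-4, 32 hidden
units per direction, dropout 0.2 on H.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .corpus_io import RELATION_LABELS, QARecord, candidate_pairs, make_marked_instance
from .encoder import EncodedInstance, LookupBackend
from .knowledge_base import RelationTriple

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ClassScores",
    "RelationModel",
    "bigru_forward",
    "attention_pool",
    "classify",
    "predict_triples",
]

_NEG = -1e9  # additive mask value before softmax


@dataclass(frozen=True)
class ModelConfig:
    hidden_units: int = 32
    labels: tuple[str, ...] = RELATION_LABELS
    dropout: float = 0.2
    learning_rate: float = 5e-4
    batch_size: int = 16
    epochs: int = 40
    optimizer: str = "adam"       # or "sgd" (plain mini-batch gradient descent)
    pooling: str = "attention"    # or "mean" (ablation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.labels) < 2:
            raise ValueError("need at least two labels")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.pooling not in ("attention", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


@dataclass
class ClassScores:
    logits: np.ndarray
    probs: np.ndarray
    predicted: str


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# GRU (one direction)


def _gru_forward(X, mask, Wx, Wh, bx, bh):
    """Run a GRU left-to-right over (B, L, D) inputs.

    Padded steps (mask False) emit zero rows and carry the hidden state
    through unchanged, so trailing padding never affects the features and
    leading padding (reversed sequences) leaves the state at zero.
    """
    B, L, _ = X.shape
    u = Wh.shape[0]
    h = np.zeros((B, u))
    out = np.zeros((B, L, u))
    Gx = X @ Wx + bx
    cache = []
    for t in range(L):
        m = mask[:, t, None].astype(float)
        gh = h @ Wh + bh
        r = _sigmoid(Gx[:, t, :u] + gh[:, :u])
        z = _sigmoid(Gx[:, t, u : 2 * u] + gh[:, u : 2 * u])
        ghn = gh[:, 2 * u :]
        n = np.tanh(Gx[:, t, 2 * u :] + r * ghn)
        h_new = (1.0 - z) * n + z * h
        out[:, t] = (m * h_new)
        cache.append((h, r, z, n, ghn, m))
        h = m * h_new + (1.0 - m) * h
    return out, cache


def _gru_backward(dOut, X, mask, cache, Wx, Wh, need_dX):
    B, L, _ = X.shape
    u = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    dbx = np.zeros(3 * u)
    dbh = np.zeros(3 * u)
    dGx = np.zeros((B, L, 3 * u)) if need_dX else None
    dh = np.zeros((B, u))
    for t in reversed(range(L)):
        h_prev, r, z, n, ghn, m = cache[t]
        dh_new = m * (dh + dOut[:, t])
        dh_prev = (1.0 - m) * dh
        dz = dh_new * (h_prev - n)
        dn = dh_new * (1.0 - z)
        dh_prev = dh_prev + dh_new * z
        dn_pre = dn * (1.0 - n * n)
        dr = dn_pre * ghn
        dr_pre = dr * r * (1.0 - r)
        dz_pre = dz * z * (1.0 - z)
        dgx = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
        dgh = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
        dWh += h_prev.T @ dgh
        dbh += dgh.sum(axis=0)
        dh_prev = dh_prev + dgh @ Wh.T
        dWx += X[:, t].T @ dgx
        dbx += dgx.sum(axis=0)
        if need_dX:
            dGx[:, t] = dgx
        dh = dh_prev
    dX = dGx @ Wx.T if need_dX else None
    return {"Wx": dWx, "Wh": dWh, "bx": dbx, "bh": dbh}, dX


# ---------------------------------------------------------------------------
# attention pooling


def _attention_forward(H, omega, mask):
    if not mask.any(axis=1).all():
        raise ValueError("attention over an all-masked instance is undefined")
    M = np.tanh(H)
    scores = M @ omega
    scores = np.where(mask, scores, _NEG)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores) * mask
    alpha = e / e.sum(axis=1, keepdims=True)
    c = np.einsum("bl,blh->bh", alpha, H)
    return alpha, c, M


def _attention_backward(dc, H, M, alpha, omega):
    dH = alpha[:, :, None] * dc[:, None, :]
    dalpha = np.einsum("bh,blh->bl", dc, H)
    ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    domega = np.einsum("bl,blh->h", ds, M)
    dH = dH + ds[:, :, None] * omega[None, None, :] * (1.0 - M * M)
    return dH, domega


def _mean_pool_forward(H, mask):
    counts = mask.sum(axis=1, keepdims=True).astype(float)
    if (counts == 0).any():
        raise ValueError("mean pooling over an all-masked instance is undefined")
    alpha = mask.astype(float) / counts
    return alpha, np.einsum("bl,blh->bh", alpha, H)


# ---------------------------------------------------------------------------
# public single-instance operations


def bigru_forward(enc: EncodedInstance, params: dict) -> np.ndarray:
    """Concatenated bidirectional GRU features H of shape (L, 2u)."""
    X = enc.matrix[None]
    mask = enc.mask[None]
    H = _bigru_batch(X, mask, params)[0]
    return H[0]


def _bigru_batch(X, mask, params):
    out_f, cache_f = _gru_forward(
        X, mask, params["f_Wx"], params["f_Wh"], params["f_bx"], params["f_bh"]
    )
    Xr, maskr = X[:, ::-1], mask[:, ::-1]
    out_b_r, cache_b = _gru_forward(
        Xr, maskr, params["b_Wx"], params["b_Wh"], params["b_bx"], params["b_bh"]
    )
    H = np.concatenate([out_f, out_b_r[:, ::-1]], axis=2)
    return H, (cache_f, cache_b, Xr, maskr)


def attention_pool(H: np.ndarray, omega: np.ndarray, mask: np.ndarray):
    """Pool (L, 2u) features into (alpha, c) with masked softmax weights."""
    alpha, c, _ = _attention_forward(H[None], omega, mask[None])
    return alpha[0], c[0]


def classify(c: np.ndarray, W: np.ndarray, b: np.ndarray,
             labels: tuple[str, ...] = RELATION_LABELS) -> ClassScores:
    """Fully connected layer + softmax; argmax ties go to the lowest index."""
    with np.errstate(invalid="ignore"):
        logits = c @ W + b
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite logits")
    shifted = logits - logits.max()
    probs = np.exp(shifted) / np.exp(shifted).sum()
    return ClassScores(logits=logits, probs=probs, predicted=labels[int(np.argmax(probs))])


# ---------------------------------------------------------------------------
# the trainable model


class RelationModel:
    """The classifier with its parameters and training loop."""

    def __init__(self, config: ModelConfig, D: int, seed: int | None = None):
        self.config = config
        self.D = D
        rng = np.random.default_rng(config.seed if seed is None else seed)
        u = config.hidden_units
        k = len(config.labels)

        def glorot(shape):
            bound = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-bound, bound, size=shape)

        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):
            self.params[f"{d}_Wx"] = glorot((D, 3 * u))
            self.params[f"{d}_Wh"] = glorot((u, 3 * u))
            self.params[f"{d}_bx"] = np.zeros(3 * u)
            self.params[f"{d}_bh"] = np.zeros(3 * u)
        self.params["omega"] = glorot((2 * u,))
        self.params["W"] = glorot((2 * u, k))
        self.params["b"] = np.zeros(k)
        self.embedding_table: np.ndarray | None = None  # best checkpoint copy
        self.trace: list[dict] = []

    # -- forward / backward over a batch ------------------------------------

    def _forward(self, X, mask, train=False, drop_mask=None):
        H, caches = _bigru_batch(X, mask, self.params)
        if train and drop_mask is not None:
            Hd = H * drop_mask
        else:
            Hd = H
        if self.config.pooling == "attention":
            alpha, c, M = _attention_forward(Hd, self.params["omega"], mask)
        else:
            alpha, c = _mean_pool_forward(Hd, mask)
            M = None
        logits = c @ self.params["W"] + self.params["b"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (X, mask, caches, Hd, M, alpha, c, drop_mask)

    def _backward(self, probs, y_idx, ctx, need_dX=False):
        X, mask, (cache_f, cache_b, Xr, maskr), Hd, M, alpha, c, drop_mask = ctx
        B = X.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B
        grads = {
            "W": c.T @ dlogits,
            "b": dlogits.sum(axis=0),
        }
        dc = dlogits @ self.params["W"].T
        if self.config.pooling == "attention":
            dH, domega = _attention_backward(dc, Hd, M, alpha, self.params["omega"])
            grads["omega"] = domega
        else:
            dH = alpha[:, :, None] * dc[:, None, :]
            grads["omega"] = np.zeros_like(self.params["omega"])
        if drop_mask is not None:
            dH = dH * drop_mask
        u = self.config.hidden_units
        g_f, dXf = _gru_backward(
            dH[:, :, :u], X, mask, cache_f,
            self.params["f_Wx"], self.params["f_Wh"], need_dX,
        )
        g_b, dXb_r = _gru_backward(
            dH[:, ::-1, u:], Xr, maskr, cache_b,
            self.params["b_Wx"], self.params["b_Wh"], need_dX,
        )
        for name, g in g_f.items():
            grads[f"f_{name}"] = g
        for name, g in g_b.items():
            grads[f"b_{name}"] = g
        dX = dXf + dXb_r[:, ::-1] if need_dX else None
        return grads, dX

    def loss_and_grads(self, X, mask, y_idx, drop_mask=None, need_dX=False):
        probs, ctx = self._forward(X, mask, train=True, drop_mask=drop_mask)
        B = X.shape[0]
        loss = -np.mean(np.log(probs[np.arange(B), y_idx] + 1e-12))
        grads, dX = self._backward(probs, y_idx, ctx, need_dX=need_dX)
        return loss, grads, dX

    # -- inference -----------------------------------------------------------

    def predict_probs(self, instances: list[EncodedInstance],
                      batch_size: int = 64) -> np.ndarray:
        out = []
        table = self.embedding_table
        for start in range(0, len(instances), batch_size):
            chunk = instances[start : start + batch_size]
            mask = np.stack([i.mask for i in chunk])
            if table is not None and all(i.token_ids is not None for i in chunk):
                # features come from the trained embedding table, so
                # instances encoded before training stay valid
                ids = np.stack([i.token_ids for i in chunk])
                X = np.where(mask[:, :, None], table[np.clip(ids, 0, None)], 0.0)
            else:
                X = np.stack([i.matrix for i in chunk])
            probs, _ = self._forward(X, mask, train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict_labels(self, instances: list[EncodedInstance]) -> list[str]:
        probs = self.predict_probs(instances)
        return [self.config.labels[i] for i in probs.argmax(axis=1)]

    def score(self, instances: list[EncodedInstance]) -> dict:
        """Weighted P/R/F1 against the instances' own labels."""
        y_true = [i.label for i in instances]
        y_pred = self.predict_labels(instances)
        report = _metrics.classification_report(
            y_true, y_pred, labels=self.config.labels
        )
        return report.total

    # -- training ------------------------------------------------------------

    def fit(
        self,
        train_set: list[EncodedInstance],
        val_set: list[EncodedInstance],
        backend: LookupBackend | None = None,
        train_embeddings: bool = True,
        verbose: bool = False,
    ) -> list[dict]:
        """Mini-batch training with cross-entropy loss.

        Dropout is applied to H during training only.  After every epoch the
        validation split is scored; the parameters of the best
        weighted-F1 epoch are restored at the end (together with the
        embedding table when that is being trained).
        """
        if not train_set:
            raise ValueError("empty training set")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        label_to_idx = {lab: i for i, lab in enumerate(cfg.labels)}
        y = np.array([label_to_idx[i.label] for i in train_set])
        update_emb = train_embeddings and backend is not None
        masks = np.stack([i.mask for i in train_set])
        if update_emb:
            ids = np.stack([i.token_ids for i in train_set])
        else:
            X_all = np.stack([i.matrix for i in train_set])

        opt_state: dict[str, tuple] = {}
        step = 0

        def adam_update(name, param, grad):
            nonlocal step
            if cfg.optimizer == "sgd":
                param -= cfg.learning_rate * grad
                return
            m, v = opt_state.get(name, (np.zeros_like(param), np.zeros_like(param)))
            m = 0.9 * m + 0.1 * grad
            v = 0.999 * v + 0.001 * grad * grad
            opt_state[name] = (m, v)
            mh = m / (1.0 - 0.9**step)
            vh = v / (1.0 - 0.999**step)
            param -= cfg.learning_rate * mh / (np.sqrt(vh) + 1e-8)

        best = {"f1": -1.0, "params": None, "table": None}
        self.trace = []
        n = len(train_set)
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                sel = perm[start : start + cfg.batch_size]
                mask = masks[sel]
                if update_emb:
                    bids = ids[sel]
                    X = np.where(
                        mask[:, :, None], backend.table[np.clip(bids, 0, None)], 0.0
                    )
                else:
                    X = X_all[sel]
                drop_mask = None
                if cfg.dropout > 0.0:
                    keep = 1.0 - cfg.dropout
                    drop_mask = (
                        rng.random((X.shape[0], X.shape[1], 1)) < keep
                    ).astype(float) / keep
                step += 1
                loss, grads, dX = self.loss_and_grads(
                    X, mask, y[sel], drop_mask=drop_mask, need_dX=update_emb
                )
                losses.append(loss)
                for name, grad in grads.items():
                    adam_update(name, self.params[name], grad)
                if update_emb:
                    dE = np.zeros_like(backend.table)
                    np.add.at(dE, bids[mask], dX[mask])
                    adam_update("embedding", backend.table, dE)
            if update_emb:
                for inst in val_set:
                    backend.refresh(inst)
            val = self.score(val_set) if val_set else {"P": 0.0, "R": 0.0, "F1": 0.0}
            entry = {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_P": val["P"],
                "val_R": val["R"],
                "val_F1": val["F1"],
            }
            self.trace.append(entry)
            if verbose:
                logger.info(
                    "epoch %d loss %.4f val F1 %.4f", epoch, entry["loss"], val["F1"]
                )
            if val["F1"] > best["f1"]:
                best = {
                    "f1": val["F1"],
                    "params": copy.deepcopy(self.params),
                    "table": backend.table.copy() if update_emb else None,
                }
        if best["params"] is not None:
            self.params = best["params"]
            if update_emb and best["table"] is not None:
                backend.table = best["table"]
                for inst in train_set + val_set:
                    backend.refresh(inst)
                self.embedding_table = backend.table
        return self.trace

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        """Parameters as an .npz checkpoint with a JSON config sidecar."""
        arrays = dict(self.params)
        if self.embedding_table is not None:
            arrays["embedding_table"] = self.embedding_table
        np.savez(path, **arrays)
        sidecar = str(path) + ".json"
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "hidden_units": self.config.hidden_units,
                    "labels": list(self.config.labels),
                    "dropout": self.config.dropout,
                    "learning_rate": self.config.learning_rate,
                    "batch_size": self.config.batch_size,
                    "epochs": self.config.epochs,
                    "optimizer": self.config.optimizer,
                    "pooling": self.config.pooling,
                    "seed": self.config.seed,
                    "D": self.D,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path) -> "RelationModel":
        with open(str(path) + ".json", encoding="utf-8") as fh:
            meta = json.load(fh)
        D = meta.pop("D")
        meta["labels"] = tuple(meta["labels"])
        model = cls(ModelConfig(**meta), D=D)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path))
        for name in model.params:
            model.params[name] = data[name]
        if "embedding_table" in data:
            model.embedding_table = data["embedding_table"]
        return model


def write_trace_csv(path, trace: list[dict]) -> None:
    import csv as _csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = _csv.DictWriter(
            fh, fieldnames=["epoch", "loss", "val_P", "val_R", "val_F1"]
        )
        writer.writeheader()
        writer.writerows(trace)


# ---------------------------------------------------------------------------
# triple extraction


def predict_triples(
    records: list[QARecord],
    model: RelationModel,
    backend: LookupBackend,
    keep_ukn: bool = True,
) -> list[RelationTriple]:
    """Classify every candidate (DIS, SYM/TRE) mention pair of each record.

    UKN-labelled pairs are kept here and dropped later at dictionary
    assembly, so callers can still audit them.
    """
    pairs = []
    encoded = []
    for record in records:
        for e1, e2 in candidate_pairs(record):
            inst = make_marked_instance(record, e1, e2, label=None)
            enc = backend.encode(inst.marked_text)
            if enc.dropped_marker:
                logger.warning(
                    "skipping pair (%s, %s) in %s: marker lost to truncation",
                    e1.surface, e2.surface, record.record_id,
                )
                continue
            pairs.append((e1.surface, e2.surface))
            encoded.append(enc)
    if not encoded:
        return []
    labels = model.predict_labels(encoded)
    triples = [
        RelationTriple(entity1=e1, entity2=e2, relation=lab)
        for (e1, e2), lab in zip(pairs, labels)
    ]
    if not keep_ukn:
        triples = [t for t in triples if t.relation != "UKN"]
    return triples
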