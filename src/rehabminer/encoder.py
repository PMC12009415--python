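"""Text -> L x D token-feature matrices with padding masks.

Two backends share one contract: every instance becomes a fixed-shape
``(L, D)`` real matrix plus an ``(L,)`` boolean mask (True = real token);
padded rows are exactly zero.

* ``LookupBackend`` — a seeded, trainable token-embedding table.  Fully
  self-contained; this is what training, tests and the acceptance run use.
* ``PretrainedBackend`` — optional adapter around an external contextual
  encoder (frozen features).  It requires the ``transformers`` package and a
  weight download, and is never needed by the rest of the package.

Tokenization is pluggable: whitespace mode for the synthetic corpora or
character mode for scripts without word boundaries.  The position markers
``#`` and ``*`` always come out as single tokens.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EncodedInstance",
    "tokenize",
    "LookupBackend",
    "PretrainedBackend",
    "encode_dataset",
]

UNK = "<unk>"


@dataclass
class EncodedInstance:
    matrix: np.ndarray          # (L, D); padded rows are zero
    mask: np.ndarray            # (L,) bool
    label: str | None = None
    token_ids: np.ndarray | None = None   # (L,) int, -1 on padding
    truncated: bool = False
    dropped_marker: bool = False  # truncation removed a position marker

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def D(self) -> int:
        return self.matrix.shape[1]


def tokenize(text: str, mode: str = "whitespace") -> list[str]:
    """Split text into tokens; markers ``#``/``*`` are single tokens."""
    text = unicodedata.normalize("NFC", text)
    if mode == "char":
        return [c for c in text if not c.isspace()]
    if mode != "whitespace":
        raise ValueError(f"unknown tokenize mode {mode!r}")
    tokens: list[str] = []
    for chunk in text.split():
        if chunk in ("#", "*") or not any(m in chunk for m in "#*"):
            tokens.append(chunk)
            continue
        # peel markers off mixed chunks, honouring backslash escapes
        buf = ""
        i = 0
        while i < len(chunk):
            ch = chunk[i]
            if ch == "\\" and i + 1 < len(chunk) and chunk[i + 1] in "#*":
                buf += chunk[i : i + 2]
                i += 2
            elif ch in "#*":
                if buf:
                    tokens.append(buf)
                    buf = ""
                tokens.append(ch)
                i += 1
            else:
                buf += ch
                i += 1
        if buf:
            tokens.append(buf)
    return tokens


class LookupBackend:
    """Seeded token-embedding table, growable or frozen with an UNK row.

    Rows are drawn N(0, 1/sqrt(D)) from the seed.  The table is a trainable
    parameter: the training loop may add gradient updates to ``table`` rows
    through the ``token_ids`` recorded on each instance.
    """

    def __init__(
        self,
        L: int = 200,
        D: int = 32,
        seed: int = 0,
        tokenize_mode: str = "whitespace",
        frozen_vocab: bool = False,
    ) -> None:
        self.L = L
        self.D = D
        self.seed = seed
        self.tokenize_mode = tokenize_mode
        self.frozen_vocab = frozen_vocab
        self._rng = np.random.default_rng(seed)
        self.vocab: dict[str, int] = {}
        self.table = np.zeros((0, D))
        self._add_token(UNK)

    def _add_token(self, token: str) -> int:
        idx = len(self.vocab)
        self.vocab[token] = idx
        row = self._rng.normal(0.0, 1.0 / np.sqrt(self.D), size=(1, self.D))
        self.table = np.concatenate([self.table, row], axis=0)
        return idx

    def token_id(self, token: str) -> int:
        if token in self.vocab:
            return self.vocab[token]
        if self.frozen_vocab:
            return self.vocab[UNK]
        return self._add_token(token)

    def encode(self, text: str, label: str | None = None) -> EncodedInstance:
        tokens = tokenize(text, self.tokenize_mode)
        truncated = len(tokens) > self.L
        dropped_marker = False
        if truncated:
            dropped = tokens[self.L :]
            tokens = tokens[: self.L]
            dropped_marker = "#" in dropped or "*" in dropped
            logger.warning(
                "truncated instance to L=%d tokens%s", self.L,
                " (position marker lost)" if dropped_marker else "",
            )
        ids = np.full(self.L, -1, dtype=np.int64)
        mask = np.zeros(self.L, dtype=bool)
        matrix = np.zeros((self.L, self.D))
        for t, token in enumerate(tokens):
            ids[t] = self.token_id(token)
            mask[t] = True
        matrix[mask] = self.table[ids[mask]]
        return EncodedInstance(
            matrix=matrix, mask=mask, label=label, token_ids=ids,
            truncated=truncated, dropped_marker=dropped_marker,
        )

    def refresh(self, inst: EncodedInstance) -> None:
        """Re-read table rows into an instance after embedding updates."""
        inst.matrix[inst.mask] = self.table[inst.token_ids[inst.mask]]

    def save_vocab(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.vocab, fh, ensure_ascii=False, indent=0)

    def load_vocab(self, path) -> None:
        with open(path, encoding="utf-8") as fh:
            vocab = json.load(fh)
        rng = np.random.default_rng(self.seed)
        order = sorted(vocab, key=vocab.get)
        self.vocab = {}
        self.table = np.zeros((0, self.D))
        self._rng = rng
        for token in order:
            self._add_token(token)


def encode_dataset(backend, instances) -> list[EncodedInstance]:
    """Encode labelled relation instances, dropping any whose position
    markers fell off the truncated tail (they are unclassifiable)."""
    out = []
    dropped = 0
    for inst in instances:
        enc = backend.encode(inst.marked_text, label=inst.label)
        if enc.dropped_marker:
            dropped += 1
            continue
        out.append(enc)
    if dropped:
        logger.warning("excluded %d instance(s) invalid after truncation", dropped)
    return out


class PretrainedBackend:
    """Adapter around a frozen external contextual encoder (optional).

    Defaults match the published architecture the pipeline was designed
    around: sequence length 200, feature width 768, character tokenization.
    """

    def __init__(self, model_name: str = "bert-base-chinese", L: int = 200) -> None:
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PretrainedBackend requires the optional 'transformers' package "
                "and a model download; use LookupBackend for self-contained runs"
            ) from exc
        import transformers

        self.L = L
        self.D = 768
        self._tokenizer = transformers.AutoTokenizer.from_pretrained(model_name)
        self._model = transformers.AutoModel.from_pretrained(model_name)
        self._model.eval()

    def encode(self, text: str, label: str | None = None) -> EncodedInstance:  # pragma: no cover
        import torch

        enc = self._tokenizer(
            text, max_length=self.L, truncation=True, padding="max_length",
            return_tensors="pt",
        )
        with torch.no_grad():
            out = self._model(**enc).last_hidden_state[0].numpy()
        mask = enc["attention_mask"][0].numpy().astype(bool)
        out[~mask] = 0.0
        return EncodedInstance(matrix=out.astype(np.float64), mask=mask, label=label)
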