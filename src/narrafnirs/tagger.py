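"""Hierarchical bidirectional-RNN token tagger with two parallel heads.

Each token is embedded, run through forward and backward Elman (tanh)
recurrences whose hidden states are concatenated per token, and scored by
two parallel softmax heads: one predicts whether the token is emotional
vocabulary, the other whether it is factual vocabulary.  Token markers
(onsets) ride along unchanged, so tagged output can drive event-locked
analysis directly.  A sentence-level pass through the same biRNN plus an
upper-level recurrence yields a whole-document representation.

Everything is plain numpy with hand-derived backpropagation-through-time;
training is full-batch gradient descent with a fixed learning rate and a
seeded initialisation, which keeps runs exactly reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import InputError

OOV = "<oov>"

PARAM_NAMES = ("E", "f_Wx", "f_Wh", "f_b", "b_Wx", "b_Wh", "b_b",
               "U_e", "c_e", "U_f", "c_f", "u_Wx", "u_Wh", "u_b")


def init_params(vocab_size: int, embed_dim: int = 16, hidden: int = 32,
                upper_hidden: int = 32, seed: int = 0, scale: float = 0.1
                ) -> dict[str, np.ndarray]:
    """Seeded random initialisation of every weight matrix."""
    rng = np.random.Generator(np.random.PCG64(seed))
    d, h, hu = embed_dim, hidden, upper_hidden

    def w(*shape):
        return rng.normal(0.0, scale, shape)

    return {
        "E": w(vocab_size, d),
        "f_Wx": w(d, h), "f_Wh": w(h, h), "f_b": np.zeros(h),
        "b_Wx": w(d, h), "b_Wh": w(h, h), "b_b": np.zeros(h),
        "U_e": w(2 * h, 2), "c_e": np.zeros(2),
        "U_f": w(2 * h, 2), "c_f": np.zeros(2),
        "u_Wx": w(2 * h, hu), "u_Wh": w(hu, hu), "u_b": np.zeros(hu),
    }


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _birnn_states(idx: np.ndarray, p: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward states, backward states, embedded inputs for one sequence."""
    x = p["E"][idx]                      # (T, d)
    T = idx.size
    h = p["f_b"].size
    hf = np.zeros((T, h))
    hb = np.zeros((T, h))
    prev = np.zeros(h)
    for t in range(T):
        prev = np.tanh(x[t] @ p["f_Wx"] + prev @ p["f_Wh"] + p["f_b"])
        hf[t] = prev
    nxt = np.zeros(h)
    for t in range(T - 1, -1, -1):
        nxt = np.tanh(x[t] @ p["b_Wx"] + nxt @ p["b_Wh"] + p["b_b"])
        hb[t] = nxt
    return hf, hb, x


def forward_tagger(idx: Sequence[int], params: dict,
                   markers: Sequence[float] | None = None) -> dict:
    """Per-token emotional/factual probabilities for one token sequence.

    Returns a dict with ``p_emotional`` and ``p_factual`` (length-T arrays
    of the positive-class probability of each head), the full per-head
    softmax outputs, the concatenated state sequence ``H``, and the input
    ``markers`` passed through untouched and in order.
    """
    idx = np.asarray(idx, int)
    if idx.size == 0:
        raise InputError("empty token sequence")
    if idx.min() < 0 or idx.max() >= params["E"].shape[0]:
        raise InputError("token index outside the vocabulary")
    hf, hb, _ = _birnn_states(idx, params)
    H = np.concatenate([hf, hb], axis=1)          # (T, 2h)
    y_e = _softmax(H @ params["U_e"] + params["c_e"])
    y_f = _softmax(H @ params["U_f"] + params["c_f"])
    return {
        "p_emotional": y_e[:, 1], "p_factual": y_f[:, 1],
        "softmax_emotion": y_e, "softmax_fact": y_f, "H": H,
        "markers": None if markers is None else list(markers),
    }


def encode_document(sentences: Sequence[Sequence[int]], params: dict
                    ) -> np.ndarray:
    """Document vector: sentence biRNN encodings fed to an upper RNN.

    Each sentence is encoded as the concatenation of its final forward
    and final backward hidden states (dimension 2h); the upper Elman cell
    consumes the sentence vectors in order and its final state is the
    document representation.
    """
    if len(sentences) == 0:
        raise InputError("empty sentence list")
    svecs = []
    for sent in sentences:
        idx = np.asarray(sent, int)
        if idx.size == 0:
            raise InputError("empty sentence")
        hf, hb, _ = _birnn_states(idx, params)
        svecs.append(np.concatenate([hf[-1], hb[0]]))
    u = np.zeros(params["u_b"].size)
    for s in svecs:
        u = np.tanh(s @ params["u_Wx"] + u @ params["u_Wh"] + params["u_b"])
    return u


def sentence_vectors(sentences: Sequence[Sequence[int]], params: dict
                     ) -> np.ndarray:
    """The s_j sentence encodings (J, 2h) used by the upper RNN."""
    out = []
    for sent in sentences:
        hf, hb, _ = _birnn_states(np.asarray(sent, int), params)
        out.append(np.concatenate([hf[-1], hb[0]]))
    return np.asarray(out)


def loss_and_grads(params: dict, sequences: Sequence[np.ndarray],
                   labels_e: Sequence[np.ndarray],
                   labels_f: Sequence[np.ndarray]) -> tuple[float, dict]:
    """Summed two-head cross-entropy and its analytic gradients (BPTT)."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    h = params["f_b"].size
    total = 0.0
    for idx, ye, yf in zip(sequences, labels_e, labels_f):
        idx = np.asarray(idx, int)
        ye = np.asarray(ye, int)
        yf = np.asarray(yf, int)
        T = idx.size
        hf, hb, x = _birnn_states(idx, params)
        H = np.concatenate([hf, hb], axis=1)
        pe = _softmax(H @ params["U_e"] + params["c_e"])
        pf = _softmax(H @ params["U_f"] + params["c_f"])
        total -= float(np.sum(np.log(pe[np.arange(T), ye])))
        total -= float(np.sum(np.log(pf[np.arange(T), yf])))

        dle = pe.copy()
        dle[np.arange(T), ye] -= 1.0
        dlf = pf.copy()
        dlf[np.arange(T), yf] -= 1.0
        grads["U_e"] += H.T @ dle
        grads["c_e"] += dle.sum(axis=0)
        grads["U_f"] += H.T @ dlf
        grads["c_f"] += dlf.sum(axis=0)
        dH = dle @ params["U_e"].T + dlf @ params["U_f"].T
        dhf, dhb = dH[:, :h], dH[:, h:]
        dx = np.zeros_like(x)

        carry = np.zeros(h)
        for t in range(T - 1, -1, -1):
            da = dhf[t] + carry
            dpre = da * (1.0 - hf[t] ** 2)
            grads["f_b"] += dpre
            grads["f_Wx"] += np.outer(x[t], dpre)
            prev = hf[t - 1] if t > 0 else np.zeros(h)
            grads["f_Wh"] += np.outer(prev, dpre)
            dx[t] += dpre @ params["f_Wx"].T
            carry = dpre @ params["f_Wh"].T

        carry = np.zeros(h)
        for t in range(T):
            da = dhb[t] + carry
            dpre = da * (1.0 - hb[t] ** 2)
            grads["b_b"] += dpre
            grads["b_Wx"] += np.outer(x[t], dpre)
            nxt = hb[t + 1] if t < T - 1 else np.zeros(h)
            grads["b_Wh"] += np.outer(nxt, dpre)
            dx[t] += dpre @ params["b_Wx"].T
            carry = dpre @ params["b_Wh"].T

        np.add.at(grads["E"], idx, dx)
    return total, grads


def train_tagger(sequences: Sequence[np.ndarray],
                 labels_e: Sequence[np.ndarray],
                 labels_f: Sequence[np.ndarray],
                 vocab_size: int, epochs: int = 150, lr: float = 0.5,
                 seed: int = 0, embed_dim: int = 16, hidden: int = 32,
                 upper_hidden: int = 32) -> tuple[dict, list[float]]:
    """Full-batch gradient descent on the summed two-head cross-entropy.

    The step is the gradient of the mean per-token loss times ``lr``.
    Returns the trained parameters and the per-epoch loss history
    (mean loss per token, evaluated before each update).
    """
    ye_all = np.concatenate([np.asarray(y) for y in labels_e])
    yf_all = np.concatenate([np.asarray(y) for y in labels_f])
    if np.unique(ye_all).size < 2 or np.unique(yf_all).size < 2:
        raise InputError("training corpus must contain both classes "
                         "for both heads")
    n_tokens = ye_all.size
    params = init_params(vocab_size, embed_dim, hidden, upper_hidden, seed)
    history: list[float] = []
    for _ in range(epochs):
        loss, grads = loss_and_grads(params, sequences, labels_e, labels_f)
        history.append(loss / n_tokens)
        for k in params:
            params[k] -= lr * grads[k] / n_tokens
    return params, history


def save_params(params: dict, path: str | Path) -> None:
    payload = {k: np.asarray(v).tolist() for k, v in params.items()}
    Path(path).write_text(json.dumps(payload))


def load_params(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {k: np.asarray(v, float) for k, v in payload.items()}


class BiRnnTagger(BaseEstimator):
    """Scikit-learn style estimator around the hierarchical biRNN tagger.

    ``X`` is a list of token sequences (lists of surface forms); ``y`` is
    a list of (T, 2) integer arrays with columns (emotional, factual).
    Words seen fewer than ``min_count`` times in training map to a shared
    out-of-vocabulary embedding, which also handles unseen test words.
    """

    def __init__(self, embed_dim: int = 16, hidden: int = 32,
                 upper_hidden: int = 32, epochs: int = 150, lr: float = 0.5,
                 min_count: int = 2, random_state: int = 0):
        self.embed_dim = embed_dim
        self.hidden = hidden
        self.upper_hidden = upper_hidden
        self.epochs = epochs
        self.lr = lr
        self.min_count = min_count
        self.random_state = random_state

    # -- vocabulary ---------------------------------------------------
    def _index(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.vocab_.get(t, 0) for t in tokens], int)

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[np.ndarray]):
        if len(X) == 0:
            raise InputError("empty training corpus")
        counts: dict[str, int] = {}
        for seq in X:
            for tok in seq:
                counts[tok] = counts.get(tok, 0) + 1
        self.vocab_ = {OOV: 0}
        for tok, c in sorted(counts.items()):
            if c >= self.min_count:
                self.vocab_[tok] = len(self.vocab_)
        seqs = [self._index(seq) for seq in X]
        ye = [np.asarray(lab)[:, 0] for lab in y]
        yf = [np.asarray(lab)[:, 1] for lab in y]
        self.params_, self.loss_curve_ = train_tagger(
            seqs, ye, yf, vocab_size=len(self.vocab_), epochs=self.epochs,
            lr=self.lr, seed=self.random_state, embed_dim=self.embed_dim,
            hidden=self.hidden, upper_hidden=self.upper_hidden)
        self.n_iter_ = len(self.loss_curve_)
        return self

    def predict_proba(self, X: Sequence[Sequence[str]]) -> list[np.ndarray]:
        out = []
        for seq in X:
            res = forward_tagger(self._index(seq), self.params_)
            out.append(np.column_stack([res["p_emotional"],
                                        res["p_factual"]]))
        return out

    def predict(self, X: Sequence[Sequence[str]]) -> list[np.ndarray]:
        return [(p >= 0.5).astype(int) for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean per-token accuracy over both heads."""
        preds = self.predict(X)
        correct = total = 0
        for p, lab in zip(preds, y):
            lab = np.asarray(lab)
            correct += int((p == lab).sum())
            total += lab.size
        return correct / total

    def encode_document(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        return encode_document([self._index(s) for s in sentences],
                               self.params_)
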