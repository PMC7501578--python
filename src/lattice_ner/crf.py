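"""Linear-chain conditional random field with exact inference.

A sequence is scored as the sum of per-position emission scores and
label-transition scores, including transitions from a START state into the
first label and from the last label into STOP:

    S(X, y) = sum_i p_{i, y_i} + sum_{i=0..n} A_{y_i, y_{i+1}}

P(y|X) is the globally normalized exp(S)/Z; the log-partition Z is
computed exactly with the forward algorithm in log space, and decoding is
exact Viterbi.  Emission scores are unnormalized logits — normalization
happens once, globally, in the partition function.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Linear, Tensor, no_grad

#: additive mask for structurally forbidden transitions.  A large finite
#: value instead of -inf keeps log-sum-exp gradients free of NaNs.
NEG_INF = -1e4


def make_transitions(n_labels: int, rng: np.random.Generator | None = None,
                     scale: float = 0.1) -> np.ndarray:
    """(k+2, k+2) transition matrix with START/STOP rows masked.

    Index k is START, k+1 is STOP; transitions *into* START and *out of*
    STOP are forbidden, as is START->STOP directly.
    """
    k = n_labels
    A = (rng.normal(0, scale, size=(k + 2, k + 2)) if rng is not None
         else np.zeros((k + 2, k + 2)))
    A[:, k] = NEG_INF          # nothing enters START
    A[k + 1, :] = NEG_INF      # nothing leaves STOP
    A[k, k + 1] = NEG_INF
    return A


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sequence_score(emissions, transitions, y: list[int] | np.ndarray):
    """S(X, y): n emission terms plus n+1 transition terms (START..STOP).

    Accepts arrays or Tensors; returns a Tensor (a scalar one)."""
    em = _as_tensor(emissions)
    A = _as_tensor(transitions)
    n, k = em.shape
    y = list(y)
    if len(y) != n:
        raise ValueError("label sequence length mismatch")
    if any(not 0 <= yi < k for yi in y):
        raise ValueError("label index out of range")
    start, stop = k, k + 1
    rows = np.arange(n)
    score = em[(rows, np.array(y))].sum()
    prev = [start] + y
    nxt = y + [stop]
    score = score + A[(np.array(prev), np.array(nxt))].sum()
    return score


def log_partition(emissions, transitions):
    """log sum over all k^n label paths of exp(S), by the forward
    recursion in log space (numerically stable log-sum-exp)."""
    em = _as_tensor(emissions)
    A = _as_tensor(transitions)
    n, k = em.shape
    start, stop = k, k + 1
    # alpha over the k real labels
    alpha = A[start, :k] + em[0]
    core = A[:k, :k]
    for t in range(1, n):
        # (k_prev, k_next): alpha[i] + A[i, j] + em[t, j]
        mat = alpha.reshape((k, 1)) + core + em[t].reshape((1, k))
        alpha = mat.logsumexp(axis=0)
    return (alpha + A[:k, stop]).logsumexp(axis=0)


def crf_nll(emissions, transitions, y):
    """-log P(y|X) = log Z - S(X, y); non-negative."""
    return log_partition(emissions, transitions) - sequence_score(
        emissions, transitions, y)


def viterbi(emissions: np.ndarray, transitions: np.ndarray,
            allowed: np.ndarray | None = None) -> tuple[list[int], float]:
    """Exact max-scoring path; ties break toward the lowest label index.

    ``allowed`` is an optional boolean (k+2, k+2) mask of permitted
    transitions (e.g. the BIO schema mask) applied additively at decode
    time.
    """
    em = np.asarray(emissions, dtype=np.float64)
    A = np.asarray(transitions, dtype=np.float64).copy()
    if allowed is not None:
        A = A + np.where(allowed, 0.0, NEG_INF)
    n, k = em.shape
    start, stop = k, k + 1
    delta = A[start, :k] + em[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        mat = delta[:, None] + A[:k, :k] + em[t][None, :]
        # argmax returns the first (lowest) index on ties
        back[t] = np.argmax(mat, axis=0)
        delta = mat[back[t], np.arange(k)]
    final = delta + A[:k, stop]
    last = int(np.argmax(final))
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(final[last])


def bio_transition_mask(labels: list[str]) -> np.ndarray:
    """Boolean (k+2, k+2) mask of BIO-schema-valid transitions.

    Forbidden: anything -> I-X unless from B-X or I-X.  START/STOP
    structural masking is handled by :func:`make_transitions`; this mask
    never makes a schema-consistent gold path infeasible.
    """
    k = len(labels)
    ok = np.ones((k + 2, k + 2), dtype=bool)
    for j, lj in enumerate(labels):
        if not lj.startswith("I-"):
            continue
        cat = lj[2:]
        for i in range(k + 2):
            li = labels[i] if i < k else None
            if li is None or li == "O" or li[2:] != cat:
                ok[i, j] = False
    return ok


class CRFLayer:
    """Trainable emission projection + transition matrix over label set."""

    def __init__(self, labels: list[str], hidden_dim: int, seed: int = 0):
        self.labels = list(labels)
        k = len(labels)
        rng = np.random.default_rng(seed)
        s = np.sqrt(6.0 / (hidden_dim + k))
        self.W_emit = Tensor(rng.uniform(-s, s, size=(k, hidden_dim)),
                             requires_grad=True)
        self.b_emit = Tensor(np.zeros(k), requires_grad=True)
        self._emit_lin = Linear(self.W_emit, self.b_emit)
        self.transitions = Tensor(make_transitions(k, rng), requires_grad=True)
        self.decode_mask = bio_transition_mask(self.labels)

    def params(self) -> list[Tensor]:
        return [self.W_emit, self.b_emit, self.transitions]

    def emissions(self, hidden: Tensor) -> Tensor:
        """Project (n, hidden_dim) encoder states to (n, k) label scores."""
        return self._emit_lin(hidden)

    def nll(self, hidden: Tensor, y: list[int]) -> Tensor:
        return crf_nll(self.emissions(hidden), self.transitions, y)

    def decode(self, hidden: Tensor, masked: bool = True) -> list[int]:
        with no_grad():
            em = self.emissions(hidden).data
        path, _ = viterbi(em, self.transitions.data,
                          self.decode_mask if masked else None)
        return path
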