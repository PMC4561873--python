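"""Linear-chain conditional random field with first- or second-order
transitions, trained by L-BFGS on the L2-regularized conditional
log-likelihood.

The second-order model keeps emission features tied to the current label and
adds a transition tensor over label triples (y_{t-2}, y_{t-1}, y_t),
evaluated exactly by forward-backward over pair states. Sentences are
encoded up front as integer feature-id lists; emissions for the whole corpus
are computed per objective evaluation with one sparse matrix product, so
training scales to a few thousand sentences on one CPU.

Everything is deterministic: zero initialization, fixed feature ordering and
a deterministic optimizer mean identical inputs give identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp


@dataclass
class CRFConfig:
    """Training configuration (all defaults recorded in model metadata)."""

    order: int = 2          # Markov order of the label chain (1 or 2)
    l2: float = 1.0         # L2 regularization coefficient
    max_iter: int = 100     # L-BFGS iteration cap
    tol: float = 1e-6       # ftol passed to the optimizer

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


class LinearChainCRF:
    """CRF over integer-encoded sentences.

    ``X`` is a list of sentences, each a list of per-token feature-id lists;
    ``y`` is the matching list of label-id lists. Feature and label
    vocabularies are managed by the caller.
    """

    def __init__(self, n_labels: int, n_features: int,
                 config: CRFConfig | None = None) -> None:
        self.L = n_labels
        self.F = n_features
        self.config = config or CRFConfig()
        self.emit = np.zeros((self.F, self.L))
        self.trans1 = np.zeros((self.L + 1, self.L))   # row L = BOS
        self.trans2 = np.zeros((self.L + 1, self.L, self.L))

    # ---------------------------------------------------------------- fit

    def _pack(self) -> np.ndarray:
        parts = [self.emit.ravel(), self.trans1.ravel()]
        if self.config.order == 2:
            parts.append(self.trans2.ravel())
        return np.concatenate(parts)

    def _unpack(self, w: np.ndarray) -> tuple[np.ndarray, ...]:
        L, F = self.L, self.F
        emit = w[: F * L].reshape(F, L)
        off = F * L
        trans1 = w[off : off + (L + 1) * L].reshape(L + 1, L)
        off += (L + 1) * L
        if self.config.order == 2:
            trans2 = w[off:].reshape(L + 1, L, L)
        else:
            trans2 = None
        return emit, trans1, trans2

    def fit(self, X: list[list[list[int]]], y: list[list[int]]) -> dict:
        if len(X) != len(y) or not X:
            raise ValueError("empty or mismatched training data")
        L, BOS = self.L, self.L
        sents = [(feats, labels) for feats, labels in zip(X, y) if labels]
        lengths = [len(lab) for _, lab in sents]
        n_tokens = sum(lengths)
        if n_tokens == 0:
            raise ValueError("training data contains no tokens")

        # sparse design matrix over all tokens
        rows, cols = [], []
        pos = 0
        for feats, _ in sents:
            for fids in feats:
                rows.extend([pos] * len(fids))
                cols.extend(fids)
                pos += 1
        Xs = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_tokens, self.F)
        )

        # empirical counts
        gold = np.concatenate([lab for _, lab in sents]).astype(int)
        Y1 = sp.csr_matrix(
            (np.ones(n_tokens), (np.arange(n_tokens), gold)),
            shape=(n_tokens, L),
        )
        emp_emit = (Xs.T @ Y1).toarray()
        emp_t1 = np.zeros((L + 1, L))
        emp_t2 = np.zeros((L + 1, L, L))
        for _, lab in sents:
            emp_t1[BOS, lab[0]] += 1
            for t in range(1, len(lab)):
                emp_t1[lab[t - 1], lab[t]] += 1
                a = lab[t - 2] if t >= 2 else BOS
                emp_t2[a, lab[t - 1], lab[t]] += 1

        starts = np.concatenate([[0], np.cumsum(lengths)])
        order2 = self.config.order == 2
        l2 = self.config.l2

        def objective(w: np.ndarray):
            emit, trans1, trans2 = self._unpack(w)
            E = np.asarray(Xs @ emit)
            nll = 0.0
            post = np.zeros_like(E)
            e1 = np.zeros_like(emp_t1)
            e2 = np.zeros_like(emp_t2) if order2 else None
            for s, (feats, lab) in enumerate(sents):
                i0, i1 = starts[s], starts[s + 1]
                e = E[i0:i1]
                if order2:
                    logZ = self._fb2(e, trans1, trans2, post[i0:i1], e1, e2)
                else:
                    logZ = self._fb1(e, trans1, post[i0:i1], e1)
                # gold path score
                score = e[np.arange(len(lab)), lab].sum()
                score += trans1[BOS, lab[0]]
                for t in range(1, len(lab)):
                    score += trans1[lab[t - 1], lab[t]]
                    if order2:
                        a = lab[t - 2] if t >= 2 else BOS
                        score += trans2[a, lab[t - 1], lab[t]]
                nll += logZ - score
            g_emit = np.asarray((Xs.T @ (post - Y1.toarray())))
            parts = [g_emit.ravel(), (e1 - emp_t1).ravel()]
            if order2:
                parts.append((e2 - emp_t2).ravel())
            grad = np.concatenate(parts) + l2 * w
            return nll + 0.5 * l2 * w @ w, grad

        w0 = self._pack()
        res = minimize(
            objective, w0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.config.max_iter,
                     "maxfun": self.config.max_iter * 3,
                     "ftol": self.config.tol},
        )
        self.emit, self.trans1, t2 = self._unpack(res.x)
        if t2 is not None:
            self.trans2 = t2
        return {"converged": bool(res.success), "n_iter": int(res.nit),
                "final_nll": float(res.fun)}

    # ------------------------------------------- forward-backward, order 1

    def _fb1(self, e, trans1, post_out, e1_acc):
        L, BOS = self.L, self.L
        n = e.shape[0]
        alpha = np.empty((n, L))
        alpha[0] = trans1[BOS] + e[0]
        for t in range(1, n):
            alpha[t] = logsumexp(alpha[t - 1][:, None] + trans1[:L], axis=0) + e[t]
        logZ = logsumexp(alpha[n - 1])
        beta = np.zeros((n, L))
        for t in range(n - 2, -1, -1):
            beta[t] = logsumexp(trans1[:L] + (e[t + 1] + beta[t + 1])[None, :],
                                axis=1)
        post_out[:] = np.exp(alpha + beta - logZ)
        e1_acc[BOS] += post_out[0]
        for t in range(1, n):
            pair = np.exp(alpha[t - 1][:, None] + trans1[:L]
                          + (e[t] + beta[t])[None, :] - logZ)
            e1_acc[:L] += pair
        return logZ

    # ------------------------------------------- forward-backward, order 2

    def _fb2(self, e, trans1, trans2, post_out, e1_acc, e2_acc):
        L, BOS = self.L, self.L
        n = e.shape[0]
        a1 = trans1[BOS] + e[0]                     # state after position 0
        if n == 1:
            logZ = logsumexp(a1)
            post_out[0] = np.exp(a1 - logZ)
            e1_acc[BOS] += post_out[0]
            return logZ
        # alpha over pair states (y_{t-1}, y_t), t = 1..n-1
        step1 = a1[:, None] + trans1[:L] + trans2[BOS] + e[1][None, :]
        alphas = [step1]
        for t in range(2, n):
            m = alphas[-1][:, :, None] + trans2[:L]
            alphas.append(logsumexp(m, axis=0) + trans1[:L] + e[t][None, :])
        logZ = logsumexp(alphas[-1])
        betas = [np.zeros((L, L))]                  # beta at t = n-1
        for t in range(n - 1, 1, -1):
            inner = trans2[:L] + (trans1[:L] + e[t][None, :]
                                  + betas[-1])[None, :, :]
            betas.append(logsumexp(inner, axis=2))
        betas.reverse()                             # betas[t-1] for t=1..n-1
        # pair marginals and expected transition counts
        for t in range(1, n):
            pair = np.exp(alphas[t - 1] + betas[t - 1] - logZ)
            e1_acc[:L] += pair
            post_out[t] = pair.sum(axis=0)
            if t == 1:
                e2_acc[BOS] += pair
                post_out[0] = pair.sum(axis=1)
            else:
                triple = np.exp(
                    alphas[t - 2][:, :, None] + trans2[:L]
                    + (trans1[:L] + e[t][None, :] + betas[t - 1]
                       - logZ)[None, :, :]
                )
                e2_acc[:L] += triple
        e1_acc[BOS] += post_out[0]
        return logZ

    # ------------------------------------------------------------- decode

    def _emissions(self, feats: list[list[int]]) -> np.ndarray:
        e = np.zeros((len(feats), self.L))
        for t, fids in enumerate(feats):
            for f in fids:
                e[t] += self.emit[f]
        return e

    def decode(self, feats: list[list[int]]) -> list[int]:
        """Viterbi decoding; returns one label id per token."""
        n = len(feats)
        if n == 0:
            return []
        e = self._emissions(feats)
        if self.config.order == 1:
            return self._viterbi1(e)
        return self._viterbi2(e)

    def _viterbi1(self, e: np.ndarray) -> list[int]:
        L, BOS = self.L, self.L
        n = e.shape[0]
        delta = self.trans1[BOS] + e[0]
        bps = []
        for t in range(1, n):
            m = delta[:, None] + self.trans1[:L]
            bps.append(np.argmax(m, axis=0))
            delta = m.max(axis=0) + e[t]
        path = [int(np.argmax(delta))]
        for bp in reversed(bps):
            path.append(int(bp[path[-1]]))
        return path[::-1]

    def _viterbi2(self, e: np.ndarray) -> list[int]:
        L, BOS = self.L, self.L
        n = e.shape[0]
        a1 = self.trans1[BOS] + e[0]
        if n == 1:
            return [int(np.argmax(a1))]
        delta = a1[:, None] + self.trans1[:L] + self.trans2[BOS] + e[1][None, :]
        bps = []
        for t in range(2, n):
            m = delta[:, :, None] + self.trans2[:L]
            bps.append(np.argmax(m, axis=0))
            delta = m.max(axis=0) + self.trans1[:L] + e[t][None, :]
        b, c = np.unravel_index(int(np.argmax(delta)), (L, L))
        path = [int(c), int(b)]
        for bp in reversed(bps):
            path.append(int(bp[path[-1], path[-2]]))
        return path[::-1]

    # ------------------------------------------------------------ persist

    def get_state(self) -> dict:
        state = {"emit": self.emit, "trans1": self.trans1,
                 "config": asdict(self.config),
                 "n_labels": self.L, "n_features": self.F}
        if self.config.order == 2:
            state["trans2"] = self.trans2
        return state

    @classmethod
    def from_state(cls, state: dict) -> "LinearChainCRF":
        crf = cls(int(state["n_labels"]), int(state["n_features"]),
                  CRFConfig(**state["config"]))
        crf.emit = np.asarray(state["emit"])
        crf.trans1 = np.asarray(state["trans1"])
        if "trans2" in state:
            crf.trans2 = np.asarray(state["trans2"])
        return crf
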