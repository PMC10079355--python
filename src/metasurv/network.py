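"""Four-layer feed-forward risk network and Cox partial-log-likelihood loss.

The network maps a feature vector to a scalar log-risk eta = f_theta(x)
through three ReLU hidden layers and a linear output layer; it generalizes
the linear predictor beta'x of the Cox proportional-hazards model.  The loss
is the negative partial log-likelihood

    L(theta) = -(1/d) * sum_{i: C_i=1} [ eta_i - log sum_{j: Y_j >= Y_i} exp(eta_j) ]

averaged over the d observed events (mean rather than sum so that learning
rates transfer across task sizes).  The risk set {j : Y_j >= Y_i} includes
the index patient and all patients with tied times (Breslow convention).

Everything is plain numpy: ``forward`` caches pre-activations, ``backward``
propagates d(loss)/d(eta) to per-layer weight gradients, so training,
meta-learning and attribution all share one exactly-differentiable core.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

Params = list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...] per layer

DEFAULT_HIDDEN = (128, 64, 32)


@dataclass
class RiskNetwork:
    """MLP with ReLU hidden layers and a scalar linear output.

    ``params`` holds one ``(W, b)`` pair per weight layer; ``W`` has shape
    (fan_in, fan_out).  Four weight layers by default: three hidden + output.
    """

    params: Params
    meta: dict = field(default_factory=dict)

    @classmethod
    def init(
        cls,
        n_features: int,
        hidden: tuple[int, ...] = DEFAULT_HIDDEN,
        seed: int = 0,
    ) -> "RiskNetwork":
        """He-initialised network with layout n_features -> hidden... -> 1."""
        rng = np.random.default_rng(seed)
        dims = [n_features, *hidden, 1]
        params: Params = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            params.append((W, b))
        return cls(params, {"layer_dims": dims, "seed": seed})

    @property
    def layer_dims(self) -> list[int]:
        return [self.params[0][0].shape[0]] + [W.shape[1] for W, _ in self.params]

    @property
    def n_features(self) -> int:
        return self.params[0][0].shape[0]

    def copy(self) -> "RiskNetwork":
        return RiskNetwork(
            [(W.copy(), b.copy()) for W, b in self.params], dict(self.meta)
        )

    # -- forward / backward ----------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Log-risk eta for each row of X; optionally return the activation cache."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input width {X.shape[1]} != network input width {self.n_features}"
            )
        acts = [X]  # post-activation inputs to each layer
        pre: list[np.ndarray] = []
        h = X
        last = len(self.params) - 1
        for i, (W, b) in enumerate(self.params):
            z = h @ W + b
            pre.append(z)
            h = z if i == last else np.maximum(z, 0.0)
            acts.append(h)
        eta = h[:, 0]
        if cache:
            return eta, (acts, pre)
        return eta

    def backward(self, cache, d_eta: np.ndarray) -> Params:
        """Gradients of sum_i d_eta[i]*eta_i w.r.t. every W and b."""
        acts, pre = cache
        grads: Params = [None] * len(self.params)  # type: ignore[list-item]
        delta = np.asarray(d_eta, dtype=float)[:, None]
        for i in range(len(self.params) - 1, -1, -1):
            W, _ = self.params[i]
            if i < len(self.params) - 1:
                delta = delta * (pre[i] > 0)
            gW = acts[i].T @ delta
            gb = delta.sum(axis=0)
            grads[i] = (gW, gb)
            if i > 0:
                delta = delta @ W.T
        return grads

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: JSON header line + flattened parameters."""
        header = {
            "layer_dims": self.layer_dims,
            "meta": {k: v for k, v in self.meta.items() if k != "layer_dims"},
        }
        flat = np.concatenate([np.r_[W.ravel(), b] for W, b in self.params])
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            fh.write(",".join(repr(float(v)) for v in flat) + "\n")

    @classmethod
    def load(cls, path) -> "RiskNetwork":
        with open(path) as fh:
            header = json.loads(fh.readline())
            flat = np.array([float(v) for v in fh.readline().split(",")])
        dims = header["layer_dims"]
        params: Params = []
        pos = 0
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            W = flat[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out)
            pos += fan_in * fan_out
            b = flat[pos : pos + fan_out]
            pos += fan_out
            params.append((W, b))
        return cls(params, header.get("meta", {}))


# -- Cox partial likelihood -----------------------------------------------


def cox_loss(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Negative mean partial log-likelihood over observed events."""
    loss, _ = cox_loss_grad(eta, time, event)
    return loss


def cox_loss_grad(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the per-patient log-risk eta.

    Risk sets are accumulated on the time-sorted order with a log-sum-exp
    shift for numerical stability.  Patients with tied times all enter each
    other's risk sets (Y_j >= Y_i taken literally).
    """
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if np.isnan(eta).any():
        raise ValueError("NaN in predicted log-risk")
    d = int(event.sum())
    if d == 0:
        warnings.warn("no observed events: Cox loss undefined, returning 0", stacklevel=2)
        return 0.0, np.zeros_like(eta)

    # sort descending by time so the risk set of patient i is a prefix;
    # stable ties: group patients with equal times
    order = np.argsort(-time, kind="stable")
    t_s, e_s, eta_s = time[order], event[order].astype(bool), eta[order]
    m = eta_s.max()
    exp_s = np.exp(eta_s - m)
    cum = np.cumsum(exp_s)
    # extend prefix over ties: risk set for time t includes every j with Y_j >= t
    n = len(t_s)
    risk_cum = cum.copy()
    for i in range(n - 2, -1, -1):
        if t_s[i] == t_s[i + 1]:
            risk_cum[i] = risk_cum[i + 1]
    log_risk = m + np.log(risk_cum)
    loss = -(eta_s[e_s] - log_risk[e_s]).sum() / d

    # gradient: dL/deta_k = -(1/d) [ 1{k event} - exp(eta_k) * sum_{i: k in R_i} 1/S_i ]
    inv_S = np.where(e_s, 1.0 / risk_cum, 0.0)
    # k belongs to the risk set of event i iff t_i <= t_k, i.e. (descending
    # order) i at or after the first index of k's tie group -> suffix sum
    grp_first = np.arange(n)
    for i in range(1, n):
        if t_s[i] == t_s[i - 1]:
            grp_first[i] = grp_first[i - 1]
    suffix_invS = np.cumsum(inv_S[::-1])[::-1]
    coef = suffix_invS[grp_first]
    grad_s = -(e_s.astype(float) - exp_s * coef) / d
    grad = np.empty_like(grad_s)
    grad[order] = grad_s
    return float(loss), grad


def cox_param_grad(
    net: RiskNetwork, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, Params]:
    """Loss and parameter gradients of the network's Cox loss on (X, time, event)."""
    eta, cache = net.forward(X, cache=True)
    loss, d_eta = cox_loss_grad(eta, time, event)
    if int(np.asarray(event).sum()) == 0:
        zero = [(np.zeros_like(W), np.zeros_like(b)) for W, b in net.params]
        return loss, zero
    return loss, net.backward(cache, d_eta)
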