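"""Model-agnostic meta-learning (MAML) for the Cox risk network.

Each cancer-type-like task contributes a support set (adaptation) and a
query set (evaluation; 30 patients by default).  The inner loop adapts the
shared initialisation theta to each task by plain gradient descent on the
support-set Cox loss (SGD, learning rate 0.01); the outer loop updates
theta with Adam (learning rate 1e-4) on the summed post-adaptation query
losses.

Second-order MAML needs the Hessian-vector product of the support loss with
the query gradient; it is computed by a central finite difference of the
support gradient, which is exact to O(eps^2) and costs two extra gradient
evaluations per task.  ``first_order=True`` drops the curvature term (FOMAML).

The direct-learning baseline trains a single network on all pooled source
support data, using a 5-fold split for early-stopping model selection, and
is evaluated on each target task's query set without adaptation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricResult, breslow_baseline, evaluate_predictions
from .network import Params, RiskNetwork, cox_param_grad

logger = logging.getLogger(__name__)


@dataclass
class TaskSplit:
    """Support/query partition of one task's patient IDs."""

    task_name: str
    support_ids: list
    query_ids: list
    role: str = "source"  # source | target

    def __post_init__(self) -> None:
        if set(self.support_ids) & set(self.query_ids):
            raise ValueError(f"task {self.task_name}: support and query overlap")


@dataclass
class TaskData:
    """Materialised arrays for one task."""

    name: str
    X_support: np.ndarray
    time_support: np.ndarray
    event_support: np.ndarray
    X_query: np.ndarray
    time_query: np.ndarray
    event_query: np.ndarray


@dataclass
class MetaConfig:
    inner_lr: float = 0.01
    outer_lr: float = 0.0001
    inner_steps: int = 1
    meta_iterations: int = 1000
    tasks_per_batch: int | None = None  # None = all tasks each iteration
    first_order: bool = False
    finetune_steps: int = 10
    validation_every: int = 25
    patience: int = 6  # validation checks without improvement before stopping
    hvp_eps: float = 1e-4
    plateau_tol: float = 1e-4
    plateau_window: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_lr < 0 or self.outer_lr <= 0:
            raise ValueError("outer_lr must be positive and inner_lr nonnegative")
        if self.inner_steps < 0:
            raise ValueError("inner_steps must be >= 0")


# -- parameter-list arithmetic --------------------------------------------


def _axpy(params: Params, grads: Params, scale: float) -> Params:
    return [
        (W + scale * gW, b + scale * gb)
        for (W, b), (gW, gb) in zip(params, grads)
    ]


def _flat(params: Params) -> np.ndarray:
    return np.concatenate([np.r_[W.ravel(), b.ravel()] for W, b in params])


def _norm(params: Params) -> float:
    return float(np.sqrt(sum((W**2).sum() + (b**2).sum() for W, b in params)))


class _Adam:
    """Minimal Adam on a parameter list."""

    def __init__(self, params: Params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.t = 0

    def step(self, params: Params, grads: Params) -> Params:
        self.t += 1
        out: Params = []
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            mW, mb = self.m[i]
            vW, vb = self.v[i]
            mW = self.b1 * mW + (1 - self.b1) * gW
            mb = self.b1 * mb + (1 - self.b1) * gb
            vW = self.b2 * vW + (1 - self.b2) * gW**2
            vb = self.b2 * vb + (1 - self.b2) * gb**2
            self.m[i] = (mW, mb)
            self.v[i] = (vW, vb)
            out.append(
                (
                    W - self.lr * (mW / bc1) / (np.sqrt(vW / bc2) + self.eps),
                    b - self.lr * (mb / bc1) / (np.sqrt(vb / bc2) + self.eps),
                )
            )
        return out


# -- MAML ------------------------------------------------------------------


def inner_adapt(
    net: RiskNetwork,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cfg: MetaConfig,
    steps: int | None = None,
) -> RiskNetwork:
    """theta' = theta - alpha * grad(support Cox loss), ``steps`` times.

    Never mutates ``net``; returns a new network.  With no events on the
    support set the parameters are returned unchanged (with a warning from
    the loss).
    """
    if len(X) == 0:
        raise ValueError("empty support set")
    params = net.params
    for _ in range(cfg.inner_steps if steps is None else steps):
        adapted = RiskNetwork(params, net.meta)
        _, grads = cox_param_grad(adapted, X, time, event)
        params = _axpy(params, grads, -cfg.inner_lr)
    return RiskNetwork(params, dict(net.meta))


def _adapt_trajectory(
    net: RiskNetwork, task: TaskData, cfg: MetaConfig
) -> list[Params]:
    """Parameter states theta_0..theta_k along the inner-loop trajectory."""
    traj = [net.params]
    params = net.params
    for _ in range(cfg.inner_steps):
        _, grads = cox_param_grad(
            RiskNetwork(params), task.X_support, task.time_support, task.event_support
        )
        params = _axpy(params, grads, -cfg.inner_lr)
        traj.append(params)
    return traj


def _support_hvp(
    params: Params, task: TaskData, v: Params, eps_scale: float
) -> Params:
    """Hessian-vector product of the support loss at ``params`` with ``v``.

    Central finite difference of the gradient:
    H v ~= [g(theta + eps v) - g(theta - eps v)] / (2 eps).
    """
    vnorm = _norm(v)
    if vnorm == 0:
        return [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    eps = eps_scale / vnorm
    _, g_plus = cox_param_grad(
        RiskNetwork(_axpy(params, v, eps)),
        task.X_support,
        task.time_support,
        task.event_support,
    )
    _, g_minus = cox_param_grad(
        RiskNetwork(_axpy(params, v, -eps)),
        task.X_support,
        task.time_support,
        task.event_support,
    )
    return [
        ((gpW - gmW) / (2 * eps), (gpb - gmb) / (2 * eps))
        for (gpW, gpb), (gmW, gmb) in zip(g_plus, g_minus)
    ]


def task_meta_gradient(
    net: RiskNetwork, task: TaskData, cfg: MetaConfig
) -> tuple[float, Params]:
    """Query loss after adaptation and its gradient w.r.t. the initialisation.

    With inner SGD steps theta_{i+1} = theta_i - alpha g_s(theta_i), the
    meta-gradient is prod_i (I - alpha H_s(theta_i)) applied to the query
    gradient at theta_k, accumulated in reverse over the trajectory.
    """
    traj = _adapt_trajectory(net, task, cfg)
    adapted = RiskNetwork(traj[-1])
    q_loss, v = cox_param_grad(
        adapted, task.X_query, task.time_query, task.event_query
    )
    if not cfg.first_order:
        for params_i in reversed(traj[:-1]):
            hv = _support_hvp(params_i, task, v, cfg.hvp_eps)
            v = _axpy(v, hv, -cfg.inner_lr)
    return q_loss, v


@dataclass
class MetaTrainResult:
    network: RiskNetwork
    loss_trace: list = field(default_factory=list)  # per-iteration outer loss
    per_task_trace: list = field(default_factory=list)
    validation_trace: list = field(default_factory=list)  # (iteration, val loss)
    diverged: bool = False


def cox_loss_on(net: RiskNetwork, X, time, event) -> float:
    """Cox loss of a network's predictions on one dataset."""
    from .network import cox_loss

    return cox_loss(net.forward(X), time, event)


def meta_train(
    init: RiskNetwork,
    tasks: list[TaskData],
    cfg: MetaConfig,
    validation_tasks: list[TaskData] | None = None,
) -> MetaTrainResult:
    """MAML outer loop: Adam on the summed post-adaptation query losses.

    With ``validation_tasks`` the outer loop additionally tracks the
    post-adaptation query loss on held-out tasks (never used for gradients)
    and returns the parameters from the best validation iteration
    (early stopping with patience ``cfg.patience``).  Long meta-training
    memorises the source query sets while generalisation to unseen tasks
    degrades, so a task-level validation signal is the reliable stop rule.
    """
    if not tasks:
        raise ValueError("need at least one source task")
    net = init.copy()
    opt = _Adam(net.params, cfg.outer_lr)
    rng = np.random.default_rng(cfg.seed)
    result = MetaTrainResult(network=net)
    last_good = net.params
    best_val, best_params, bad = np.inf, net.params, 0
    for it in range(cfg.meta_iterations):
        if validation_tasks is not None and it % cfg.validation_every == 0:
            vloss = 0.0
            for vt in validation_tasks:
                adapted = inner_adapt(
                    net, vt.X_support, vt.time_support, vt.event_support, cfg
                )
                vloss += cox_loss_on(adapted, vt.X_query, vt.time_query, vt.event_query)
            result.validation_trace.append((it, vloss))
            if vloss < best_val - 1e-9:
                best_val, best_params, bad = vloss, net.params, 0
            else:
                bad += 1
                if bad >= cfg.patience:
                    logger.info("meta-validation early stop at iteration %d", it)
                    break
        if cfg.tasks_per_batch is None or cfg.tasks_per_batch >= len(tasks):
            batch = tasks
        else:
            idx = rng.choice(len(tasks), size=cfg.tasks_per_batch, replace=False)
            batch = [tasks[i] for i in idx]
        total: Params = [(np.zeros_like(W), np.zeros_like(b)) for W, b in net.params]
        outer_loss = 0.0
        task_losses = {}
        for task in batch:
            q_loss, g = task_meta_gradient(net, task, cfg)
            outer_loss += q_loss
            task_losses[task.name] = q_loss
            total = _axpy(total, g, 1.0)
        if not np.isfinite(outer_loss):
            warnings.warn(
                f"meta-training diverged at iteration {it}; keeping last finite state",
                stacklevel=2,
            )
            result.network = RiskNetwork(last_good, dict(init.meta))
            result.diverged = True
            return result
        last_good = net.params
        net = RiskNetwork(opt.step(net.params, total), net.meta)
        result.loss_trace.append(outer_loss)
        result.per_task_trace.append(task_losses)
        # plateau stop on the outer loss
        w = cfg.plateau_window
        if it >= 2 * w and abs(
            np.mean(result.loss_trace[-w:]) - np.mean(result.loss_trace[-2 * w : -w])
        ) < cfg.plateau_tol:
            logger.info("outer loss plateau at iteration %d", it)
            break
    if validation_tasks is not None:
        result.network = RiskNetwork(best_params, dict(init.meta))
    else:
        result.network = net
    return result


def finetune_evaluate(
    meta_net: RiskNetwork,
    task: TaskData,
    cfg: MetaConfig,
    steps: int | None = None,
    compute_brier: bool = True,
) -> tuple[RiskNetwork, np.ndarray, MetricResult]:
    """Adapt on the target support set, then score the query set.

    Returns the adapted network, the query log-risks, and a MetricResult
    with the C-index (and integrated Brier score from a Breslow baseline
    estimated on the adapted support set).
    """
    if len(task.X_support) == 0 or len(task.X_query) == 0:
        raise ValueError("target task needs nonempty support and query sets")
    n_steps = cfg.finetune_steps if steps is None else steps
    adapted = inner_adapt(
        meta_net, task.X_support, task.time_support, task.event_support, cfg, steps=n_steps
    )
    eta_q = adapted.forward(task.X_query)
    baseline = None
    if compute_brier and task.event_support.sum() > 0:
        eta_s = adapted.forward(task.X_support)
        baseline = breslow_baseline(eta_s, task.time_support, task.event_support)
    res = evaluate_predictions(
        eta_q, task.time_query, task.event_query, baseline=baseline
    )
    return adapted, eta_q, res


def direct_learning_baseline(
    source_tasks: list[TaskData],
    target_tasks: list[TaskData],
    n_features: int | None = None,
    hidden=(32, 16, 8),
    folds: int = 5,
    lr: float = 0.0001,
    max_epochs: int = 500,
    patience: int = 10,
    seed: int = 0,
) -> dict[str, MetricResult]:
    """Train one network on all pooled source support data; evaluate per target.

    The 5-fold structure selects the stopping epoch: for each fold, train on
    the remainder and track the fold's validation Cox loss; the final model
    is retrained on everything for the mean best-epoch count.
    """
    X = np.vstack([t.X_support for t in source_tasks])
    time = np.concatenate([t.time_support for t in source_tasks])
    event = np.concatenate([t.event_support for t in source_tasks])
    n = len(X)
    if n == 0:
        raise ValueError("empty pooled training data")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds

    def train(Xt, tt, et, epochs, X_val=None, t_val=None, e_val=None):
        net = RiskNetwork.init(Xt.shape[1], hidden=hidden, seed=seed)
        opt = _Adam(net.params, lr)
        best, best_epoch, bad = np.inf, 0, 0
        for ep in range(epochs):
            _, grads = cox_param_grad(net, Xt, tt, et)
            net = RiskNetwork(opt.step(net.params, grads), net.meta)
            if X_val is not None:
                val_loss, _ = cox_param_grad(net, X_val, t_val, e_val)
                if val_loss < best - 1e-6:
                    best, best_epoch, bad = val_loss, ep + 1, 0
                else:
                    bad += 1
                    if bad >= patience:
                        break
        return net, best_epoch

    best_epochs = []
    for f in range(folds):
        tr, va = fold_of != f, fold_of == f
        if event[tr].sum() == 0 or event[va].sum() == 0:
            continue
        _, be = train(X[tr], time[tr], event[tr], max_epochs, X[va], time[va], event[va])
        best_epochs.append(max(be, 1))
    n_epochs = int(np.mean(best_epochs)) if best_epochs else max_epochs
    net, _ = train(X, time, event, n_epochs)

    results: dict[str, MetricResult] = {}
    for task in target_tasks:
        eta_q = net.forward(task.X_query)
        baseline = None
        if event.sum() > 0:
            baseline = breslow_baseline(net.forward(X), time, event)
        results[task.name] = evaluate_predictions(
            eta_q, task.time_query, task.event_query, baseline=baseline
        )
    return results


def make_task_data(matrix, survival, splits: list[TaskSplit]) -> list[TaskData]:
    """Materialise per-task arrays from an OmicsMatrix and a survival table.

    ``survival`` is a DataFrame indexed by patient ID with ``time`` and
    ``event`` columns; patients missing from the matrix (e.g. dropped during
    integration) are silently excluded from their split.
    """
    tasks = []
    have = set(matrix.patient_ids)
    for split in splits:
        sup = [p for p in split.support_ids if p in have]
        qry = [p for p in split.query_ids if p in have]
        tasks.append(
            TaskData(
                name=split.task_name,
                X_support=matrix.data.loc[sup].to_numpy(dtype=float),
                time_support=survival.loc[sup, "time"].to_numpy(dtype=float),
                event_support=survival.loc[sup, "event"].to_numpy(dtype=int),
                X_query=matrix.data.loc[qry].to_numpy(dtype=float),
                time_query=survival.loc[qry, "time"].to_numpy(dtype=float),
                event_query=survival.loc[qry, "event"].to_numpy(dtype=int),
            )
        )
    return tasks


def pooled_folds(n: int, folds: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment covering every sample exactly once as validation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds
    return fold_of
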