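"""Multi-task, multi-block synthetic survival cohorts with known ground truth.

The generator emulates the shape of an integrated pan-cancer cohort:

* many tasks ("cancer types") of very different support sizes, each with a
  fixed-size query set (30 by default);
* three feature blocks of very different widths — a small clinical-like
  block with categorical columns, a wide transcriptomic-like block, and a
  mid-width proteomic-like block;
* equicorrelated feature groups (so the 0.7 Pearson filter has work to do)
  and missing values in the clinical/proteomic blocks;
* proportional-hazards event times: a sparse linear log-risk
  eta_i = x_i . beta_task shared across tasks up to a per-task perturbation,
  with the transcriptomic signal features grouped into planted gene sets
  (>= 30 members so they survive the co-enrichment size filter);
* event times ~ Exponential(rate = exp(eta)/baseline_scale) and independent
  uniform censoring on [0, c], with c solved per task so the realised
  censoring fraction hits the requested target;
* per-task censoring targets spanning the heterogeneity seen in real
  pan-cancer cohorts (roughly 30-86% censored).

Everything is driven by one integer seed; identical specs give
bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coenrichment import GeneSetCollection
from .matrix import CATEGORICAL, NUMERIC, OmicsMatrix
from .maml import TaskSplit

BLOCKS = ("clinical", "transcriptomics", "proteomics")

# support sizes and censored fractions of a 17-task pan-cancer cohort
# (14 source + 3 target), used as the default task layout
DEFAULT_SUPPORT_SIZES = (
    16, 840, 139, 290, 95, 27, 175, 395, 286, 189, 68, 18, 361, 302,  # source
    308, 308, 320,  # target
)
DEFAULT_CENSORING = (
    0.696, 0.861, 0.817, 0.778, 0.648, 0.298, 0.854, 0.772, 0.592, 0.352,
    0.429, 0.354, 0.826, 0.602,
    0.547, 0.500, 0.600,
)


@dataclass
class CohortSpec:
    """Generative conditions for one synthetic cohort."""

    n_tasks: int = 17
    n_target_tasks: int = 3
    support_sizes: tuple = DEFAULT_SUPPORT_SIZES
    query_size: int = 30
    block_dims: tuple = (20, 200, 60)  # clinical, transcriptomic, proteomic widths
    n_categorical_clinical: int = 5
    n_signal_features: int = 60  # transcriptomic signal (inside planted sets)
    n_signal_clinical: int = 2
    n_signal_proteomic: int = 2
    n_planted_sets: int = 2
    planted_set_size: int = 30
    censoring_target: tuple | float = DEFAULT_CENSORING
    correlation_groups: int = 5  # equicorrelated groups in the transcriptomic block
    correlation_group_size: int = 4
    rho: float = 0.5
    missing_rate: float = 0.01
    baseline_scale: float = 10.0
    coef_scale: float = 1.0
    task_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tasks <= 0 or self.query_size <= 0:
            raise ValueError("counts must be positive")
        if len(self.support_sizes) != self.n_tasks:
            raise ValueError("need one support size per task")
        if any(s <= 0 for s in self.support_sizes):
            raise ValueError("support sizes must be positive")
        if not np.isscalar(self.censoring_target) and len(self.censoring_target) != self.n_tasks:
            raise ValueError(
                "censoring_target must be a scalar or give one value per task"
            )
        targets = self.censoring_targets()
        if any(not 0 <= c < 1 for c in targets):
            raise ValueError("censoring_target must lie in [0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.task_effect_sd < 0 or self.baseline_scale <= 0:
            raise ValueError("task_effect_sd >= 0 and baseline_scale > 0 required")
        if self.n_planted_sets * self.planted_set_size > self.block_dims[1]:
            raise ValueError("planted sets exceed the transcriptomic block width")
        if self.n_signal_features > self.n_planted_sets * self.planted_set_size:
            raise ValueError("signal features must fit inside the planted sets")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def censoring_targets(self) -> list[float]:
        if np.isscalar(self.censoring_target):
            return [float(self.censoring_target)] * self.n_tasks
        return [float(c) for c in self.censoring_target]

    @property
    def n_patients(self) -> int:
        return sum(self.support_sizes) + self.n_tasks * self.query_size


@dataclass
class GroundTruth:
    shared_coefficients: pd.Series  # per integrated feature
    task_coefficients: dict  # task name -> pd.Series
    planted_set_membership: dict  # set name -> list of feature names
    true_risk: pd.Series  # per patient


@dataclass
class Cohort:
    blocks: dict  # block name -> OmicsMatrix (with injected missingness)
    survival: pd.DataFrame  # id, time, event
    tasks: list  # TaskSplit
    truth: GroundTruth
    spec: CohortSpec


def _feature_names(spec: CohortSpec) -> dict:
    c, t, p = spec.block_dims
    return {
        "clinical": [f"clin_{i:03d}" for i in range(c)],
        "transcriptomics": [f"gene_{i:05d}" for i in range(t)],
        "proteomics": [f"prot_{i:03d}" for i in range(p)],
    }


def _calibrate_censoring(T: np.ndarray, U: np.ndarray, target: float) -> float:
    """Solve for c so that mean(U*c < T) ~= target, by bisection.

    The censoring fraction is monotone decreasing in c; U are fixed
    uniform(0,1) draws so the solution is exact for the realised sample.
    """
    if target <= 0:
        return np.inf

    def frac(c):
        return float((U * c < T).mean())

    lo, hi = 1e-12, float(T.max()) / max(U.min(), 1e-12) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw features, risks, event and censoring times, and task splits."""
    rng = np.random.default_rng(spec.seed)
    names = _feature_names(spec)
    n = spec.n_patients
    c_dim, t_dim, p_dim = spec.block_dims

    ids = [f"P{i:06d}" for i in range(n)]

    # --- task assignment: contiguous blocks of support+query per task
    task_names = [f"task{i:02d}" for i in range(spec.n_tasks)]
    task_of = np.empty(n, dtype=int)
    splits: list[TaskSplit] = []
    start = 0
    for ti, sz in enumerate(spec.support_sizes):
        sup = ids[start : start + sz]
        qry = ids[start + sz : start + sz + spec.query_size]
        task_of[start : start + sz + spec.query_size] = ti
        role = "target" if ti >= spec.n_tasks - spec.n_target_tasks else "source"
        splits.append(TaskSplit(task_names[ti], sup, qry, role))
        start += sz + spec.query_size

    # --- clinical block: numeric + small-cardinality categorical levels
    n_cat = min(spec.n_categorical_clinical, c_dim)
    clin_num = rng.normal(size=(n, c_dim - n_cat))
    cat_levels = rng.integers(2, 5, size=n_cat)
    clin_cat = np.empty((n, n_cat), dtype=object)
    for j in range(n_cat):
        clin_cat[:, j] = np.array(
            [f"lvl{v}" for v in rng.integers(0, cat_levels[j], size=n)]
        )

    # --- transcriptomic block: equicorrelated groups at rho, rest iid
    trans = rng.normal(size=(n, t_dim))
    grp_cols = []
    col = spec.n_planted_sets * spec.planted_set_size  # keep planted sets iid
    for _ in range(spec.correlation_groups):
        cols = list(range(col, min(col + spec.correlation_group_size, t_dim)))
        if len(cols) < 2:
            break
        shared = rng.normal(size=n)
        for j in cols:
            trans[:, j] = np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * trans[:, j]
        grp_cols.append(cols)
        col += spec.correlation_group_size

    # --- proteomic block: iid numeric
    prot = rng.normal(size=(n, p_dim))

    # --- planted sets and signal coefficients
    planted = {}
    for s in range(spec.n_planted_sets):
        members = names["transcriptomics"][
            s * spec.planted_set_size : (s + 1) * spec.planted_set_size
        ]
        planted[f"planted_set_{s}"] = list(members)
    planted_pool = [g for mem in planted.values() for g in mem]
    signal_trans = planted_pool[: spec.n_signal_features]

    all_names = names["clinical"] + names["transcriptomics"] + names["proteomics"]
    beta = pd.Series(0.0, index=all_names)
    signs = rng.choice([-1.0, 1.0], size=spec.n_signal_features)
    beta[signal_trans] = signs * spec.coef_scale
    clin_sig = [nm for nm in names["clinical"][n_cat:][: spec.n_signal_clinical]]
    prot_sig = names["proteomics"][: spec.n_signal_proteomic]
    beta[clin_sig] = rng.choice([-1.0, 1.0], size=len(clin_sig)) * spec.coef_scale
    beta[prot_sig] = rng.choice([-1.0, 1.0], size=len(prot_sig)) * spec.coef_scale
    signal_names = signal_trans + clin_sig + list(prot_sig)

    task_betas = {}
    for ti, tname in enumerate(task_names):
        pert = pd.Series(0.0, index=all_names)
        if spec.task_effect_sd > 0:
            pert[signal_names] = rng.normal(0.0, spec.task_effect_sd, len(signal_names))
        task_betas[tname] = beta + pert

    # --- linear risk on the complete numeric matrix (pre-missingness)
    X_full = np.hstack([clin_num, trans, prot])
    numeric_names = names["clinical"][n_cat:] + names["transcriptomics"] + names["proteomics"]
    eta = np.empty(n)
    B = np.stack([task_betas[task_names[t]][numeric_names].to_numpy() for t in range(spec.n_tasks)])
    for ti in range(spec.n_tasks):
        rows = task_of == ti
        eta[rows] = X_full[rows] @ B[ti]

    # --- exponential PH event times and per-task uniform censoring
    T = rng.exponential(scale=spec.baseline_scale * np.exp(-eta))
    U = rng.uniform(size=n)
    time = T.copy()
    event = np.ones(n, dtype=int)
    for ti, target in enumerate(spec.censoring_targets()):
        rows = np.flatnonzero(task_of == ti)
        c = _calibrate_censoring(T[rows], U[rows], target)
        if np.isfinite(c):
            cens = U[rows] * c
            censored = cens < T[rows]
            time[rows] = np.where(censored, cens, T[rows])
            event[rows] = (~censored).astype(int)

    # --- inject missingness (numeric cells of clinical/proteomic blocks)
    clin_num_miss = clin_num.copy()
    prot_miss = prot.copy()
    if spec.missing_rate > 0:
        for arr in (clin_num_miss, prot_miss):
            mask = rng.uniform(size=arr.shape) < spec.missing_rate
            # keep at least one observed value per column
            mask[:, mask.all(axis=0)] = False
            arr[mask] = np.nan

    # --- assemble blocks
    clin_df = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    for j in range(n_cat):
        clin_df[names["clinical"][j]] = clin_cat[:, j]
    for j, nm in enumerate(names["clinical"][n_cat:]):
        clin_df[nm] = clin_num_miss[:, j]
    clin_df = clin_df[names["clinical"]]
    clin_kinds = pd.Series(
        [CATEGORICAL] * n_cat + [NUMERIC] * (c_dim - n_cat), index=names["clinical"]
    )
    blocks = {
        "clinical": OmicsMatrix(
            clin_df, pd.Series("clinical", index=names["clinical"]), clin_kinds
        ),
        "transcriptomics": OmicsMatrix(
            pd.DataFrame(trans, index=clin_df.index, columns=names["transcriptomics"]),
            pd.Series("transcriptomics", index=names["transcriptomics"]),
        ),
        "proteomics": OmicsMatrix(
            pd.DataFrame(prot_miss, index=clin_df.index, columns=names["proteomics"]),
            pd.Series("proteomics", index=names["proteomics"]),
        ),
    }

    survival = pd.DataFrame(
        {"patient_id": ids, "time": time, "event": event}
    ).set_index("patient_id")

    truth = GroundTruth(
        shared_coefficients=beta,
        task_coefficients=task_betas,
        planted_set_membership=planted,
        true_risk=pd.Series(eta, index=clin_df.index),
    )
    return Cohort(blocks, survival, splits, truth, spec)


def generate_scores_with_planted_clusters(
    truth: GroundTruth,
    noise_sd: float,
    seed: int,
    n_background: int | None = None,
    centers: dict | None = None,
) -> pd.Series:
    """Per-feature scores in which planted-set members share a set-level centre.

    Members of set k score centre_k + N(0, noise_sd); every other
    transcriptomic feature scores N(0, sqrt(1 + noise_sd^2)), so the
    background spread tracks the member noise.  With noise_sd = 0 each set's
    members tie exactly and the score-sorted list places them contiguously;
    as noise_sd grows the set structure washes out into the background.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sets = truth.planted_set_membership
    if centers is None:
        centers = {
            name: float(len(sets) - k + 3) for k, name in enumerate(sets)
        }
    genes = [g for g in truth.shared_coefficients.index if g.startswith("gene_")]
    scores = pd.Series(
        rng.normal(0.0, np.sqrt(1.0 + noise_sd**2), len(genes)), index=genes
    )
    for name, members in sets.items():
        scores[members] = centers[name] + (
            rng.normal(0.0, noise_sd, len(members)) if noise_sd > 0 else 0.0
        )
    return scores


# -- on-disk dialect -------------------------------------------------------


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write TSV blocks, survival/task tables, planted-set GMT and truth JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, mat in cohort.blocks.items():
        p = os.path.join(outdir, f"{name}.tsv")
        mat.to_tsv(p)
        paths[name] = p
    p = os.path.join(outdir, "survival.tsv")
    cohort.survival.to_csv(p, sep="\t")
    paths["survival"] = p
    rows = []
    for split in cohort.tasks:
        rows += [(pid, split.task_name, split.role, "support") for pid in split.support_ids]
        rows += [(pid, split.task_name, split.role, "query") for pid in split.query_ids]
    tasks_df = pd.DataFrame(rows, columns=["patient_id", "task", "role", "split"])
    p = os.path.join(outdir, "tasks.tsv")
    tasks_df.to_csv(p, sep="\t", index=False)
    paths["tasks"] = p
    p = os.path.join(outdir, "planted_sets.gmt")
    GeneSetCollection(cohort.truth.planted_set_membership).to_gmt(p, "planted")
    paths["gene_sets"] = p
    p = os.path.join(outdir, "ground_truth.json")
    with open(p, "w") as fh:
        json.dump(
            {
                "shared_coefficients": cohort.truth.shared_coefficients.to_dict(),
                "task_coefficients": {
                    k: v.to_dict() for k, v in cohort.truth.task_coefficients.items()
                },
                "planted_set_membership": cohort.truth.planted_set_membership,
                "true_risk": cohort.truth.true_risk.to_dict(),
            },
            fh,
        )
    paths["ground_truth"] = p
    return paths


def read_task_table(path) -> list[TaskSplit]:
    df = pd.read_csv(path, sep="\t")
    splits = []
    for (task, role), grp in df.groupby(["task", "role"], sort=True):
        sup = grp.loc[grp["split"] == "support", "patient_id"].tolist()
        qry = grp.loc[grp["split"] == "query", "patient_id"].tolist()
        splits.append(TaskSplit(task, sup, qry, role))
    return sorted(splits, key=lambda s: s.task_name)
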