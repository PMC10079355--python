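"""DeepLIFT contribution scores for the risk network (Rescale rule).

DeepLIFT explains the difference between the network's output at an input x
and at a reference input x0 by propagating multipliers backwards: linear
layers pass multipliers through their weights (biases cancel in the
difference), and each ReLU uses the Rescale rule

    m = (relu(z) - relu(z0)) / (z - z0)      when |z - z0| > eps,
    m = relu'(z0)                            otherwise,

so that per-feature contributions phi_i = m_i * (x_i - x0_i) satisfy
summation-to-delta exactly: sum_i phi_i = f(x) - f(x0).

The reference is a cohort statistic: the per-feature median or mean over
deceased (event = 1) or censored-alive (event = 0) patients; the paper's
selected default is the median over deceased patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import RiskNetwork

RELU_EPS = 1e-7

STRATEGIES = ("median_deceased", "mean_deceased", "median_survived", "mean_survived", "custom")
DEFAULT_STRATEGY = "median_deceased"


@dataclass
class ReferenceSpec:
    strategy: str
    reference_vector: np.ndarray

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown reference strategy {self.strategy!r}")
        self.reference_vector = np.asarray(self.reference_vector, dtype=float)


@dataclass
class AttributionVector:
    feature_names: list
    contributions: np.ndarray
    output_delta: float
    reference: ReferenceSpec

    def summation_gap(self) -> float:
        return float(abs(self.contributions.sum() - self.output_delta))


def build_reference(
    X: np.ndarray,
    event: np.ndarray,
    strategy: str = DEFAULT_STRATEGY,
    custom_vector: np.ndarray | None = None,
) -> ReferenceSpec:
    """Materialise the reference vector from the chosen patient stratum."""
    if strategy == "custom":
        if custom_vector is None:
            raise ValueError("custom strategy requires a reference vector")
        return ReferenceSpec("custom", custom_vector)
    stat, stratum = strategy.split("_")
    event = np.asarray(event).astype(bool)
    mask = event if stratum == "deceased" else ~event
    if not mask.any():
        raise ValueError(f"empty stratum: no {stratum} patients")
    rows = np.asarray(X, dtype=float)[mask]
    vec = np.median(rows, axis=0) if stat == "median" else rows.mean(axis=0)
    return ReferenceSpec(strategy, vec)


def attribute(
    net: RiskNetwork, x: np.ndarray, ref: ReferenceSpec, feature_names=None
) -> AttributionVector:
    """Per-feature contribution scores for one patient."""
    x = np.asarray(x, dtype=float).ravel()
    x0 = ref.reference_vector
    if x.shape != x0.shape or len(x) != net.n_features:
        raise ValueError("input / reference width must match the network input width")
    eta_x, (_, pre_x) = net.forward(x[None, :], cache=True)
    eta_r, (_, pre_r) = net.forward(x0[None, :], cache=True)
    delta_out = float(eta_x[0] - eta_r[0])
    if not np.isfinite(delta_out):
        raise ValueError("non-finite network output")

    # backward multiplier pass; m has shape (layer_width,)
    m = np.ones(1)
    last = len(net.params) - 1
    for i in range(last, -1, -1):
        W, _ = net.params[i]
        if i < last:
            z, z0 = pre_x[i][0], pre_r[i][0]
            dz = z - z0
            rescale = np.where(
                np.abs(dz) > RELU_EPS,
                (np.maximum(z, 0) - np.maximum(z0, 0)) / np.where(dz == 0, 1.0, dz),
                (z0 > 0).astype(float),
            )
            m = m * rescale
        m = W @ m
    phi = m * (x - x0)
    names = list(feature_names) if feature_names is not None else list(range(len(x)))
    return AttributionVector(names, phi, delta_out, ref)


def cohort_attribution(
    net: RiskNetwork,
    X: np.ndarray,
    ref: ReferenceSpec,
    aggregate: str = "mean",
    feature_names=None,
) -> np.ndarray:
    """Feature-wise aggregate of per-patient contribution scores."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phis = np.stack([attribute(net, row, ref).contributions for row in X])
    if aggregate == "mean":
        return phis.mean(axis=0)
    if aggregate == "median":
        return np.median(phis, axis=0)
    raise ValueError(f"unknown aggregate {aggregate!r}")


@dataclass
class GeneLists:
    """Ranked (GSEA .rnk) and mean-filtered (g:Profiler query) gene lists."""

    ranked: list  # (feature, score) sorted by score descending
    filtered: list  # features with score >= mean score
    metadata: dict = field(default_factory=dict)


def export_gene_lists(
    scores: np.ndarray, feature_names, reference_strategy: str = DEFAULT_STRATEGY
) -> GeneLists:
    """Build downstream-tool inputs from cohort contribution scores.

    The ranked list carries every feature sorted by score (pre-ranked GSEA
    input); the filtered list keeps features scoring at or above the mean
    score (g:Profiler query).  Downstream significance conventions are
    recorded in the metadata (g:Profiler adjusted p < 0.05, GSEA FDR
    q < 0.25) but not applied here.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite attribution scores")
    names = list(feature_names)
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    ranked = [(names[i], float(scores[i])) for i in order]
    mean_score = scores.mean()
    filtered = [names[i] for i in order if scores[i] >= mean_score]
    return GeneLists(
        ranked,
        filtered,
        metadata={
            "reference_strategy": reference_strategy,
            "filter_rule": "score >= mean(score)",
            "gprofiler_significance": "adjusted p < 0.05",
            "gsea_significance": "FDR q < 0.25",
        },
    )


def write_gene_lists(lists: GeneLists, rnk_path, filtered_path, sidecar_path=None) -> None:
    import json

    with open(rnk_path, "w") as fh:
        for name, score in lists.ranked:
            fh.write(f"{name}\t{score:.10g}\n")
    with open(filtered_path, "w") as fh:
        fh.write("\n".join(lists.filtered) + "\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(lists.metadata, fh, indent=2)
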