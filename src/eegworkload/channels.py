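"""mRMR channel selection on a single feature's per-channel values.

Relevance of a channel set S with respect to the class variable c is
D = (1/|S|) sum_i I(x_i; c); redundancy is R = (1/|S|^2) sum_ij I(x_i, x_j);
the selection criterion is max phi = D - R. The standard greedy incremental
realization is used: the first channel maximizes I(x_i; c), and step m adds
the channel maximizing I(x_i; c) - (1/|S|) sum_{j in S} I(x_i; x_j), ties
broken by lowest channel index.

Mutual information is a plugin estimate in bits on discretized values
(equal-frequency binning by default, 8 bins): the estimator the analysis
needs but that the selection criterion itself leaves open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIEstimatorConfig",
    "ChannelRanking",
    "ConsensusReport",
    "discretize",
    "mutual_information",
    "mrmr_select",
    "consensus",
]


@dataclass(frozen=True)
class MIEstimatorConfig:
    discretization: str = "equal_frequency"  # or "equal_width"
    n_bins: int = 8
    unit: str = "bits"

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.discretization not in ("equal_frequency", "equal_width"):
            raise ValueError("discretization must be equal_frequency or equal_width")
        if self.unit not in ("bits", "nats"):
            raise ValueError("unit must be bits or nats")


def discretize(x: np.ndarray, config: MIEstimatorConfig = MIEstimatorConfig()) -> np.ndarray:
    """Integer bin codes for a sample vector.

    Vectors that are already discrete (at most n_bins distinct values, or
    non-float dtype) are label-encoded unchanged; continuous vectors are
    binned by quantiles (equal_frequency) or uniformly (equal_width).
    Duplicate quantile edges (heavy ties) collapse into fewer bins.
    """
    x = np.asarray(x)
    uniq = np.unique(x)
    if uniq.size <= config.n_bins or not np.issubdtype(x.dtype, np.floating):
        return np.searchsorted(uniq, x)
    if config.discretization == "equal_frequency":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, config.n_bins + 1)[1:-1]))
    else:
        edges = np.linspace(x.min(), x.max(), config.n_bins + 1)[1:-1]
    return np.searchsorted(edges, x, side="right")


def _mi_from_contingency(counts: np.ndarray, unit: str = "bits") -> float:
    """Plugin MI of a joint count table: sum p log(p / (p_row p_col))."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    mi = max(mi, 0.0)  # clip -0.0 / rounding
    return mi / np.log(2.0) if unit == "bits" else mi


def mutual_information(
    x: np.ndarray, y: np.ndarray, config: MIEstimatorConfig = MIEstimatorConfig()
) -> float:
    """Plugin mutual information between two (discretized) sample vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    cx = discretize(x, config)
    cy = discretize(y, config)
    counts = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(counts, (cx, cy), 1.0)
    return _mi_from_contingency(counts, config.unit)


@dataclass
class StepRecord:
    channel: int        # column index into channel_data
    label: str
    relevance: float    # D term of the added channel: I(x_i; c)
    redundancy: float   # R term: mean I(x_i; x_j) over already-selected j
    phi: float          # D - R


@dataclass
class ChannelRanking:
    subject_id: str
    order: list[int]                    # selected column indices, in order
    labels: list[str]                   # channel labels, same order
    steps: list[StepRecord] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.order)


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    _, codes = np.unique(y, return_inverse=True)
    return codes


def mrmr_select(
    channel_data: np.ndarray,
    labels,
    k: int = 10,
    channel_labels: tuple[str, ...] | None = None,
    subject_id: str = "",
    config: MIEstimatorConfig = MIEstimatorConfig(),
) -> ChannelRanking:
    """Greedy mRMR forward selection of k channels.

    channel_data is (n_epochs, n_channels); labels is the per-epoch class.
    Per-step relevance, redundancy and phi are logged in the result. Ties
    break toward the lowest channel index.
    """
    X = np.asarray(channel_data, dtype=float)
    if X.ndim != 2:
        raise ValueError("channel_data must be (n_epochs, n_channels)")
    n_ep, n_ch = X.shape
    if not 1 <= k <= n_ch:
        raise ValueError(f"k={k} must be in [1, {n_ch}]")
    y = _encode_labels(labels)
    if y.size != n_ep:
        raise ValueError("labels length must match n_epochs")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n_ch))

    codes = [discretize(X[:, i], config) for i in range(n_ch)]
    relevance = np.array([
        mutual_information(codes[i], y, config) for i in range(n_ch)
    ])
    pair_cache: dict[tuple[int, int], float] = {}

    def pair_mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pair_cache:
            pair_cache[key] = mutual_information(codes[i], codes[j], config)
        return pair_cache[key]

    selected: list[int] = []
    steps: list[StepRecord] = []
    remaining = list(range(n_ch))
    for _ in range(k):
        best, best_phi, best_red = None, -np.inf, 0.0
        for i in remaining:
            red = (
                float(np.mean([pair_mi(i, j) for j in selected]))
                if selected else 0.0
            )
            phi = relevance[i] - red
            if phi > best_phi:  # strict: first (lowest) index wins ties
                best, best_phi, best_red = i, phi, red
        selected.append(best)
        remaining.remove(best)
        steps.append(StepRecord(
            channel=best,
            label=channel_labels[best],
            relevance=float(relevance[best]),
            redundancy=best_red,
            phi=float(best_phi),
        ))
    return ChannelRanking(
        subject_id=subject_id,
        order=selected,
        labels=[channel_labels[i] for i in selected],
        steps=steps,
    )


@dataclass
class ConsensusReport:
    counts: dict[str, int]          # channel label -> subjects listing it
    frequencies: dict[str, float]
    selected: list[str]             # frequency strictly above threshold
    threshold: float
    n_subjects: int


def consensus(rankings: list[ChannelRanking], threshold: float = 0.8) -> ConsensusReport:
    """Cross-subject frequency consensus over top-k channel lists.

    A channel is selected when it appears in STRICTLY more than
    ``threshold`` of the subjects' lists (8 of 10 at threshold 0.8 is not
    enough).
    """
    if not rankings:
        raise ValueError("rankings must be non-empty")
    counts: dict[str, int] = {}
    for r in rankings:
        for lab in r.labels:
            counts[lab] = counts.get(lab, 0) + 1
    n = len(rankings)
    freqs = {lab: c / n for lab, c in counts.items()}
    selected = sorted([lab for lab, f in freqs.items() if f > threshold],
                      key=lambda lab: -freqs[lab])
    return ConsensusReport(
        counts=counts, frequencies=freqs, selected=selected,
        threshold=threshold, n_subjects=n,
    )
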