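"""Conductance-histogram featurization and design-matrix assembly.

Classifier features are *H-sample conductance histograms*: the pooled
samples of H valid conductance traces, counted into ``n_bins`` bins
spaced uniformly in log10(G/G0) over a fixed range, with the two
terminal bins dropped and the rest renormalized to a probability
vector.  Terminal bins absorb everything at or beyond the range ends —
including the spikes that current clipping piles up at the
preamplifier limits — which is exactly why they are trimmed.

Trace pools are split into train/test at the *trace* level, so no trace
ever contributes samples to histograms on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preprocess import ConductanceTrace

__all__ = [
    "HistogramConfig",
    "ConductanceHistogram",
    "LabelingScheme",
    "DesignMatrix",
    "DegenerateHistogramError",
    "bin_edges",
    "trace_bin_counts",
    "build_histogram",
    "split_traces",
    "sample_histogram_set",
    "apply_labeling",
    "tls1",
    "tls2",
]


class DegenerateHistogramError(ValueError):
    """All pooled samples fell into the trimmed terminal bins."""


@dataclass(frozen=True)
class HistogramConfig:
    """Binning parameters for conductance histograms.

    Attributes
    ----------
    n_bins : int
        Number of log-spaced bins before trimming; the feature length is
        ``n_bins - 2`` when ``trim_edges``.
    h : int
        Number of valid traces pooled into one histogram.
    log_range : (float, float)
        Exponent range of G/G0 covered by the bins.  The default
        [-7, 0] spans the conductances reachable inside the 10 pA -
        100 nA preamplifier window at the study's bias voltages.
    trim_edges : bool
        Drop the first and last bin (clipping-spike guards).
    """

    n_bins: int = 600
    h: int = 30
    log_range: tuple[float, float] = (-7.0, 0.0)
    trim_edges: bool = True

    def __post_init__(self) -> None:
        if self.trim_edges and self.n_bins < 3:
            raise ValueError("n_bins must be >= 3 when trimming edges")
        if self.n_bins < 1 or self.h < 1:
            raise ValueError("n_bins and h must be positive")
        if not self.log_range[0] < self.log_range[1]:
            raise ValueError("log_range must be increasing")

    @property
    def feature_length(self) -> int:
        return self.n_bins - 2 if self.trim_edges else self.n_bins


@dataclass(frozen=True)
class ConductanceHistogram:
    """Trimmed, normalized probability vector over log-conductance bins."""

    probabilities: np.ndarray
    bin_edges: np.ndarray
    class_label: str = ""
    member_trace_ids: tuple[str, ...] = ()
    #: untrimmed integer counts, kept for auditing and bin-refinement checks
    counts: np.ndarray | None = None


@dataclass(frozen=True)
class LabelingScheme:
    """Mapping from dataset labels to target class indices."""

    name: str
    mapping: Mapping[str, int]

    @property
    def n_classes(self) -> int:
        return len(set(self.mapping.values()))


def tls1() -> LabelingScheme:
    """Label by strand: the five same-strand datasets collapse to one class (6 total)."""
    mapping = {"S1": 0, "S2": 1, "S6": 1, "S7": 1, "S8": 1, "S9": 1,
               "S3": 2, "S4": 3, "S5": 4, "S10": 5}
    return LabelingScheme("TLS-1", mapping)


def tls2() -> LabelingScheme:
    """Label by (strand, bias) tuple: 8 classes over the ten datasets."""
    mapping = {"S1": 0, "S2": 1, "S8": 1, "S3": 2, "S4": 3, "S5": 4,
               "S6": 5, "S9": 5, "S7": 6, "S10": 7}
    return LabelingScheme("TLS-2", mapping)


def identity_scheme(labels: Iterable[str]) -> LabelingScheme:
    """One class per dataset label, indices in sorted label order."""
    return LabelingScheme("identity", {lab: i for i, lab in enumerate(sorted(set(labels)))})


@dataclass(frozen=True)
class DesignMatrix:
    """Labeled histogram feature matrix for training or testing."""

    features: np.ndarray
    labels: np.ndarray
    scheme: LabelingScheme
    seed: int
    member_trace_ids: tuple[tuple[str, ...], ...] = ()

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])


def bin_edges(cfg: HistogramConfig) -> np.ndarray:
    """The ``n_bins + 1`` bin edges, in log10(G/G0)."""
    return np.linspace(cfg.log_range[0], cfg.log_range[1], cfg.n_bins + 1)


def trace_bin_counts(trace: ConductanceTrace, cfg: HistogramConfig) -> np.ndarray:
    """Integer bin counts of one trace's samples (untrimmed).

    Out-of-range samples land in the terminal bins.  Non-positive values
    (possible after low-pass overshoot near clip edges) are treated as
    below-range and land in the first bin, which trimming discards.
    """
    low, high = cfg.log_range
    width = (high - low) / cfg.n_bins
    values = trace.values
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(values > 0, np.log10(np.where(values > 0, values, 1.0)), -np.inf)
    idx = np.floor((logv - low) / width)
    idx = np.clip(idx, 0, cfg.n_bins - 1).astype(np.intp)
    return np.bincount(idx, minlength=cfg.n_bins)


def _finalize(counts: np.ndarray, cfg: HistogramConfig) -> np.ndarray:
    if cfg.trim_edges:
        kept = counts[1:-1]
    else:
        kept = counts
    total = kept.sum()
    if total == 0:
        raise DegenerateHistogramError(
            "all pooled samples fell into the trimmed terminal bins"
        )
    return kept / total


def build_histogram(
    traces: Sequence[ConductanceTrace], cfg: HistogramConfig | None = None
) -> ConductanceHistogram:
    """Pool the samples of the given traces into one probability histogram.

    Deterministic: counts are exact integers summed per trace; trimming
    (when enabled) happens before renormalization, so the returned
    probabilities form a proper simplex vector of length ``n_bins - 2``.
    """
    cfg = cfg or HistogramConfig()
    if not traces:
        raise ValueError("cannot build a histogram from zero traces")
    counts = np.zeros(cfg.n_bins, dtype=np.int64)
    for trace in traces:
        counts += trace_bin_counts(trace, cfg)
    probs = _finalize(counts, cfg)
    return ConductanceHistogram(
        probabilities=probs,
        bin_edges=bin_edges(cfg),
        class_label=traces[0].dataset_label,
        member_trace_ids=tuple(t.source_trace_id for t in traces),
        counts=counts,
    )


def split_traces(
    pool: Mapping[str, Sequence[ConductanceTrace]],
    train_fraction: float,
    seed: int,
) -> tuple[dict[str, list[ConductanceTrace]], dict[str, list[ConductanceTrace]]]:
    """Per-class disjoint random partition of traces into train and test.

    The split is at the trace level: histograms built later from either
    side can never share a member trace, ruling out leakage.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: dict[str, list[ConductanceTrace]] = {}
    test: dict[str, list[ConductanceTrace]] = {}
    for label in sorted(pool):
        traces = list(pool[label])
        n = len(traces)
        k = int(round(train_fraction * n))
        if k == 0 or k == n:
            raise ValueError(
                f"class {label!r}: split {train_fraction} of {n} traces leaves a side empty"
            )
        order = rng.permutation(n)
        train[label] = [traces[i] for i in order[:k]]
        test[label] = [traces[i] for i in order[k:]]
    return train, test


def sample_histogram_set(
    pool: Mapping[str, Sequence[ConductanceTrace]],
    cfg: HistogramConfig,
    n_hist: int,
    seed: int,
    scheme: LabelingScheme | None = None,
) -> DesignMatrix:
    """Draw ``n_hist`` H-sample histograms per class into a design matrix.

    Within one histogram the ``cfg.h`` member traces are drawn uniformly
    *without* replacement; across the ``n_hist`` repetitions draws are
    independent, so traces are reusable between histograms.  Per-trace
    bin counts are precomputed once, making each draw a sum of count
    vectors — numerically identical to pooling the raw samples.
    """
    scheme = scheme or identity_scheme(pool.keys())
    rng = np.random.default_rng(seed)
    # histograms are drawn per target class: dataset labels mapping to the
    # same class contribute to one merged trace pool
    class_pools: dict[int, list[ConductanceTrace]] = {}
    class_names: dict[int, list[str]] = {}
    for label in sorted(pool):
        if label not in scheme.mapping:
            raise KeyError(f"label {label!r} not covered by scheme {scheme.name!r}")
        cls = scheme.mapping[label]
        class_pools.setdefault(cls, []).extend(pool[label])
        class_names.setdefault(cls, []).append(label)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    members: list[tuple[str, ...]] = []
    for cls in sorted(class_pools):
        traces = class_pools[cls]
        if len(traces) < cfg.h:
            raise ValueError(
                f"class {cls} ({'+'.join(class_names[cls])}) has only "
                f"{len(traces)} traces; need h={cfg.h}"
            )
        counts = np.stack([trace_bin_counts(t, cfg) for t in traces])
        ids = np.array([t.source_trace_id for t in traces])
        for _ in range(n_hist):
            pick = rng.choice(len(traces), size=cfg.h, replace=False)
            rows.append(_finalize(counts[pick].sum(axis=0), cfg))
            labels.append(cls)
            members.append(tuple(ids[pick]))
    return DesignMatrix(
        features=np.asarray(rows),
        labels=np.asarray(labels, dtype=np.intp),
        scheme=scheme,
        seed=seed,
        member_trace_ids=tuple(members),
    )


def apply_labeling(labels: Iterable[str], scheme: LabelingScheme) -> np.ndarray:
    """Map dataset labels to class indices; unmapped labels are an error."""
    out = []
    for lab in labels:
        if lab not in scheme.mapping:
            raise KeyError(f"label {lab!r} not covered by scheme {scheme.name!r}")
        out.append(scheme.mapping[lab])
    return np.asarray(out, dtype=np.intp)
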