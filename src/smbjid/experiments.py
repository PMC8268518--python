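"""Sensitivity sweeps, experiment-budget arithmetic and 2-D embeddings.

Orchestrates the study-level analyses on top of the lower modules:
sweeping the validity threshold beta, the bin count, or the
traces-per-histogram count H while holding the other baseline
parameters fixed; the expected number of junction pulls H/p needed to
collect H valid traces when each pull succeeds with probability p; and
qualitative t-SNE / metric-MDS maps of histogram feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import MDS, TSNE

from .classification import ClassifierConfig, EvaluationResult, repeat_protocol
from .histogramming import DesignMatrix, HistogramConfig, LabelingScheme, identity_scheme
from .preprocess import ConductanceTrace, PreprocessConfig, preprocess_dataset
from .trace_io import CurrentTrace

__all__ = [
    "SweepSpec",
    "ExperimentBudget",
    "BASELINE",
    "sweep",
    "expected_trials",
    "embed_2d",
    "run_baseline",
    "parameter_recovery_experiment",
    "tandem_comparison_experiment",
    "chance_level_experiment",
]

#: the baseline operating point: beta, n_bins, h
BASELINE = {"beta": 0.95, "n_bins": 600, "h": 30}

#: default sweep grids for each parameter
DEFAULT_GRIDS = {
    "beta": (0.87, 0.90, 0.95, 1.0),
    "n_bins": (60, 200, 600),
    "h": (10, 20, 30, 40, 50),
}


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sensitivity sweep around a fixed operating point.

    ``fixed`` holds the (beta, n_bins, h) triple used for the two
    parameters that are not being swept; it defaults to the baseline.
    """

    parameter: str
    values: tuple = ()
    scheme: LabelingScheme | None = None
    n_repeats: int = 10
    fixed: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.parameter not in DEFAULT_GRIDS:
            raise ValueError(f"parameter must be one of {sorted(DEFAULT_GRIDS)}")
        values = tuple(self.values) or DEFAULT_GRIDS[self.parameter]
        if list(values) != sorted(values):
            raise ValueError("sweep values must be sorted ascending")
        object.__setattr__(self, "values", values)
        fixed = dict(BASELINE)
        fixed.update(self.fixed or {})
        object.__setattr__(self, "fixed", fixed)
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ExperimentBudget:
    """Expected number of junction pulls needed for H valid traces."""

    h: int
    p: float
    expected_trials: float


def expected_trials(h: int, p: float) -> ExperimentBudget:
    """H valid traces at per-pull validity probability p cost H/p pulls on average."""
    if h < 1:
        raise ValueError("h must be >= 1")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return ExperimentBudget(h=int(h), p=float(p), expected_trials=h / p)


def _preprocess_pools(
    raw_pools: Mapping[str, Sequence[CurrentTrace]],
    pre_cfg: PreprocessConfig,
    interp_factors: Mapping[str, int] | None = None,
) -> dict[str, list[ConductanceTrace]]:
    out = {}
    for label in sorted(raw_pools):
        cfg = pre_cfg
        if interp_factors and label in interp_factors:
            cfg = replace(pre_cfg, interp_factor=interp_factors[label])
        conductance, _ = preprocess_dataset(raw_pools[label], cfg)
        out[label] = conductance
    return out


def sweep(
    raw_pools: Mapping[str, Sequence[CurrentTrace]],
    spec: SweepSpec,
    clf_cfg: ClassifierConfig,
    base_seed: int,
    pre_cfg: PreprocessConfig | None = None,
    n_hist_train: int = 700,
    n_hist_test: int = 300,
    interp_factors: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Run the repeat protocol at every swept value of one parameter.

    Accepts *raw* current-trace pools so that beta sweeps can re-filter
    from scratch.  A swept value that leaves some class with fewer than
    H valid traces yields a flagged row (``status`` column) with NaN
    accuracies rather than aborting the sweep — with harsh thresholds,
    data scarcity is an expected outcome, not a failure.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    scheme = spec.scheme or identity_scheme(raw_pools.keys())
    baseline_pools = None
    rows = []
    confusions: dict[float, np.ndarray] = {}
    for value in spec.values:
        beta = value if spec.parameter == "beta" else spec.fixed["beta"]
        n_bins = int(value) if spec.parameter == "n_bins" else int(spec.fixed["n_bins"])
        h = int(value) if spec.parameter == "h" else int(spec.fixed["h"])
        if spec.parameter == "beta":
            pools = _preprocess_pools(raw_pools, replace(pre_cfg, beta=beta), interp_factors)
        else:
            if baseline_pools is None:
                baseline_pools = _preprocess_pools(
                    raw_pools, replace(pre_cfg, beta=spec.fixed["beta"]), interp_factors
                )
            pools = baseline_pools
        hist_cfg = HistogramConfig(n_bins=n_bins, h=h)
        # a 70/30 split needs h valid traces on the test (30 %) side
        short = {lab: len(tr) for lab, tr in pools.items()
                 if len(tr) - int(round(0.7 * len(tr))) < h}
        row = {"parameter": spec.parameter, "value": value}
        if short:
            row.update(
                status=f"insufficient traces for h={h}: {short}",
                overall_accuracy=np.nan,
            )
            rows.append(row)
            continue
        res = repeat_protocol(
            pools, scheme, hist_cfg, clf_cfg,
            n_repeats=spec.n_repeats, base_seed=base_seed,
            n_hist_train=n_hist_train, n_hist_test=n_hist_test,
        )
        row.update(status="ok", overall_accuracy=res.overall_accuracy)
        for cls, acc in zip(res.classes, res.per_class_accuracy):
            row[f"class_{cls}_accuracy"] = acc
        rows.append(row)
        confusions[value] = res.confusion
    table = pd.DataFrame(rows)
    table.attrs["confusions"] = confusions
    return table


def embed_2d(
    design: DesignMatrix, method: str = "tsne", seed: int = 0
) -> np.ndarray:
    """Qualitative 2-D map of a histogram feature set (t-SNE or metric MDS).

    Intended for visual inspection of class structure only; coordinates
    carry no quantitative meaning.  t-SNE rejects an all-identical
    feature set (its neighbor calibration is undefined there), while
    metric MDS simply collapses identical rows onto one point.
    """
    X = np.asarray(design.features, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to embed")
    if method == "tsne":
        if np.allclose(X, X[0]):
            raise ValueError("degenerate input: all feature rows are identical")
        perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
        model = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
        return model.fit_transform(X)
    if method == "mds":
        model = MDS(n_components=2, random_state=seed, normalized_stress="auto",
                    init="classical_mds")
        # all-identical rows give zero total dissimilarity; the stress ratio
        # is then 0/0 inside the solver, which still converges to one point
        with np.errstate(invalid="ignore", divide="ignore"):
            return model.fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


def parameter_recovery_experiment(
    seed: int,
    n_traces: int = 400,
    n_repeats: int = 10,
    n_hist_train: int = 700,
    n_hist_test: int = 300,
) -> EvaluationResult:
    """End-to-end recovery study on three well-separated synthetic classes.

    Three single-peak classes with centers at -5.5, -4.0 and -2.5
    decades of G/G0 (>= 1 decade apart) are simulated, conditioned at
    the baseline operating point (beta = 0.95), and classified with the
    baseline histogram (600 bins, H = 30) and boosted-tree settings
    over ``n_repeats`` random 70/30 trace splits.  With signatures this
    distinct the pipeline is expected to recover class identity nearly
    perfectly.
    """
    from .synthetic_data import ClassSignature, SimulatorConfig, simulate_dataset

    sim_cfg = SimulatorConfig()
    sigs = {
        lab: ClassSignature((center,), (0.1,), (1.0,), plateau_prob=0.8, n_plateaus_mean=2.0)
        for lab, center in [("A", -5.5), ("B", -4.0), ("C", -2.5)]
    }
    raw_pools, _ = simulate_dataset(sigs, sim_cfg, n_traces, seed=seed)
    pools = {lab: preprocess_dataset(tr)[0] for lab, tr in raw_pools.items()}
    return repeat_protocol(
        pools, identity_scheme(pools), HistogramConfig(), ClassifierConfig(seed=seed),
        n_repeats=n_repeats, base_seed=seed,
        n_hist_train=n_hist_train, n_hist_test=n_hist_test,
    )


def tandem_comparison_experiment(
    seed: int,
    n_traces: int = 300,
    n_repeats: int = 10,
    n_hist_train: int = 300,
    n_hist_test: int = 150,
) -> dict:
    """Paired stage-1-only vs tandem comparison on a hard near-identical pair.

    Four classes are simulated, two of which ("P1"/"P2") differ only by
    a 0.15-decade shift of their peak center with 0.2-decade peak
    widths — a synthetic analog of a single-base-mismatch duplex pair.
    The routed pair is re-decided by the binary RBF-SVM stage; both
    architectures share every split, histogram draw and stage-1 model.
    """
    from .classification import TandemConfig, tandem_protocol
    from .synthetic_data import ClassSignature, SimulatorConfig, simulate_dataset

    sim_cfg = SimulatorConfig()
    sigs = {
        "D1": ClassSignature((-5.5,), (0.15,), (1.0,), 0.8, 2.0),
        "P1": ClassSignature((-4.00,), (0.20,), (1.0,), 0.8, 2.0),
        "P2": ClassSignature((-4.15,), (0.20,), (1.0,), 0.8, 2.0),
        "D2": ClassSignature((-2.5,), (0.15,), (1.0,), 0.8, 2.0),
    }
    raw_pools, _ = simulate_dataset(sigs, sim_cfg, n_traces, seed=seed)
    pools = {lab: preprocess_dataset(tr)[0] for lab, tr in raw_pools.items()}
    scheme = identity_scheme(pools)
    pair = (scheme.mapping["P1"], scheme.mapping["P2"])
    s1, td = tandem_protocol(
        pools, scheme, HistogramConfig(), ClassifierConfig(seed=seed),
        TandemConfig(routed_pair=pair), n_repeats=n_repeats, base_seed=seed,
        n_hist_train=n_hist_train, n_hist_test=n_hist_test,
    )
    return {"stage1_pair_accuracy": s1, "tandem_pair_accuracy": td,
            "routed_pair": pair, "n_repeats": n_repeats}


def chance_level_experiment(
    seed: int,
    n_classes: int = 3,
    n_train_traces: int = 120,
    n_test_traces: int = 240,
    n_hist_train: int = 150,
    n_test_hist: int = 180,
    hist_cfg: HistogramConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
) -> dict:
    """Null-calibration: identical class signatures must yield chance accuracy.

    All classes share one generating signature, so class labels carry no
    information.  The subtlety is dependence: any finite per-class trace
    pool has an idiosyncratic fingerprint (its particular plateau-level
    draws) shared by every histogram built from it, which makes
    predictions within a class perfectly correlated and the binomial
    null model invalid.  The calibration therefore scores the trained
    model on histograms drawn from a *single shared pool of fresh
    traces* with labels assigned round-robin: features are then
    independent of labels and the hit count is binomial with success
    probability 1/k.

    Returns the observed accuracy, 1/k, and the 3-standard-error
    binomial band half-width.
    """
    from .classification import evaluate, train
    from .histogramming import sample_histogram_set
    from .synthetic_data import ClassSignature, SimulatorConfig, simulate_dataset

    hist_cfg = hist_cfg or HistogramConfig()
    clf_cfg = clf_cfg or ClassifierConfig(seed=seed)
    sig = ClassSignature((-4.0,), (0.2,), (1.0,), plateau_prob=0.8, n_plateaus_mean=2.0)
    sim_cfg = SimulatorConfig()
    labels = [f"C{i}" for i in range(n_classes)]

    train_pools_raw, _ = simulate_dataset({lab: sig for lab in labels}, sim_cfg,
                                          n_train_traces, seed=seed)
    train_pools = {lab: preprocess_dataset(tr)[0] for lab, tr in train_pools_raw.items()}
    scheme = identity_scheme(train_pools)
    train_design = sample_histogram_set(train_pools, hist_cfg, n_hist_train, seed + 1, scheme)
    model = train(train_design, clf_cfg)

    test_raw, _ = simulate_dataset({"shared": sig}, sim_cfg, n_test_traces, seed=seed + 7919)
    shared = preprocess_dataset(test_raw["shared"])[0]
    test_design = sample_histogram_set({"shared": shared},
                                       hist_cfg, n_test_hist, seed + 2,
                                       LabelingScheme("shared", {"shared": 0}))
    y = np.arange(n_test_hist) % n_classes
    preds = model.predict(test_design.features)
    accuracy = float(np.mean(preds == y))
    p0 = 1.0 / n_classes
    half_width = 3.0 * float(np.sqrt(p0 * (1 - p0) / n_test_hist))
    return {"accuracy": accuracy, "chance": p0, "band_half_width": half_width,
            "n_test": n_test_hist}


def run_baseline(
    pools: Mapping[str, Sequence[ConductanceTrace]],
    scheme: LabelingScheme,
    seed: int,
    n_repeats: int = 10,
    n_hist_train: int = 700,
    n_hist_test: int = 300,
    clf_cfg: ClassifierConfig | None = None,
) -> EvaluationResult:
    """The baseline protocol: 598-length features, H=30, shallow boosting.

    Convenience composition of histogram sampling at (600 bins, H=30)
    and the repeat protocol with the default boosted-tree
    configuration; ``pools`` must already be preprocessed at the
    baseline beta.
    """
    hist_cfg = HistogramConfig(n_bins=BASELINE["n_bins"], h=BASELINE["h"])
    clf_cfg = clf_cfg or ClassifierConfig(seed=seed)
    return repeat_protocol(
        pools, scheme, hist_cfg, clf_cfg,
        n_repeats=n_repeats, base_seed=seed,
        n_hist_train=n_hist_train, n_hist_test=n_hist_test,
    )
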