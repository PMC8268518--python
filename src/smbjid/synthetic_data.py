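"""Synthetic SMBJ current-trace simulator with ground-truth class identity.

The generator reproduces the two trace phenotypes seen in break-junction
experiments:

* **invalid** traces — bare tunneling between tip and substrate, a
  predominantly exponential current decay from near preamplifier
  saturation (~100 nA) toward the noise floor (~10 pA);
* **valid** traces — the same decay interrupted by one or more
  conductance *plateaus* where a molecule bridges the junction; plateau
  levels are drawn from a per-class lognormal mixture in
  log10(G/G0), which is what makes experimental conductance histograms
  peaked on log axes.

Each trace is valid with probability ``plateau_prob`` — the validity
probability p that sets the expected experimental budget H/p.  All
randomness flows through a single seeded generator, so every simulated
corpus is reproducible.

The ten bundled presets mimic the acquisition geometry of a ten-dataset
duplex-DNA study (bias voltages, 30 kHz sampling except one 10 kHz
dataset, a near-identical single-mismatch pair); their peak placements
are illustrative, not fitted to any measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import G0
from .trace_io import CurrentTrace, DatasetManifest

__all__ = [
    "ClassSignature",
    "SimulatorConfig",
    "simulate_invalid_trace",
    "simulate_valid_trace",
    "simulate_dataset",
    "study_presets",
    "preset_manifests",
]

#: preamplifier window, amperes
CLIP_LOW = 1e-11
CLIP_HIGH = 1e-7
#: starting current of the retraction decay, just below saturation
I_START = 9e-8


@dataclass(frozen=True)
class ClassSignature:
    """Spectral fingerprint of one molecular class.

    Plateau conductance levels (in log10(G/G0)) are drawn from a
    mixture of Gaussians in log space — i.e. a lognormal mixture in
    conductance — with the given centers, widths (decades) and weights.
    ``plateau_prob`` is the per-trace probability p of a valid
    experiment; ``n_plateaus_mean`` the Poisson mean plateau count of a
    valid trace (floored at one plateau unless the mean is exactly 0).
    """

    peak_centers: tuple[float, ...]
    peak_widths: tuple[float, ...]
    peak_weights: tuple[float, ...]
    plateau_prob: float = 0.6
    n_plateaus_mean: float = 2.0

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.peak_centers)
        widths = tuple(float(w) for w in self.peak_widths)
        weights = tuple(float(w) for w in self.peak_weights)
        object.__setattr__(self, "peak_centers", centers)
        object.__setattr__(self, "peak_widths", widths)
        object.__setattr__(self, "peak_weights", weights)
        if not (len(centers) == len(widths) == len(weights)):
            raise ValueError("centers, widths and weights must have equal length")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if not 0 <= self.plateau_prob <= 1:
            raise ValueError("plateau_prob must be in [0, 1]")
        if self.n_plateaus_mean < 0:
            raise ValueError("n_plateaus_mean must be >= 0")


@dataclass(frozen=True)
class SimulatorConfig:
    """Acquisition-side parameters of the simulator.

    ``decay_time`` is the tunneling decay constant of the retraction
    background; ``noise_sd_log`` the standard deviation (in decades) of
    the multiplicative log-normal measurement noise.  ``plateau_frac_range``
    bounds each plateau's duration as a fraction of the trace.
    """

    sampling_rate: float = 30000.0
    bias_voltage: float = 0.1
    trace_duration: float = 0.5
    decay_time: float = 0.1
    noise_sd_log: float = 0.05
    plateau_frac_range: tuple[float, float] = (0.05, 0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "bias_voltage", "trace_duration", "decay_time"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        lo, hi = self.plateau_frac_range
        if not 0 < lo <= hi < 1:
            raise ValueError("plateau_frac_range must satisfy 0 < lo <= hi < 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.trace_duration * self.sampling_rate))


def _rng(cfg: SimulatorConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def _base_decay(cfg: SimulatorConfig) -> np.ndarray:
    t = np.arange(cfg.n_samples, dtype=np.float64) / cfg.sampling_rate
    return I_START * np.exp(-t / cfg.decay_time)


def _finish(current: np.ndarray, cfg: SimulatorConfig, rng: np.random.Generator,
            label: str, trace_id: str) -> CurrentTrace:
    if cfg.noise_sd_log > 0:
        current = current * np.exp(rng.normal(0.0, cfg.noise_sd_log * np.log(10.0),
                                              size=current.size))
    current = np.clip(current, CLIP_LOW, CLIP_HIGH)
    return CurrentTrace(
        samples=current,
        sampling_rate=cfg.sampling_rate,
        bias_voltage=cfg.bias_voltage,
        dataset_label=label,
        trace_id=trace_id,
    )


def simulate_invalid_trace(
    cfg: SimulatorConfig,
    rng: np.random.Generator | None = None,
    label: str = "sim",
    trace_id: str = "sim:invalid",
) -> CurrentTrace:
    """A bare tunneling decay: exponential from ~100 nA with log-normal noise.

    With ``noise_sd_log = 0`` the trace is exactly exponential between
    the clip limits, so the validity test scores it R^2 = 1.
    """
    rng = _rng(cfg, rng)
    return _finish(_base_decay(cfg), cfg, rng, label, trace_id)


def _plateaus(sig: ClassSignature, cfg: SimulatorConfig,
              rng: np.random.Generator) -> list[dict]:
    """Draw plateau levels, durations and placements for one valid trace."""
    if sig.n_plateaus_mean == 0:
        k = 0
    else:
        k = max(1, int(rng.poisson(sig.n_plateaus_mean)))
    n = cfg.n_samples
    out = []
    for _ in range(k):
        comp = int(rng.choice(len(sig.peak_weights), p=np.asarray(sig.peak_weights)))
        log_g = float(rng.normal(sig.peak_centers[comp], sig.peak_widths[comp]))
        frac = float(rng.uniform(*cfg.plateau_frac_range))
        length = max(1, int(round(frac * n)))
        start = int(rng.integers(0, max(1, n - length + 1)))
        current = 10.0**log_g * G0 * cfg.bias_voltage
        out.append(
            {
                "log_g": log_g,
                "current": current,
                "start": start,
                "length": length,
                "truncated": not (CLIP_LOW <= current <= CLIP_HIGH),
            }
        )
    return out


def _simulate_valid(sig: ClassSignature, cfg: SimulatorConfig,
                    rng: np.random.Generator, label: str,
                    trace_id: str) -> tuple[CurrentTrace, list[dict]]:
    current = _base_decay(cfg)
    plateaus = _plateaus(sig, cfg, rng)
    for p in plateaus:
        current[p["start"]: p["start"] + p["length"]] = p["current"]
    return _finish(current, cfg, rng, label, trace_id), plateaus


def simulate_valid_trace(
    sig: ClassSignature,
    cfg: SimulatorConfig,
    rng: np.random.Generator | None = None,
    label: str = "sim",
    trace_id: str = "sim:valid",
) -> CurrentTrace:
    """A molecular-binding trace: the tunneling decay interrupted by plateaus.

    Plateau conductances come from the class's lognormal mixture;
    plateau currents outside the preamplifier window are silently
    truncated by the final clip.  With ``n_plateaus_mean = 0`` the trace
    degenerates to :func:`simulate_invalid_trace` draw-for-draw.
    """
    rng = _rng(cfg, rng)
    trace, _ = _simulate_valid(sig, cfg, rng, label, trace_id)
    return trace


def simulate_dataset(
    signatures: Mapping[str, ClassSignature],
    cfg: SimulatorConfig | Mapping[str, SimulatorConfig],
    n_traces: int,
    seed: int | None = None,
) -> tuple[dict[str, list[CurrentTrace]], pd.DataFrame]:
    """Simulate per-class trace pools plus a ground-truth table.

    Each trace is valid (contains plateaus) with its class's
    ``plateau_prob``.  ``cfg`` may be a single configuration shared by
    all classes or a per-label mapping.  Returns ``(pools, truth)``
    where ``truth`` has one row per trace: trace_id, dataset label,
    validity flag, plateau count, and plateau log-conductance levels.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    per_label = isinstance(cfg, Mapping)
    base_seed = seed if seed is not None else (
        next(iter(cfg.values())).seed if per_label else cfg.seed
    )
    rng = np.random.default_rng(base_seed)
    pools: dict[str, list[CurrentTrace]] = {}
    rows = []
    for label in sorted(signatures):
        sig = signatures[label]
        c = cfg[label] if per_label else cfg
        traces = []
        for i in range(n_traces):
            trace_id = f"{label}:{i}"
            valid = bool(rng.random() < sig.plateau_prob)
            if valid:
                trace, plateaus = _simulate_valid(sig, c, rng, label, trace_id)
            else:
                trace, plateaus = simulate_invalid_trace(c, rng, label, trace_id), []
            traces.append(trace)
            rows.append(
                {
                    "trace_id": trace_id,
                    "dataset_label": label,
                    "valid": valid,
                    "n_plateaus": len(plateaus),
                    "plateau_log_g": ";".join(f"{p['log_g']:.4f}" for p in plateaus),
                }
            )
        pools[label] = traces
    return pools, pd.DataFrame(rows)


def study_presets() -> dict[str, tuple[ClassSignature, SimulatorConfig]]:
    """Ten presets mimicking the acquisition layout of a ten-dataset study.

    Bias voltages follow the study design (0.01-0.30 V); all datasets
    sample at 30 kHz except S10 at 10 kHz.  Peak placements are
    illustrative: S1 carries a single pronounced low-conductance peak
    (placed at 1e-5 G0); S3/S4 are a near-identical pair whose
    signatures differ in a single peak center, emulating a
    single-base-mismatch duplex pair; S2/S8 and S10 overlap, the
    same-strand datasets S2/S6/S7/S8/S9 share a common motif.
    """

    def sig(centers, widths, weights, p=0.6, k=2.0):
        return ClassSignature(tuple(centers), tuple(widths), tuple(weights), p, k)

    def cfg(bias, rate=30000.0):
        return SimulatorConfig(sampling_rate=rate, bias_voltage=bias)

    same_strand = ((-3.2, -2.4), (0.20, 0.25), (0.6, 0.4))
    presets = {
        "S1": (sig((-5.0,), (0.10,), (1.0,)), cfg(0.30)),
        "S2": (sig(*same_strand), cfg(0.01)),
        "S3": (sig((-4.00, -3.0), (0.20, 0.30), (0.7, 0.3)), cfg(0.05)),
        "S4": (sig((-4.15, -3.0), (0.20, 0.30), (0.7, 0.3)), cfg(0.05)),
        "S5": (sig((-3.5,), (0.15,), (1.0,)), cfg(0.30)),
        "S6": (sig((-3.3, -2.5), (0.20, 0.25), (0.6, 0.4)), cfg(0.10)),
        "S7": (sig((-3.25, -2.45), (0.20, 0.25), (0.6, 0.4)), cfg(0.20)),
        "S8": (sig(*same_strand), cfg(0.01)),
        "S9": (sig((-3.3, -2.5), (0.20, 0.25), (0.6, 0.4)), cfg(0.10)),
        "S10": (sig((-3.0, -2.2), (0.25, 0.25), (0.5, 0.5)), cfg(0.01, rate=10000.0)),
    }
    return presets


def preset_manifests() -> list[DatasetManifest]:
    """Manifest rows matching :func:`study_presets`."""
    notes = {
        "S1": "octanedithiol control (non-nucleic)",
        "S3": "duplex, single mismatch vs S4",
        "S4": "duplex, single mismatch vs S3",
        "S10": "G-quadruplex-forming strand",
    }
    out = []
    for label, (_, cfg) in study_presets().items():
        out.append(
            DatasetManifest(
                label=label,
                bias_voltage=cfg.bias_voltage,
                sampling_rate=cfg.sampling_rate,
                sequence_note=notes.get(label, "duplex strand"),
                buffer_note="synthetic",
            )
        )
    return out
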