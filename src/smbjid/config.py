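"""YAML/JSON configuration loading for the command-line interface.

A config file carries up to three blocks mirroring the dataclass field
names, e.g.::

    preprocess:
      beta: 0.95
      cutoff_fraction: 0.6
    histogram:
      n_bins: 600
      h: 30
    classifier:
      n_est: 200
      d_est: 2
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .classification import ClassifierConfig
from .histogramming import HistogramConfig
from .preprocess import PreprocessConfig

__all__ = ["load_config", "resolve_configs"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def resolve_configs(
    mapping: dict,
) -> tuple[PreprocessConfig, HistogramConfig, ClassifierConfig]:
    """Build the three config dataclasses from a parsed config mapping."""
    pre = PreprocessConfig(**mapping.get("preprocess", {}))
    hist_kwargs = dict(mapping.get("histogram", {}))
    if "log_range" in hist_kwargs:
        hist_kwargs["log_range"] = tuple(hist_kwargs["log_range"])
    hist = HistogramConfig(**hist_kwargs)
    clf = ClassifierConfig(**mapping.get("classifier", {}))
    return pre, hist, clf
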