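"""Run configuration: defaults, YAML config files, CLI override merging.

The defaults reproduce the reference operating point of the method:
spatial standard deviation 14 px and range standard deviation 0.10 for the
adaptive manifold filter, a 3x3 saliency window (radius 1), and 256
histogram bins for the mutual-information metric (8-bit sources).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .amfilter import FilterParams
from .errors import InvalidParameterError
from .metrics import MetricConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration mirrored by the YAML config file keys."""

    sigma_s: float = 14.0
    sigma_r: float = 0.10
    num_manifolds: int | str = "auto"
    msf_window_radius: int = 1
    bins: int = 256
    log_level: str = "WARNING"

    def filter_params(self) -> FilterParams:
        return FilterParams(sigma_s=self.sigma_s, sigma_r=self.sigma_r,
                            num_manifolds=self.num_manifolds)

    def metric_config(self) -> MetricConfig:
        return MetricConfig(bins=self.bins)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Overrides (typically CLI flags) win over file values, which win over
    the defaults.  Override values of ``None`` mean "not given".
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise InvalidParameterError(
                f"{path}: config file must be a flat key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    valid = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise InvalidParameterError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(valid)}")
    return RunConfig(**data)
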