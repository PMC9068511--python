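"""Analysis configuration: one source of truth for the pipeline constants.

Defaults reproduce the fixed constants of the assays being modelled: 50 bp
single-end reads, 100 log-spaced histogram bins over 1e-3..1e5, a
30-point running-average window, 10^4 bootstrap surrogates, the
0.85 h^-1 contamination cutoff and the two OD fitting windows.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    seed: int = 0
    read_length: int = 50
    hist_bins: int = 100
    hist_lo: float = 1e-3
    hist_hi: float = 1e5
    running_window: int = 30
    smooth_window: int = 5
    n_surrogates: int = 10_000
    od_window_screen: tuple[float, float] = (0.01, 1.0)
    od_window_sorted: tuple[float, float] = (0.02, 0.2)
    max_rate: float = 0.85
    top_n_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.hist_bins < 1:
            raise ValueError("read_length and hist_bins must be positive")
        if not self.hist_lo < self.hist_hi:
            raise ValueError("hist_lo must be below hist_hi")
        if self.running_window < 1 or self.smooth_window < 1:
            raise ValueError("windows must be >= 1")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if not 0 < self.top_n_fraction <= 1:
            raise ValueError("top_n_fraction must lie in (0, 1]")
        self.od_window_screen = tuple(self.od_window_screen)
        self.od_window_sorted = tuple(self.od_window_sorted)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value)} to TOML")


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    lines = ["[isoretain]"]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {_toml_value(getattr(config, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    section = data.get("isoretain", data)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = sorted(set(section) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return AnalysisConfig(**section)
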