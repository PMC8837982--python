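"""Layered run configuration for the command-line pipeline.

A single YAML file governs every stage; CLI flags override individual
fields. Each section is validated by constructing the corresponding
module object at load time, so a bad window size or date range fails
before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date, datetime
from pathlib import Path

import yaml

from .bes import BESConfig
from .synthetic import SimConfig, TruthParams
from .tuner import SearchSpace


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    # simulate
    sim: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    # preprocess
    window_days: int = 5
    sg_window: int = 5
    sg_order: int = 2
    envelope: bool = True
    # regression
    n_train: int = 60
    # lstm / tuner
    lookback: int = 2
    n_train_lstm: int = 50
    lstm_hidden: int = 16
    lstm_lr: float = 0.01
    lstm_epochs: int = 500
    inner_seed: int = 0
    bes: dict = field(default_factory=dict)
    search_space: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        params = dict(self.sim)
        for key in ("start_date", "end_date"):
            if key in params and not isinstance(params[key], date):
                params[key] = datetime.strptime(params[key], "%Y-%m-%d").date()
        params.setdefault("seed", self.seed)
        try:
            return SimConfig(**params)
        except (TypeError, ValueError) as exc:
            raise RunConfigError(f"invalid [sim] section: {exc}") from exc

    def truth_params(self) -> TruthParams:
        params = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.truth.items()
        }
        try:
            return TruthParams(**params)
        except (TypeError, ValueError) as exc:
            raise RunConfigError(f"invalid [truth] section: {exc}") from exc

    def bes_config(self, lower, upper) -> BESConfig:
        params = dict(self.bes)
        params.setdefault("seed", self.seed)
        try:
            return BESConfig(lower=lower, upper=upper, **params)
        except (TypeError, ValueError) as exc:
            raise RunConfigError(f"invalid [bes] section: {exc}") from exc

    def space(self) -> SearchSpace:
        params = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in self.search_space.items()
        }
        try:
            return SearchSpace(**params)
        except (TypeError, ValueError) as exc:
            raise RunConfigError(f"invalid [search_space] section: {exc}") from exc

    def validate(self) -> "RunConfig":
        if self.sg_window % 2 == 0 or self.sg_order >= self.sg_window:
            raise RunConfigError("need odd sg_window and sg_order < sg_window")
        if self.window_days < 1 or self.lookback < 1:
            raise RunConfigError("window_days and lookback must be positive")
        if self.n_train < 1 or self.n_train_lstm < 1:
            raise RunConfigError("split sizes must be positive")
        if self.lstm_lr <= 0 or self.lstm_epochs < 1 or self.lstm_hidden < 1:
            raise RunConfigError("invalid LSTM settings")
        self.sim_config()
        self.truth_params()
        self.space()
        bes_params = dict(self.bes)
        if bes_params.get("iterations", 1) < 1 or bes_params.get("pop_size", 2) < 2:
            raise RunConfigError("BES needs iterations >= 1 and pop_size >= 2")
        return self


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    payload = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise RunConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise RunConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in (overrides or {}).items():
        if value is not None:
            payload[key] = value
    return RunConfig(**payload).validate()
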