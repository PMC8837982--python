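"""BES-driven hyperparameter tuning for the LSTM regressor.

BES searches a 2-D space — log₁₀ learning rate and (continuously
relaxed) hidden size — minimising the held-out RMSE of the trained
network. Every fitness evaluation trains under the *same* inner seed,
so fitness is a deterministic function of the candidate; without this
the greedy acceptance of BES would compare training noise rather than
hyperparameters. The tuned model is compared with a default-
hyperparameter baseline on the identical test split using the shared
five-metric report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bes
from .lstm import (
    DEFAULT_EPOCHS,
    DEFAULT_HIDDEN,
    DEFAULT_LR,
    LstmModel,
    LstmResults,
    SequenceDataset,
    TrainingError,
)
from .metrics import MetricReport

__all__ = ["SearchSpace", "decode", "make_fitness", "tune", "TuneResult",
           "compare_report"]

log = logging.getLogger(__name__)

PENALTY_FITNESS = 1e6


@dataclass(frozen=True)
class SearchSpace:
    """Bounds of the tuned hyperparameters.

    The learning rate is searched on a log₁₀ scale (it spans decades);
    the hidden size is relaxed to a continuous coordinate and rounded
    to the nearest integer on decoding.
    """

    lr_bounds: tuple[float, float] = (1e-4, 1e-1)
    hidden_bounds: tuple[int, int] = (2, 64)

    def __post_init__(self):
        lo, hi = self.lr_bounds
        if not (0 < lo <= hi):
            raise ValueError("lr bounds must be positive and ordered")
        h_lo, h_hi = self.hidden_bounds
        if not (1 <= h_lo <= h_hi):
            raise ValueError("hidden-size bounds must be >= 1 and ordered")

    @property
    def lower(self):
        return (math.log10(self.lr_bounds[0]), float(self.hidden_bounds[0]))

    @property
    def upper(self):
        return (math.log10(self.lr_bounds[1]), float(self.hidden_bounds[1]))


def decode(candidate, space: SearchSpace):
    """Map a BES position to concrete hyperparameters (lr, hidden)."""
    log_lr, h_real = float(candidate[0]), float(candidate[1])
    lr = 10.0 ** log_lr
    lr = min(max(lr, space.lr_bounds[0]), space.lr_bounds[1])
    h = int(round(h_real))
    h = min(max(h, space.hidden_bounds[0]), space.hidden_bounds[1])
    return lr, h


def make_fitness(train_data: SequenceDataset, holdout: SequenceDataset,
                 space: SearchSpace, inner_seed: int = 0,
                 epochs: int = DEFAULT_EPOCHS):
    """Fitness callable: decoded candidate → held-out RMSE.

    Training failures (divergence, non-finite loss) are encoded as a
    large penalty so BES simply avoids that region.
    """

    def fitness(candidate) -> float:
        lr, hidden = decode(candidate, space)
        try:
            results = LstmModel(train_data, hidden_size=hidden).fit(
                lr=lr, epochs=epochs, seed=inner_seed
            )
            rmse = results.score(holdout).rmse
        except (TrainingError, FloatingPointError) as exc:
            log.debug("penalising candidate lr=%.3g H=%d: %s", lr, hidden, exc)
            return PENALTY_FITNESS
        return rmse if np.isfinite(rmse) else PENALTY_FITNESS

    return fitness


@dataclass(frozen=True)
class TuneResult:
    best_lr: float
    best_hidden: int
    best_fitness: float
    history: np.ndarray
    results: LstmResults          # final model retrained at the optimum
    trace: pd.DataFrame           # iteration, best_fitness


def tune(
    train_data: SequenceDataset,
    holdout: SequenceDataset,
    space: SearchSpace | None = None,
    bes_config: bes.BESConfig | None = None,
    inner_seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
) -> TuneResult:
    """Run BES over (learning rate, hidden size); retrain at the optimum.

    Deterministic under the pair (``seed`` for BES, ``inner_seed`` for
    every training run).
    """
    space = space or SearchSpace()
    # a zero-width (pinned) dimension is widened by an epsilon the decoding
    # collapses back, so degenerate spaces return their single candidate
    lower = np.asarray(space.lower, float)
    upper = np.asarray(space.upper, float)
    upper = tuple(np.where(upper - lower > 0, upper, lower + 1e-9))
    lower = tuple(lower)
    if bes_config is None:
        bes_config = bes.BESConfig(lower=lower, upper=upper, seed=seed)
    else:
        if tuple(bes_config.lower) != lower or tuple(bes_config.upper) != upper:
            bes_config = bes.BESConfig(
                lower=lower, upper=upper,
                pop_size=bes_config.pop_size, iterations=bes_config.iterations,
                alpha=bes_config.alpha, a_corner=bes_config.a_corner,
                R_cycles=bes_config.R_cycles, c1=bes_config.c1, c2=bes_config.c2,
                seed=bes_config.seed,
            )
    fitness = make_fitness(train_data, holdout, space, inner_seed=inner_seed,
                           epochs=epochs)
    result = bes.optimize(fitness, bes_config)
    best_lr, best_hidden = decode(result.best_position, space)
    final = LstmModel(train_data, hidden_size=best_hidden).fit(
        lr=best_lr, epochs=epochs, seed=inner_seed
    )
    trace = pd.DataFrame(
        {"iteration": np.arange(len(result.history)), "best_fitness": result.history}
    )
    log.info("tuned: lr=%.4g, hidden=%d, holdout RMSE=%.4g",
             best_lr, best_hidden, result.best_fitness)
    return TuneResult(
        best_lr=best_lr, best_hidden=best_hidden,
        best_fitness=float(result.best_fitness),
        history=result.history, results=final, trace=trace,
    )


def compare_report(
    tuned: LstmResults,
    baseline: LstmResults,
    test_data: SequenceDataset,
) -> pd.DataFrame:
    """Side-by-side five-metric report (rows LSTM / BES-LSTM)."""
    rows = []
    for label, res in (("LSTM", baseline), ("BES-LSTM", tuned)):
        report: MetricReport = res.score(test_data)
        rows.append({"model": label, "R2": report.r2, "RMSE": report.rmse,
                     "MSE": report.mse, "MAE": report.mae, "MAPE": report.mape})
    return pd.DataFrame(rows).set_index("model")
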