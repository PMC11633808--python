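"""Shared fixtures.

The ``benchmark`` fixture performs the expensive part of the acceptance
suite once per session: five training runs on the same ~200-slice phantom
dataset (full adversarial model, adversarial without synthetic errors,
sequential baseline, and the two input-channel ablations), all scored on
one shared corrupted held-out set. Every seed below is a fixed study
condition; none may be adjusted to influence outcomes.
"""

import numpy as np
import pytest

from autoconfidence.errors import ErrorInjectionConfig
from autoconfidence.evaluation import EvalOptions
from autoconfidence.phantom import PhantomConfig, generate_slices
from autoconfidence.training import (TrainConfig, corrupt_cases,
                                     evaluate_error_detection, train,
                                     train_sequential_baseline)

BENCH_N_TRAIN = 200
BENCH_N_TEST = 40
BENCH_DATA_SEED = 101
BENCH_TEST_SEED = 202
BENCH_TRAIN_SEED = 303
BENCH_CORRUPT_SEED = 404

_EVAL_CONFIGS = {
    "baseline": EvalOptions(ier=False, gdc=False),
    "ier": EvalOptions(ier=True, gdc=False),
    "ier_gdc": EvalOptions(ier=True, gdc=True),
}


def _train_kwargs(**overrides):
    kwargs = dict(epochs=12, batch_size=8, val_fraction=0.15,
                  seed=BENCH_TRAIN_SEED)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@pytest.fixture(scope="session")
def benchmark():
    train_cases = generate_slices(BENCH_N_TRAIN,
                                  PhantomConfig(seed=BENCH_DATA_SEED))
    test_cases = generate_slices(BENCH_N_TEST,
                                 PhantomConfig(seed=BENCH_TEST_SEED))
    corrupted = corrupt_cases(test_cases, ErrorInjectionConfig(),
                              seed=BENCH_CORRUPT_SEED)

    runs = {
        "main": lambda: train(train_cases, _train_kwargs()),
        "no_injection": lambda: train(
            train_cases, _train_kwargs(use_synthetic_errors=False)),
        "sequential": lambda: train_sequential_baseline(
            train_cases, _train_kwargs()),
        "ablate_image": lambda: train(
            train_cases, _train_kwargs(ablate="image")),
        "ablate_masks": lambda: train(
            train_cases, _train_kwargs(ablate="masks")),
    }

    models = {}
    summaries = {}
    for name, fn in runs.items():
        gen, disc, history = fn()
        models[name] = (gen, disc, history)
        summaries[name] = {
            cfg: evaluate_error_detection(disc, corrupted, opts)[1]
            for cfg, opts in _EVAL_CONFIGS.items()
        }

    return {
        "train_cases": train_cases,
        "test_cases": test_cases,
        "corrupted": corrupted,
        "models": models,
        "summaries": summaries,
    }


def mcc_score(summary: dict) -> float:
    """Comparison score for a model: nan-excluded mean MCC, scored 0 when no
    case is defined (a model that detects nothing earns no credit)."""
    value = summary["mean_mcc"]
    return float(value) if np.isfinite(value) else 0.0
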