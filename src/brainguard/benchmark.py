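"""Reference benchmark runs of the monitor workflow.

The default benchmark mirrors the study design the package targets:
J = 5000 measurement points, 900 monitor-mode samples split 720/180,
truncation threshold 1e-10, optional output-side noise at a prescribed
SNR (dB) with optional bias.  Everything is deterministic given one
integer seed, from which per-stage child seeds are spawned.
"""

from __future__ import annotations

import numpy as np

from .platform import EvaluationReport, TrainConfig, evaluate, train_emulator
from .synthetic import NoiseSpec, SceneConfig, generate_dataset, inject_noise

__all__ = ["monitor_benchmark", "BenchmarkResult"]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def monitor_benchmark(
    seed: int,
    snr_db: float | None = None,
    bias_mean: float = 0.0,
    n: int = 900,
    split: float = 0.8,
    j_points: int = 5000,
    truncation_threshold: float = 1e-10,
) -> "BenchmarkResult":
    """Generate, (optionally corrupt,) train and evaluate one condition.

    Noise is injected into the training outputs only; evaluation is
    against the clean test references.
    """
    seed_scene, seed_data, seed_noise, seed_train = _child_seeds(seed, 4)
    scene = SceneConfig(n_points=j_points, rng_seed=seed_scene)
    train, test = generate_dataset(scene, "monitor", n=n, split=split,
                                   seed=seed_data)
    if snr_db is not None or bias_mean != 0.0:
        train = inject_noise(
            train,
            NoiseSpec(snr_db=snr_db, bias_mean=bias_mean, rng_seed=seed_noise),
        )
    config = TrainConfig(
        truncation_threshold=truncation_threshold, seed=seed_train
    )
    emulator = train_emulator(train, config)
    report = evaluate(emulator, test)
    return BenchmarkResult(
        emulator=emulator, report=report, n_test=test.n_samples,
        snr_db=snr_db, bias_mean=bias_mean,
    )


class BenchmarkResult:
    """One benchmark condition's trained emulator and error report."""

    def __init__(self, emulator, report: EvaluationReport, n_test: int,
                 snr_db, bias_mean):
        self.emulator = emulator
        self.report = report
        self.n_test = n_test
        self.snr_db = snr_db
        self.bias_mean = bias_mean

    @property
    def max_mean_error(self) -> float:
        """Max over points of the test-sample-averaged error map."""
        return self.report.max_mean_error

    @property
    def max_per_sample_mean_error(self) -> float:
        return float(self.report.per_sample_mean_error.max())

    @property
    def pct_samples_below_005(self) -> float:
        return 100.0 * float(np.mean(self.report.per_sample_mean_error < 0.005))
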