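"""Synthetic two-day, multi-workload test-retest data.

Emulates the kind of repeatability protocol behind the shipped
calibrations: each subject rides a fixed set of workloads on two separate
days, and each day's VO2 reading is the true workload value plus
flow-dependent (differential) measurement error.  The observed value is
drawn as ``W ~ Normal(X, sigma_true(X))`` where ``sigma_true`` is a
polynomial in the true VO2 ``X`` — the additive error form whose scale
depends on the true value.  Draws are truncated at zero by resampling,
since a negative oxygen uptake is unphysical.

The generator exists so calibration fitting and the full analysis
pipeline can be exercised end-to-end with a known ground truth; workload
labels are opaque (no physiological workload-to-VO2 model).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibrate import TestRetestRecord
from .exceptions import InvalidInputError

__all__ = [
    "DEFAULT_WORKLOAD_MUS",
    "SyntheticProtocol",
    "simulate_measurement_pair",
    "generate_test_retest",
    "write_test_retest_csv",
]

#: Default workload grid (true VO2, L/min): seven evenly spaced cycling
#: intensities spanning the validity range of the shipped calibrations.
DEFAULT_WORKLOAD_MUS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


def _sigma_true(noise_model: Sequence[float], x: float) -> float:
    return float(np.polynomial.polynomial.polyval(x, list(noise_model)))


@dataclass(frozen=True)
class SyntheticProtocol:
    """Specification of one simulated test-retest study.

    Parameters
    ----------
    workload_mus : sequence of float
        True VO2 (L/min) at each workload.
    n_subjects : int
        Subjects completing the full workload grid on both days.
    noise_model : sequence of float
        Ascending polynomial coefficients of ``sigma_true(X)`` (L/min) —
        the magnitude of the differential measurement error.
    seed : int
        Seed of the generator; required, so every dataset is reproducible.
    """

    workload_mus: tuple[float, ...] = DEFAULT_WORKLOAD_MUS
    n_subjects: int = 10
    noise_model: tuple[float, ...] = (0.02, 0.01, 0.005, 0.001)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "workload_mus", tuple(float(x) for x in self.workload_mus))
        object.__setattr__(self, "noise_model", tuple(float(c) for c in self.noise_model))
        if self.n_subjects < 1:
            raise InvalidInputError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if any(x <= 0 for x in self.workload_mus):
            raise InvalidInputError("all workload VO2 values must be positive")
        for x in self.workload_mus:
            if _sigma_true(self.noise_model, x) < 0:
                raise InvalidInputError(
                    f"noise model gives sigma_true < 0 at X={x} L/min"
                )


def simulate_measurement_pair(
    x: float,
    noise_model: Sequence[float],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw one day-1/day-2 observation pair at true VO2 `x`.

    Each day is an independent ``Normal(x, sigma_true(x))`` draw,
    resampled while non-positive.  ``sigma_true(x) == 0`` is permitted
    (degenerate, returns ``(x, x)``) so noise-free limits are testable.
    """
    if not x > 0:
        raise InvalidInputError(f"true VO2 must be positive, got {x}")
    sigma = _sigma_true(noise_model, x)
    if sigma < 0:
        raise InvalidInputError(f"sigma_true(X)={sigma} < 0 at X={x}")
    if sigma == 0.0:
        return (x, x)

    def draw() -> float:
        w = rng.normal(x, sigma)
        while w <= 0:
            w = rng.normal(x, sigma)
        return float(w)

    return (draw(), draw())


def generate_test_retest(protocol: SyntheticProtocol) -> list[TestRetestRecord]:
    """Simulate the full protocol: one record per (subject, workload).

    Returns ``n_subjects * len(workload_mus)`` records, each the
    (mean, SD) summary of that subject-workload pair, in deterministic
    subject-major order.  Byte-identical for identical seeds.
    """
    rng = np.random.default_rng(protocol.seed)
    records: list[TestRetestRecord] = []
    for s in range(protocol.n_subjects):
        for w, x in enumerate(protocol.workload_mus):
            d1, d2 = simulate_measurement_pair(x, protocol.noise_model, rng)
            records.append(
                TestRetestRecord.from_pair(
                    d1, d2, subject_id=f"S{s + 1:03d}", workload=f"W{w + 1}"
                )
            )
    return records


def write_test_retest_csv(records: Sequence[TestRetestRecord], path) -> None:
    """Write records in the calibration CSV dialect read by
    :func:`vo2overlap.calibrate.read_test_retest_csv`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "workload", "mean_vo2", "sd_vo2"])
        for r in records:
            writer.writerow([r.subject_id or "", r.workload or "", repr(r.mean_vo2), repr(r.sd_vo2)])
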