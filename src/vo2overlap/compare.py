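"""User-facing comparison of two VO2 measures.

The central question: given a baseline and a follow-up VO2 reading, what
is the probability that they are the same measurement, once the
device-specific day-to-day error at each flow level is accounted for?
Each reading becomes a normal distribution via its device calibration and
the answer is the overlapping coefficient of the two densities.

A batch ("stacked") mode averages the per-subject probabilities into a
net probability of similarity for a cohort; a verdict classifies a
probability against a similarity threshold (default 10%: below it the two
measures are called truly different).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .error_model import CalibrationRegistry, default_registry, make_distribution
from .exceptions import InvalidInputError
from .overlap import ovl_normal

__all__ = [
    "DEFAULT_SYSTEM",
    "DEFAULT_THRESHOLD",
    "VERDICT_DIFFERENT",
    "VERDICT_SAME",
    "ComparisonResult",
    "compare",
    "net_similarity",
    "classify",
    "plot_overlap",
    "run_batch",
]

DEFAULT_SYSTEM = "parvo_2400"
DEFAULT_THRESHOLD = 0.10
VERDICT_DIFFERENT = "truly different"
VERDICT_SAME = "not distinguishable"


def classify(prob_same: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Verdict for a similarity probability at a threshold.

    ``"truly different"`` iff ``prob_same < threshold``; a probability
    exactly at the threshold is not below the bar and therefore
    ``"not distinguishable"``.
    """
    if not 0.0 <= prob_same <= 1.0:
        raise InvalidInputError(f"prob_same must be in [0, 1], got {prob_same}")
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError(f"threshold must be in (0, 1), got {threshold}")
    return VERDICT_DIFFERENT if prob_same < threshold else VERDICT_SAME


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of comparing two VO2 measures.

    ``prob_same`` is kept at full precision; use :meth:`report` for the
    display form (3 decimals / 1 decimal on the percent scale).
    """

    prob_same: float
    verdict: str
    threshold: float
    mu_a: float
    device_a: str
    sigma_a: float
    mu_b: float
    device_b: str
    sigma_b: float

    def report(self) -> str:
        return (
            f"P(same measure) = {self.prob_same:.3f} ({self.prob_same * 100:.1f}%)\n"
            f"verdict at {self.threshold * 100:.0f}% threshold: {self.verdict}\n"
            f"a: {self.mu_a} L/min on {self.device_a} (sigma = {self.sigma_a:.4f} L/min)\n"
            f"b: {self.mu_b} L/min on {self.device_b} (sigma = {self.sigma_b:.4f} L/min)"
        )


def compare(
    a: float,
    b: float,
    system_a: str = DEFAULT_SYSTEM,
    system_b: str = DEFAULT_SYSTEM,
    registry: CalibrationRegistry | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ComparisonResult:
    """Probability that VO2 measures `a` and `b` (L/min) are the same.

    Builds each measure's device-specific normal error distribution and
    returns the overlapping coefficient of the two densities, with a
    verdict at `threshold`.  Symmetric in its two (value, system) pairs.
    When no system is given both measures default to the automated
    ParvoMedics 2400 TrueOne calibration.
    """
    if registry is None:
        registry = default_registry()
    dist_a = make_distribution(a, system_a, registry)
    dist_b = make_distribution(b, system_b, registry)
    prob = ovl_normal(dist_a.mu, dist_a.sigma, dist_b.mu, dist_b.sigma)
    return ComparisonResult(
        prob_same=prob,
        verdict=classify(prob, threshold),
        threshold=threshold,
        mu_a=dist_a.mu,
        device_a=dist_a.device_id,
        sigma_a=dist_a.sigma,
        mu_b=dist_b.mu,
        device_b=dist_b.device_id,
        sigma_b=dist_b.sigma,
    )


def net_similarity(
    pre: Sequence[float],
    post: Sequence[float],
    system_a: str = DEFAULT_SYSTEM,
    system_b: str = DEFAULT_SYSTEM,
    registry: CalibrationRegistry | None = None,
) -> float:
    """Net probability of similarity for a cohort ("stacked" analysis).

    Pairs `pre` and `post` by position and returns the arithmetic mean of
    the per-pair similarity probabilities.  One pair of systems applies to
    the whole batch (per-row systems are available via :func:`run_batch`).
    """
    pre = list(pre)
    post = list(post)
    if len(pre) == 0 or len(post) == 0:
        raise InvalidInputError("pre and post vectors must be non-empty")
    if len(pre) != len(post):
        raise InvalidInputError(
            f"pre and post vectors differ in length ({len(pre)} vs {len(post)})"
        )
    probs = [
        compare(a, b, system_a, system_b, registry).prob_same
        for a, b in zip(pre, post)
    ]
    return float(np.mean(probs))


def plot_overlap(result: ComparisonResult, output_path) -> None:
    """Render the two densities with the shared (minimum) region shaded.

    The x-range spans both means plus/minus 4 of the larger sigma; the
    overlap coefficient is annotated to 3 decimals.  Output format (PNG,
    SVG, PDF) follows the file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    s = max(result.sigma_a, result.sigma_b)
    lo = min(result.mu_a, result.mu_b) - 4.0 * s
    hi = max(result.mu_a, result.mu_b) + 4.0 * s
    x = np.linspace(lo, hi, 2000)
    f_a = norm.pdf(x, result.mu_a, result.sigma_a)
    f_b = norm.pdf(x, result.mu_b, result.sigma_b)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(x, f_a, label=f"{result.mu_a} L/min ({result.device_a})")
    ax.plot(x, f_b, label=f"{result.mu_b} L/min ({result.device_b})")
    ax.fill_between(x, np.minimum(f_a, f_b), color="0.3", alpha=0.8,
                    label="shared region")
    ax.annotate(
        f"overlap = {result.prob_same:.3f}",
        xy=(0.02, 0.95),
        xycoords="axes fraction",
        va="top",
    )
    ax.set_xlabel("VO$_2$ (L/min)")
    ax.set_ylabel("density")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    try:
        fig.savefig(output_path)
    except (OSError, IOError) as exc:
        raise OSError(f"cannot write plot to {output_path}: {exc}") from exc
    finally:
        plt.close(fig)


def run_batch(
    input_path,
    system_a: str = DEFAULT_SYSTEM,
    system_b: str = DEFAULT_SYSTEM,
    registry: CalibrationRegistry | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Stacked analysis of a batch CSV.

    Input columns: ``subject_id``, ``pre_vo2``, ``post_vo2``; optional
    ``system_pre`` / ``system_post`` override the batch-level systems per
    row.  Returns one result row per subject plus a final summary row
    (subject_id ``"net_probability"``) holding the net probability of
    similarity — the mean of the per-subject probabilities.
    """
    try:
        df = pd.read_csv(input_path)
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"batch CSV {input_path} is empty") from exc
    required = {"subject_id", "pre_vo2", "post_vo2"}
    if not required <= set(df.columns):
        raise InvalidInputError(
            f"batch CSV must have columns {sorted(required)}; found {sorted(df.columns)}"
        )
    if len(df) == 0:
        raise InvalidInputError(f"batch CSV {input_path} has no data rows")

    rows = []
    for idx, row in df.iterrows():
        sys_a = str(row["system_pre"]) if "system_pre" in df.columns and pd.notna(row.get("system_pre")) else system_a
        sys_b = str(row["system_post"]) if "system_post" in df.columns and pd.notna(row.get("system_post")) else system_b
        try:
            res = compare(
                float(row["pre_vo2"]), float(row["post_vo2"]),
                sys_a, sys_b, registry, threshold,
            )
        except (ValueError, InvalidInputError) as exc:
            raise InvalidInputError(f"batch CSV row {idx} (subject {row['subject_id']}): {exc}") from exc
        rows.append(
            {
                "subject_id": row["subject_id"],
                "pre_vo2": res.mu_a,
                "post_vo2": res.mu_b,
                "system_pre": res.device_a,
                "system_post": res.device_b,
                "prob_same": res.prob_same,
                "verdict": res.verdict,
            }
        )
    net = float(np.mean([r["prob_same"] for r in rows]))
    rows.append(
        {
            "subject_id": "net_probability",
            "pre_vo2": np.nan,
            "post_vo2": np.nan,
            "system_pre": "",
            "system_post": "",
            "prob_same": net,
            "verdict": classify(net, threshold),
        }
    )
    return pd.DataFrame(rows)
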