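"""Device error models: sigma(mu) calibrations and measurement distributions.

Indirect-calorimetry systems exhibit differential measurement error: the
day-to-day standard deviation of a VO2 reading depends on the gas flow
being measured.  Each device is described by a low-order polynomial
``sigma(mu)`` mapping a VO2 level (L/min) to the standard deviation of its
test-retest error distribution (L/min).  A user-supplied measurement then
becomes a normal distribution ``N(mu, sigma(mu)^2)``.

All VO2 values are strictly in L/min, the raw un-normalized unit produced
by gas-exchange systems; body-mass-normalized data (mL/kg/min) is out of
scope for the error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

from .exceptions import (
    CalibrationDomainError,
    InvalidInputError,
    RangeError,
    UnknownDeviceError,
)

__all__ = [
    "HARD_ENVELOPE",
    "DEFAULT_VALID_RANGE",
    "DeviceCalibration",
    "MeasurementDistribution",
    "CalibrationRegistry",
    "sigma_at",
    "make_distribution",
    "default_registry",
]

#: Hard physiologic envelope for VO2 input (L/min).  Resting adult VO2 sits
#: near 0.25-0.35 L/min and elite maximal values below 6 L/min; values
#: outside this band are rejected outright rather than extrapolated.
HARD_ENVELOPE = (0.3, 6.0)

#: Validity range of the shipped default calibrations (L/min), modestly
#: extending the span of the worked examples they were recovered from.
DEFAULT_VALID_RANGE = (1.0, 4.0)

_POSITIVITY_GRID_POINTS = 401


@dataclass(frozen=True)
class DeviceCalibration:
    """Polynomial sigma(mu) for one indirect-calorimetry system.

    Parameters
    ----------
    device_id : str
        Canonical label, e.g. ``"parvo_2400"`` or ``"douglas_bag"``.
    coefficients : tuple of float
        Ascending polynomial coefficients c0..ck so that
        ``sigma(mu) = sum(c_i * mu**i)``.
    order : int
        Polynomial order, 1 to 3; ``len(coefficients) == order + 1``.
    valid_range : tuple of float
        Closed interval [mu_min, mu_max] (L/min) over which the calibration
        is considered trustworthy; sigma positivity is enforced here.
    provenance : str
        Free-text origin note (e.g. fit diagnostics, or a note that the
        coefficients were recovered from published overlap values).
    """

    device_id: str
    coefficients: tuple[float, ...]
    order: int
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "valid_range", (float(self.valid_range[0]), float(self.valid_range[1])))
        if not 1 <= self.order <= 3:
            raise InvalidInputError(f"polynomial order must be 1-3, got {self.order}")
        if len(self.coefficients) != self.order + 1:
            raise InvalidInputError(
                f"expected {self.order + 1} coefficients for order {self.order}, "
                f"got {len(self.coefficients)}"
            )
        lo, hi = self.valid_range
        if not (lo > 0 and lo < hi):
            raise InvalidInputError(f"valid_range must satisfy 0 < mu_min < mu_max, got {self.valid_range}")
        # Positivity of sigma over the validity range, checked on a dense grid.
        grid = np.linspace(lo, hi, _POSITIVITY_GRID_POINTS)
        sig = np.polynomial.polynomial.polyval(grid, self.coefficients)
        if np.any(sig <= 0):
            bad = grid[np.argmin(sig)]
            raise CalibrationDomainError(
                f"calibration '{self.device_id}' yields sigma <= 0 inside its "
                f"valid range (e.g. at mu={bad:.3f} L/min)"
            )

    def sigma(self, mu: float) -> float:
        """Evaluate sigma(mu); see module-level :func:`sigma_at`."""
        return sigma_at(self, mu)


@dataclass(frozen=True)
class MeasurementDistribution:
    """One VO2 measurement modeled as a normal error distribution."""

    mu: float
    sigma: float
    device_id: str

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise InvalidInputError(f"mu must be positive, got {self.mu}")
        if not self.sigma > 0:
            raise InvalidInputError(f"sigma must be positive, got {self.sigma}")


def sigma_at(cal: DeviceCalibration, mu: float) -> float:
    """Standard deviation of device `cal` at measured level `mu` (L/min).

    Evaluates the calibration polynomial.  Inside the hard physiologic
    envelope but outside the calibration's validity range the polynomial is
    extrapolated with a warning; outside the envelope a :class:`RangeError`
    is raised.  A non-positive evaluated sigma raises
    :class:`CalibrationDomainError`.
    """
    if not mu > 0:
        raise InvalidInputError(f"VO2 must be positive, got {mu} L/min")
    if not HARD_ENVELOPE[0] <= mu <= HARD_ENVELOPE[1]:
        raise RangeError(
            f"VO2 {mu} L/min is outside the physiologic envelope "
            f"[{HARD_ENVELOPE[0]}, {HARD_ENVELOPE[1]}] L/min"
        )
    lo, hi = cal.valid_range
    if not lo <= mu <= hi:
        warnings.warn(
            f"VO2 {mu} L/min is outside the validity range [{lo}, {hi}] of "
            f"calibration '{cal.device_id}'; extrapolating",
            UserWarning,
            stacklevel=2,
        )
    sigma = float(np.polynomial.polynomial.polyval(mu, cal.coefficients))
    if sigma <= 0:
        raise CalibrationDomainError(
            f"calibration '{cal.device_id}' evaluates to sigma={sigma:.4g} <= 0 "
            f"at mu={mu} L/min"
        )
    return sigma


class CalibrationRegistry(Mapping[str, DeviceCalibration]):
    """Immutable lookup of device calibrations by identifier.

    Passed explicitly to the comparison functions (no global mutable
    state); unknown device identifiers fail loudly with the list of known
    devices.
    """

    def __init__(self, calibrations: Mapping[str, DeviceCalibration] | list[DeviceCalibration]):
        if isinstance(calibrations, Mapping):
            items = dict(calibrations)
        else:
            items = {cal.device_id: cal for cal in calibrations}
        for key, cal in items.items():
            if key != cal.device_id:
                raise InvalidInputError(
                    f"registry key '{key}' does not match calibration id '{cal.device_id}'"
                )
        self._calibrations: dict[str, DeviceCalibration] = items

    def __getitem__(self, device_id: str) -> DeviceCalibration:
        try:
            return self._calibrations[device_id]
        except KeyError:
            known = ", ".join(sorted(self._calibrations)) or "(none)"
            raise UnknownDeviceError(
                f"unknown device '{device_id}'; known devices: {known}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._calibrations)

    def __len__(self) -> int:
        return len(self._calibrations)

    def to_yaml(self, path) -> None:
        """Serialize to a registry YAML file (repr-roundtrip precision)."""
        payload = {
            "devices": {
                cal.device_id: {
                    "coefficients": [float(c) for c in cal.coefficients],
                    "order": cal.order,
                    "valid_range": [float(v) for v in cal.valid_range],
                    "provenance": cal.provenance,
                }
                for cal in self._calibrations.values()
            }
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationRegistry":
        """Load a registry from a YAML file written by :meth:`to_yaml`."""
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "CalibrationRegistry":
        if not isinstance(payload, dict) or "devices" not in payload:
            raise InvalidInputError("registry file must contain a top-level 'devices' mapping")
        cals = {
            device_id: DeviceCalibration(
                device_id=device_id,
                coefficients=tuple(entry["coefficients"]),
                order=int(entry["order"]),
                valid_range=tuple(entry["valid_range"]),
                provenance=str(entry.get("provenance", "")),
            )
            for device_id, entry in payload["devices"].items()
        }
        return cls(cals)


def make_distribution(
    mu: float, device_id: str, registry: CalibrationRegistry
) -> MeasurementDistribution:
    """Turn a VO2 value into its device-specific normal error distribution.

    Deterministic: the returned distribution is exactly
    ``(mu, sigma_at(registry[device_id], mu), device_id)`` with no internal
    rounding of `mu`.
    """
    cal = registry[device_id]
    return MeasurementDistribution(mu=mu, sigma=sigma_at(cal, mu), device_id=device_id)


_DEFAULT_REGISTRY: CalibrationRegistry | None = None


def default_registry() -> CalibrationRegistry:
    """Shipped default calibrations (ParvoMedics 2400 TrueOne, Douglas bag).

    Loaded once from packaged data; the file is the deterministic output of
    :func:`vo2overlap.calibrate.recover_default_calibrations` on the shipped
    worked-example constraint table.
    """
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        ref = resources.files("vo2overlap.data").joinpath("default_calibrations.yaml")
        payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT_REGISTRY = CalibrationRegistry._from_payload(payload)
    return _DEFAULT_REGISTRY
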