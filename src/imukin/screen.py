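"""Rule-based pre-screening of sensors from early-trial IK orientation
differences.

Two rules are applied to each sensor's inverse-kinematics orientation
difference theta over the first 10 s of a trial:

(i)  *absolute*: any sample exceeding 45 degrees indicates poor orientation
     tracking;
(ii) *range*: the mean of per-bin (60 ms) theta ranges exceeding 30 degrees
     indicates unrealistic high-frequency variability.

A sensor firing either rule is excluded; the recommended workflow is
screen → drop excluded sensors (weight 0) → re-run IK on the full trial.
Thresholds exactly at the boundary do not fire (strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["ScreenConfig", "SensorScreen", "ScreenReport", "screen", "screen_trial"]

log = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    window_s: float = 10.0
    abs_threshold_deg: float = 45.0
    bin_ms: float = 60.0
    range_threshold_deg: float = 30.0
    #: statistic for rule (i): "max" (any sample) or "mean" over the window
    abs_statistic: str = "max"

    def __post_init__(self):
        for name in ("window_s", "abs_threshold_deg", "bin_ms", "range_threshold_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.abs_statistic not in ("max", "mean"):
            raise ValueError("abs_statistic must be 'max' or 'mean'")


@dataclass
class SensorScreen:
    included: bool
    rule: str  # none | absolute | range | both
    max_theta_deg: float
    mean_bin_range_deg: float


@dataclass
class ScreenReport:
    sensors: dict

    @property
    def excluded(self) -> list:
        return sorted(s for s, r in self.sensors.items() if not r.included)

    @property
    def included(self) -> list:
        return sorted(s for s, r in self.sensors.items() if r.included)

    def to_dict(self) -> dict:
        return {
            s: {
                "included": r.included,
                "rule": r.rule,
                "max_theta_deg": r.max_theta_deg,
                "mean_bin_range_deg": r.mean_bin_range_deg,
            }
            for s, r in self.sensors.items()
        }

    def weights_after_exclusion(self, weights: Mapping[str, float]) -> dict:
        """Copy of ``weights`` with excluded sensors set to 0."""
        out = dict(weights)
        for s in self.excluded:
            if s in out:
                out[s] = 0.0
        return out


def _screen_one(theta_deg: np.ndarray, rate_hz: float, config: ScreenConfig) -> SensorScreen:
    n_needed = int(round(config.window_s * rate_hz))
    theta = np.asarray(theta_deg, float)
    if len(theta) < n_needed:
        raise ValueError(
            f"theta series covers {len(theta)} samples; "
            f"{n_needed} needed for a {config.window_s} s window at {rate_hz} Hz"
        )
    theta = theta[:n_needed]
    stat = float(np.max(theta)) if config.abs_statistic == "max" else float(np.mean(theta))
    fired_abs = stat > config.abs_threshold_deg
    bin_n = int(round(config.bin_ms * rate_hz / 1000.0))
    if bin_n < 2:
        log.warning(
            "bin of %d samples at %g Hz floored to 2 samples", bin_n, rate_hz
        )
        bin_n = 2
    n_bins = len(theta) // bin_n
    binned = theta[: n_bins * bin_n].reshape(n_bins, bin_n)
    ranges = binned.max(axis=1) - binned.min(axis=1)
    mean_range = float(np.mean(ranges)) if n_bins else 0.0
    fired_range = mean_range > config.range_threshold_deg
    rule = {
        (False, False): "none",
        (True, False): "absolute",
        (False, True): "range",
        (True, True): "both",
    }[(fired_abs, fired_range)]
    return SensorScreen(
        included=rule == "none",
        rule=rule,
        max_theta_deg=float(np.max(theta)),
        mean_bin_range_deg=mean_range,
    )


def screen(theta: Mapping[str, np.ndarray], rate_hz: float, config: ScreenConfig | None = None) -> ScreenReport:
    """Apply both rules to per-sensor theta series (degrees) covering at
    least the screening window at ``rate_hz``."""
    config = config or ScreenConfig()
    return ScreenReport({s: _screen_one(v, rate_hz, config) for s, v in theta.items()})


def screen_trial(
    model,
    registration,
    orientations: Mapping,
    weights: Mapping[str, float] | None = None,
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """Run a single all-sensor IK pass over the first screening window and
    screen each sensor on its resulting orientation differences."""
    from .ik import ik_trajectory

    config = config or ScreenConfig()
    t0 = next(iter(orientations.values())).t[0]
    window = {
        s: ser.slice(t0, t0 + config.window_s + 1e-9) for s, ser in orientations.items()
    }
    n = len(next(iter(window.values())))
    if n < 2:
        raise ValueError("orientation series shorter than the screening window")
    dt = np.median(np.diff(next(iter(window.values())).t))
    rate_hz = 1.0 / dt
    result = ik_trajectory(model, registration, window, weights)
    return screen(result.theta_deg, rate_hz, config)
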