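"""Soil-water-deficit-triggered irrigation scheduling.

An irrigation is applied on any in-season day the soil water deficit of the
monitored depth (default 0-60 cm) reaches the policy threshold, expressed
as a fraction of that depth's plant available water capacity.  The applied
amount is 120% of the deficit by default, representing the over-application
inherent to flood irrigation.  ``rainfed`` never irrigates; ``potential``
disables both irrigation accounting and water stress (non-limiting water).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IrrigationPolicy", "should_irrigate", "irrigation_amount"]

MODES = ("swd_threshold", "rainfed", "potential")


@dataclass(frozen=True)
class IrrigationPolicy:
    mode: str = "swd_threshold"
    threshold: float = 0.5            # fraction of PAWC(0-60 cm)
    application_multiplier: float = 1.2
    monitored_depth_mm: float = 600.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "swd_threshold" and not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")

    @property
    def label(self) -> str:
        if self.mode == "swd_threshold":
            return f"{self.threshold:.0%}"
        return self.mode


def should_irrigate(swd_mm: float, pawc60_mm: float, policy: IrrigationPolicy,
                    in_season: bool = True) -> bool:
    """True iff the deficit has reached the threshold on an in-season day."""
    if swd_mm < 0 or pawc60_mm < 0:
        raise ValueError("swd and pawc must be non-negative")
    if policy.mode != "swd_threshold" or not in_season:
        return False
    if pawc60_mm == 0:
        raise ValueError("pawc60 must be positive for threshold scheduling")
    return swd_mm >= policy.threshold * pawc60_mm


def irrigation_amount(swd_mm: float, policy: IrrigationPolicy) -> float:
    """Applied depth: multiplier x deficit, mm."""
    if swd_mm < 0:
        raise ValueError("swd must be non-negative")
    return policy.application_multiplier * swd_mm
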