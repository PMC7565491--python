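"""Deterministic assay arithmetic: extinction coefficients, Beer-Lambert
concentrations and percent inhibition of enzyme-activity readings.

Peptide concentrations are determined from A280 with the standard molar
extinction coefficients for tryptophan (5690), tyrosine (1280) and cystine
(120 M^-1 cm^-1).  Inhibition is expressed relative to the uninhibited
negative control after background subtraction, clamped to [0, 100] with an
explicit flag rather than erroring on activation or noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import composition

__all__ = [
    "EPS_TRP",
    "EPS_TYR",
    "EPS_CYSTINE",
    "AssayReading",
    "InhibitionResult",
    "ControlError",
    "extinction_coefficient",
    "molar_concentration",
    "percent_inhibition",
    "summarize_inhibition",
]

EPS_TRP = 5690.0  # M^-1 cm^-1 at 280 nm
EPS_TYR = 1280.0
EPS_CYSTINE = 120.0


class ControlError(ValueError):
    """Negative control equals background: inhibition is undefined."""


@dataclass(frozen=True)
class AssayReading:
    signal: float
    negative_control: float
    background: float


@dataclass(frozen=True)
class InhibitionResult:
    percent: float
    clamped: bool


def extinction_coefficient(sequence: str, n_cystines: int) -> float:
    """Molar extinction coefficient at 280 nm from W/Y counts and cystines."""
    counts = composition(sequence)
    if n_cystines < 0 or n_cystines > counts["C"] // 2:
        raise ValueError(
            f"{n_cystines} cystines impossible for {counts['C']} Cys"
        )
    return counts["W"] * EPS_TRP + counts["Y"] * EPS_TYR + n_cystines * EPS_CYSTINE


def molar_concentration(a280: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Beer-Lambert: c = A / (epsilon * l), in mol/L."""
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return a280 / (epsilon * path_cm)


def percent_inhibition(r: AssayReading) -> InhibitionResult:
    """Inhibition relative to total (uninhibited) enzyme activity.

    100 * (1 - (signal - background) / (negative_control - background)),
    clamped to [0, 100] with ``clamped=True`` when out of range.
    """
    span = r.negative_control - r.background
    if span == 0:
        raise ControlError("negative control equals background")
    pct = 100.0 * (1.0 - (r.signal - r.background) / span)
    clamped = not 0.0 <= pct <= 100.0
    return InhibitionResult(percent=float(np.clip(pct, 0.0, 100.0)), clamped=clamped)


def summarize_inhibition(readings: list[AssayReading]) -> tuple[float, float]:
    """Mean and standard deviation of percent inhibition over replicates."""
    values = [percent_inhibition(r).percent for r in readings]
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
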