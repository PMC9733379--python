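"""Accuracy metrics for measured-vs-estimated series.

Two determination coefficients are reported everywhere: ``r2_paper`` is the
variance ratio sum((est - mean_meas)^2) / sum((meas - mean_meas)^2), which can
exceed 1; ``r2_standard`` is the conventional 1 - SSres/SStot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

__all__ = ["PairedSeries", "mae", "rmse", "r2_paper", "r2_standard", "metrics_report"]


@dataclass(frozen=True)
class PairedSeries:
    """Aligned measured/estimated value pairs."""

    measured: np.ndarray
    estimated: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=float).ravel()
        e = np.asarray(self.estimated, dtype=float).ravel()
        if m.shape != e.shape:
            raise ValidationError(
                f"length mismatch: measured {m.shape[0]} vs estimated {e.shape[0]}"
            )
        if m.size == 0:
            raise ValidationError("empty series")
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "estimated", e)

    @property
    def n(self) -> int:
        return self.measured.size

    @property
    def mean_measured(self) -> float:
        return float(self.measured.mean())


def _pair(measured, estimated=None) -> PairedSeries:
    if isinstance(measured, PairedSeries):
        return measured
    return PairedSeries(measured, estimated)


def mae(measured, estimated=None) -> float:
    s = _pair(measured, estimated)
    return float(np.mean(np.abs(s.measured - s.estimated)))


def rmse(measured, estimated=None) -> float:
    s = _pair(measured, estimated)
    return float(np.sqrt(np.mean((s.measured - s.estimated) ** 2)))


def r2_paper(measured, estimated=None) -> float:
    """Variance-ratio determination coefficient (may exceed 1)."""
    s = _pair(measured, estimated)
    if s.n < 2:
        raise ValidationError("r2 needs at least 2 pairs")
    sst = float(np.sum((s.measured - s.mean_measured) ** 2))
    if sst == 0.0:
        raise DegenerateGeometryError("measured series has zero variance")
    return float(np.sum((s.estimated - s.mean_measured) ** 2)) / sst


def r2_standard(measured, estimated=None) -> float:
    """Conventional coefficient of determination, 1 - SSres/SStot."""
    s = _pair(measured, estimated)
    if s.n < 2:
        raise ValidationError("r2 needs at least 2 pairs")
    sst = float(np.sum((s.measured - s.mean_measured) ** 2))
    if sst == 0.0:
        raise DegenerateGeometryError("measured series has zero variance")
    ssr = float(np.sum((s.measured - s.estimated) ** 2))
    return 1.0 - ssr / sst


def metrics_report(measured, estimated=None) -> dict:
    s = _pair(measured, estimated)
    return {
        "mae": mae(s),
        "rmse": rmse(s),
        "r2_paper": r2_paper(s),
        "r2_standard": r2_standard(s),
        "n": s.n,
    }
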