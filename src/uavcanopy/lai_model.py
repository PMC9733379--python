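"""Multivariate linear LAI model: published coefficients, prediction, stepwise fit.

The model is affine in a set of canopy descriptors and scaled by the row
spacing delta:  LAI = (sum_w t_w * g_w + j) / delta.  The shipped published
model uses descriptors (g, d_t, h_e): density-grid occupancy ratio, maximum
canopy diameter (m) and estimated height (m).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import NumericError, ValidationError

__all__ = [
    "LaiLinearModel",
    "published_model",
    "predict_lai",
    "fit_lai_stepwise",
    "PUBLISHED_ROW_SPACING",
    "PLANTED_ROW_SPACING",
]

logger = logging.getLogger(__name__)

#: Row spacing used by the published model's divisor.
PUBLISHED_ROW_SPACING = 0.76
#: Agronomic row spacing of the study field (m); conflicts with the divisor above.
PLANTED_ROW_SPACING = 0.60


@dataclass(frozen=True)
class LaiLinearModel:
    """Affine LAI model on named descriptors, scaled by row spacing."""

    descriptors: Tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    row_spacing: float
    diagnostics: Dict[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (len(self.descriptors),):
            raise ValidationError("coefficient count must equal descriptor count")
        if self.row_spacing <= 0:
            raise ValidationError("row spacing must be > 0")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "descriptors", tuple(self.descriptors))

    def to_json(self) -> str:
        return json.dumps(
            {
                "descriptors": list(self.descriptors),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "row_spacing": self.row_spacing,
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "LaiLinearModel":
        d = json.loads(s)
        return cls(
            descriptors=tuple(d["descriptors"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            row_spacing=float(d["row_spacing"]),
            diagnostics=d.get("diagnostics", {}),
        )


def published_model() -> LaiLinearModel:
    """The shipped three-descriptor model (g, d_t, h_e)."""
    return LaiLinearModel(
        descriptors=("g", "d_t", "h_e"),
        coefficients=np.array([1.37618, 0.66738, -0.02035]),
        intercept=-0.51087,
        row_spacing=PUBLISHED_ROW_SPACING,
    )


def predict_lai(model: LaiLinearModel, features: pd.DataFrame) -> pd.Series:
    """Predict LAI per feature row; negative predictions are flagged, not clipped."""
    missing = [d for d in model.descriptors if d not in features.columns]
    if missing:
        raise ValidationError(f"missing descriptor column(s): {', '.join(missing)}")
    x = features[list(model.descriptors)].to_numpy(dtype=float)
    lai = (x @ model.coefficients + model.intercept) / model.row_spacing
    out = pd.Series(lai, index=features.index, name="lai_pred")
    n_neg = int((out < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} negative LAI prediction(s); affine model output returned as-is",
            stacklevel=2,
        )
    return out


def _fit_ols(y: np.ndarray, x: pd.DataFrame):
    design = sm.add_constant(x, has_constant="add")
    res = sm.OLS(y, design).fit()
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise NumericError(
            f"rank-deficient design; collinear descriptors among {list(x.columns)}"
        )
    return res


def fit_lai_stepwise(
    table: pd.DataFrame,
    candidates: Optional[Sequence[str]] = None,
    row_spacing: float = PUBLISHED_ROW_SPACING,
    criterion: str = "aic",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> LaiLinearModel:
    """Bidirectional stepwise OLS of LAI * row_spacing on candidate descriptors.

    ``criterion="aic"`` adds/drops the move with the best AIC improvement
    until no move helps; ``criterion="pvalue"`` uses entry/stay thresholds.
    The returned coefficients are on the row-spacing-scaled side, i.e. the
    model predicts LAI = (x @ t + j) / row_spacing.
    """
    if row_spacing <= 0:
        raise ValidationError("row spacing must be > 0")
    if row_spacing != PLANTED_ROW_SPACING:
        logger.warning(
            "fitting with row spacing %.2f m (field planting used %.2f m)",
            row_spacing,
            PLANTED_ROW_SPACING,
        )
    if "lai" not in table.columns:
        raise ValidationError("feature table needs a measured 'lai' column to fit")
    if candidates is None:
        candidates = [c for c in table.columns if c not in ("lai", "quadrat_id", "plot_id")]
    candidates = list(candidates)
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValidationError(f"missing candidate column(s): {', '.join(missing)}")
    data = table.dropna(subset=["lai", *candidates]).sort_index()
    if len(data) < 10:
        raise ValidationError(f"need >= 10 complete rows to fit, have {len(data)}")
    y = data["lai"].to_numpy(dtype=float) * row_spacing

    if criterion == "aic":
        selected = _stepwise_aic(y, data, candidates)
    elif criterion == "pvalue":
        selected = _stepwise_pvalue(y, data, candidates, p_enter, p_remove)
    else:
        raise ValidationError(f"unknown stepwise criterion {criterion!r}")

    res = _fit_ols(y, data[selected])
    params = res.params
    conf = res.conf_int(alpha=0.05)
    diagnostics = {
        "r_squared": float(res.rsquared) if len(selected) else 0.0,
        "resid_sd": float(np.sqrt(res.mse_resid)),
        "aic": float(res.aic),
        "n": int(res.nobs),
    }
    for name in selected:
        diagnostics[f"ci_low_{name}"] = float(conf.loc[name, 0])
        diagnostics[f"ci_high_{name}"] = float(conf.loc[name, 1])
    return LaiLinearModel(
        descriptors=tuple(selected),
        coefficients=np.array([params[name] for name in selected]),
        intercept=float(params["const"]),
        row_spacing=row_spacing,
        diagnostics=diagnostics,
    )


def _stepwise_aic(y, data, candidates):
    selected: list = []
    current = _fit_ols(y, data[selected]).aic
    while True:
        moves = []
        for c in candidates:
            if c not in selected:
                moves.append(([*selected, c], "add", c))
        for c in selected:
            moves.append(([s for s in selected if s != c], "drop", c))
        best = None
        for cols, _, _ in moves:
            aic = _fit_ols(y, data[cols]).aic
            if aic < current - 1e-10 and (best is None or aic < best[0]):
                best = (aic, cols)
        if best is None:
            return selected
        current, selected = best[0], best[1]


def _stepwise_pvalue(y, data, candidates, p_enter, p_remove):
    selected: list = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            pvals = {}
            for c in remaining:
                res = _fit_ols(y, data[[*selected, c]])
                pvals[c] = float(res.pvalues[c])
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                selected.append(best)
                changed = True
        if selected:
            res = _fit_ols(y, data[selected])
            worst = max(selected, key=lambda c: float(res.pvalues[c]))
            if float(res.pvalues[worst]) > p_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            return selected
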