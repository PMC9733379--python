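"""End-to-end analysis: localize -> ground model -> heights -> features -> LAI.

``run_pipeline`` chains the stages on in-memory objects and returns a
:class:`RunReport`; the CLI wraps it with file I/O.  Stages mirror the
method order of the underlying field study: geodetic localization, DSM
rasterization, sampled-height ground inversion, percentile heights,
above-ground density/diameter descriptors, LAI prediction or stepwise fit,
and paired accuracy metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .canopy_density import (
    CanopyCloud,
    canopy_diameter,
    density_grid,
    occupancy_ratio,
    segment_above_ground,
)
from .canopy_height import PlotLayout, estimate_heights, rasterize_dsm, upper_boundary_p99
from .errors import ValidationError
from .evaluation import metrics_report
from .geodesy import GeorefPointCloud, LocalFrame, localize_cloud
from .lai_model import LaiLinearModel, fit_lai_stepwise, predict_lai, published_model
from .terrain import GroundModel, ground_from_samples

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "extract_features"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Numeric knobs for a pipeline run (I/O-free; paths live in the CLI)."""

    cell_size: float = 0.05
    percentile: float = 99.0
    eps: float = 1.0  # density-grid cell for whole-field maps
    feature_eps: float = 0.1  # density-grid cell for per-quadrat descriptors
    axes: str = "xe"
    ground_mode: str = "inverted"
    ground_threshold: float = 0.08  # above-ground segmentation buffer (m)
    row_spacing: float = 0.76
    lai_mode: str = "predict"  # "predict" (published model) or "fit"
    stepwise_criterion: str = "aic"
    diameter_method: str = "hull"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.eps <= 0 or self.feature_eps <= 0:
            raise ValidationError("cell sizes must be > 0")
        if not 0 < self.percentile <= 100:
            raise ValidationError("percentile must lie in (0, 100]")
        if self.lai_mode not in ("predict", "fit"):
            raise ValidationError(f"unknown lai_mode {self.lai_mode!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    """All pipeline outputs plus provenance."""

    config: PipelineConfig
    frame: Optional[LocalFrame]
    ground: GroundModel
    heights: pd.DataFrame  # plot- and quadrat-level height table
    features: pd.DataFrame  # per-quadrat descriptors + predicted LAI
    model: LaiLinearModel
    height_metrics: Optional[dict]
    lai_metrics: Optional[dict]
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"uavcanopy run {self.provenance.get('config_hash', '')}",
            f"  plots: {self.heights['quadrat_id'].isna().sum()}"
            f"  quadrats: {self.heights['quadrat_id'].notna().sum()}",
            f"  LAI model: {self.model.descriptors} / delta={self.model.row_spacing}",
        ]
        if self.height_metrics:
            m = self.height_metrics
            lines.append(
                f"  height: MAE={m['mae']:.4f} RMSE={m['rmse']:.4f} "
                f"R2={m['r2_standard']:.4f} (paper-style {m['r2_paper']:.4f})"
            )
        if self.lai_metrics:
            m = self.lai_metrics
            lines.append(
                f"  LAI:    MAE={m['mae']:.4f} RMSE={m['rmse']:.4f} "
                f"R2={m['r2_standard']:.4f} (paper-style {m['r2_paper']:.4f})"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "ground": {str(k): v for k, v in self.ground.per_plot.items()},
                "heights": self.heights.to_dict(orient="records"),
                "features": self.features.to_dict(orient="records"),
                "model": json.loads(self.model.to_json()),
                "height_metrics": self.height_metrics,
                "lai_metrics": self.lai_metrics,
            },
            indent=2,
            default=float,
        )


def _quadrat_p99(dsm, layout: PlotLayout, percentile: float) -> pd.DataFrame:
    q2p = layout.quadrat_plot()
    rows = [
        {
            "quadrat_id": q.id,
            "plot_id": q2p[q.id],
            "p99": upper_boundary_p99(dsm, q.bounds, percentile),
        }
        for q in layout.quadrats
    ]
    return pd.DataFrame(rows)


def attach_plot_relative_heights(
    cloud: GeorefPointCloud, ground: GroundModel, layout: PlotLayout
) -> GeorefPointCloud:
    """Per-point e = z - plot ground elevation; points outside all plots get NaN."""
    e = np.full(len(cloud), np.nan)
    for plot in layout.plots:
        xmin, ymin, xmax, ymax = plot.bounds
        m = (
            (cloud.x >= xmin)
            & (cloud.x < xmax)
            & (cloud.y >= ymin)
            & (cloud.y < ymax)
        )
        e[m] = cloud.z[m] - ground.plot_elevation(plot.id)
    return cloud.with_e(e)


def extract_features(
    canopy: CanopyCloud,
    layout: PlotLayout,
    heights: pd.DataFrame,
    feature_eps: float = 0.1,
    axes: str = "xe",
    diameter_method: str = "hull",
) -> pd.DataFrame:
    """Per-quadrat descriptor table (g, d_t, h_e) for the LAI model."""
    h_by_quadrat = (
        heights.dropna(subset=["quadrat_id"]).set_index("quadrat_id")["h_est"].to_dict()
    )
    q2p = layout.quadrat_plot()
    rows = []
    for q in layout.quadrats:
        xmin, ymin, xmax, ymax = q.bounds
        m = (
            (canopy.points[:, 0] >= xmin)
            & (canopy.points[:, 0] < xmax)
            & (canopy.points[:, 1] >= ymin)
            & (canopy.points[:, 1] < ymax)
        )
        sub = CanopyCloud(points=canopy.points[m], e=canopy.e[m])
        if len(sub) >= 2:
            g = occupancy_ratio(density_grid(sub, eps=feature_eps, axes=axes))
            d_t = canopy_diameter(sub, method=diameter_method)
        else:
            g, d_t = 0.0, 0.0
        rows.append(
            {
                "quadrat_id": q.id,
                "plot_id": q2p[q.id],
                "g": g,
                "d_t": d_t,
                "h_e": float(h_by_quadrat.get(q.id, np.nan)),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cloud: GeorefPointCloud,
    measurements: pd.DataFrame,
    layout: PlotLayout,
    config: Optional[PipelineConfig] = None,
) -> RunReport:
    """Run the full analysis on a WGS84 (or already LOCAL) cloud."""
    config = config or PipelineConfig()
    if config.lai_mode == "fit" and "lai" not in measurements.columns:
        raise ValidationError("lai_mode='fit' needs a measured 'lai' column")
    if "h_c" not in measurements.columns:
        raise ValidationError("measurements need an 'h_c' column for ground inversion")

    logger.info("stage localize: %d points", len(cloud))
    if cloud.frame == "WGS84":
        local = localize_cloud(cloud)
    elif cloud.frame == "LOCAL":
        local = cloud
    else:
        raise ValidationError(f"stage localize: unsupported input frame {cloud.frame}")

    logger.info("stage dsm: cell %.3f m", config.cell_size)
    dsm = rasterize_dsm(local, cell_size=config.cell_size)

    logger.info("stage ground (%s mode)", config.ground_mode)
    p99q = _quadrat_p99(dsm, layout, config.percentile)
    ground = ground_from_samples(p99q, measurements, layout, mode=config.ground_mode)

    logger.info("stage heights")
    heights = estimate_heights(dsm, ground, layout, percentile=config.percentile)

    logger.info("stage density features")
    local = attach_plot_relative_heights(local, ground, layout)
    canopy = segment_above_ground(local, threshold=config.ground_threshold)
    features = extract_features(
        canopy,
        layout,
        heights,
        feature_eps=config.feature_eps,
        axes=config.axes,
        diameter_method=config.diameter_method,
    )

    logger.info("stage lai (%s)", config.lai_mode)
    merged = features.merge(
        measurements[[c for c in ("quadrat_id", "lai") if c in measurements.columns]],
        on="quadrat_id",
        how="left",
    )
    if config.lai_mode == "fit":
        model = fit_lai_stepwise(
            merged,
            candidates=["g", "d_t", "h_e"],
            row_spacing=config.row_spacing,
            criterion=config.stepwise_criterion,
        )
    else:
        model = published_model()
    features = merged
    features["lai_pred"] = predict_lai(model, features)

    logger.info("stage metrics")
    hm = None
    qheights = heights.dropna(subset=["quadrat_id"]).set_index("quadrat_id")["h_est"]
    hc = measurements.set_index("quadrat_id")["h_c"]
    common = qheights.index.intersection(hc.index)
    if len(common) >= 2:
        hm = metrics_report(hc.loc[common].to_numpy(), qheights.loc[common].to_numpy())
    lm = None
    if "lai" in features.columns and features["lai"].notna().sum() >= 2:
        ok = features["lai"].notna()
        lm = metrics_report(
            features.loc[ok, "lai"].to_numpy(), features.loc[ok, "lai_pred"].to_numpy()
        )

    provenance = {
        "config_hash": config.hash(),
        "version": __version__,
        "seed": config.seed,
        "n_points": len(cloud),
    }
    return RunReport(
        config=config,
        frame=local.local_frame,
        ground=ground,
        heights=heights,
        features=features,
        model=model,
        height_metrics=hm,
        lai_metrics=lm,
        provenance=provenance,
    )
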