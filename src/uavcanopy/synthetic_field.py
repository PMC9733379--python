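"""Synthetic cotton-field point clouds with full ground truth.

Generates a sloped terrain plane sprinkled with ground points, row-planted
plants built from vertical stem points plus a Gaussian-ellipsoid leaf blob
whose point count shrinks with a defoliation-stage parameter, and per-quadrat
measurements (tallest-plant height, LAI from a known linear model plus
noise).  The cloud is emitted in WGS84 through the real inverse geodetic
transform, so the whole pipeline can be exercised end-to-end offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .canopy_density import CanopyCloud, canopy_diameter, density_grid, occupancy_ratio
from .canopy_height import Plot, PlotLayout, Quadrat
from .errors import ValidationError
from .geodesy import (
    GeoPoint,
    GeorefPointCloud,
    build_local_frame,
    delocalize_cloud,
)

__all__ = ["FieldConfig", "GroundTruth", "make_plot_layout", "generate_field"]

#: Geodetic anchor used by default for synthetic fields.
DEFAULT_ORIGIN = GeoPoint(37.947351231, 117.835755425, 4.1627)


@dataclass(frozen=True)
class FieldConfig:
    """Knobs for the synthetic field; defaults emulate the study layout."""

    extent: Tuple[float, float] = (40.0, 20.0)
    origin: GeoPoint = DEFAULT_ORIGIN
    base_elevation: float = 0.0
    slope: Tuple[float, float] = (0.004, 0.002)  # dz/dx, dz/dy (m/m)
    row_spacing: float = 0.60
    plant_spacing: float = 0.25
    plot_buffer: float = 0.3  # unplanted alley half-width along plot borders (m)
    plant_height_mean: float = 0.60
    plant_height_sd: float = 0.05  # within-plot spread
    height_trend_amp: float = 0.15  # amplitude of the smooth between-plot trend (m)
    canopy_radius: float = 0.25
    canopy_radius_spread: float = 0.25  # relative per-plot variation of the radius
    points_per_plant: int = 200
    ground_density: float = 50.0  # points / m^2
    noise_sd: float = 0.005  # per-point elevation noise (m)
    stage: float = 0.0  # defoliation: fraction of leaf points removed
    stage_spread: float = 0.15  # per-plot jitter around `stage`
    sd_height: float = 0.01  # measurement noise on tallest-plant height (m)
    sd_lai: float = 0.1  # measurement noise on LAI
    lai_coefficients: Tuple[float, float, float] = (1.37618, 0.66738, -0.02035)
    lai_intercept: float = -0.51087
    lai_row_spacing: float = 0.76
    feature_eps: float = 0.1  # density-grid cell size for quadrat descriptors
    descriptor_threshold: float = 0.08  # above-ground cut used for true descriptors
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.row_spacing, self.plant_spacing, self.ground_density) <= 0:
            raise ValidationError("spacings and densities must be > 0")
        if not 0.0 <= self.stage <= 1.0:
            raise ValidationError("stage must lie in [0, 1]")
        if self.points_per_plant < 10:
            raise ValidationError("points_per_plant must be >= 10")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: FieldConfig
    layout: PlotLayout
    plane: Tuple[float, float, float]  # base, dz/dx, dz/dy
    plots: pd.DataFrame  # plot_id, ground_elev, tallest
    quadrats: pd.DataFrame  # quadrat_id, plot_id, g, d_t, h, lai_true
    lai_coefficients: dict
    n_ground_points: int
    n_plant_points: int
    n_leaf_points: int = 0
    local_points: np.ndarray = field(repr=False, default=None)

    def ground_elevation(self, x, y) -> np.ndarray:
        b, sx, sy = self.plane
        return b + sx * np.asarray(x) + sy * np.asarray(y)


def make_plot_layout(
    extent: Tuple[float, float] = (40.0, 20.0),
    plot_size: float = 5.0,
    quadrat_size: float = 1.0,
) -> PlotLayout:
    """Tile the extent into square plots, four quadrats each at fixed offsets."""
    ex, ey = extent
    nx, ny = int(ex // plot_size), int(ey // plot_size)
    if nx < 1 or ny < 1:
        raise ValidationError(
            f"extent {extent} cannot hold a single {plot_size}x{plot_size} m plot"
        )
    # Quadrat lower-left offsets inside a plot, one per plot quadrant.
    gap = (plot_size / 2.0 - quadrat_size) / 2.0
    offs = [
        (gap, gap),
        (plot_size / 2.0 + gap, gap),
        (gap, plot_size / 2.0 + gap),
        (plot_size / 2.0 + gap, plot_size / 2.0 + gap),
    ]
    plots = []
    for j in range(ny):
        for i in range(nx):
            x0, y0 = i * plot_size, j * plot_size
            pid = f"p{j * nx + i:02d}"
            quadrats = tuple(
                Quadrat(
                    id=f"{pid}q{k}",
                    bounds=(x0 + ox, y0 + oy, x0 + ox + quadrat_size, y0 + oy + quadrat_size),
                )
                for k, (ox, oy) in enumerate(offs)
            )
            plots.append(
                Plot(id=pid, bounds=(x0, y0, x0 + plot_size, y0 + plot_size), quadrats=quadrats)
            )
    return PlotLayout(plots=plots)


def _plant_positions(config: FieldConfig) -> np.ndarray:
    ex, ey = config.extent
    rows = np.arange(config.row_spacing / 2.0, ex, config.row_spacing)
    along = np.arange(config.plant_spacing / 2.0, ey, config.plant_spacing)
    px, py = np.meshgrid(rows, along, indexing="ij")
    return np.column_stack([px.ravel(), py.ravel()])


def _in_bounds(xy: np.ndarray, bounds) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    return (
        (xy[:, 0] >= xmin) & (xy[:, 0] < xmax) & (xy[:, 1] >= ymin) & (xy[:, 1] < ymax)
    )


def generate_field(
    config: FieldConfig,
) -> Tuple[GeorefPointCloud, GroundTruth, pd.DataFrame]:
    """Build a WGS84 field cloud, its ground truth and the measurement table."""
    rng = np.random.default_rng(config.seed)
    ex, ey = config.extent
    base, (sx, sy) = config.base_elevation, config.slope
    layout = make_plot_layout((ex, ey))

    # Terrain points.
    n_ground = int(round(config.ground_density * ex * ey))
    gxy = rng.uniform((0.0, 0.0), (ex, ey), size=(n_ground, 2))
    gz = base + sx * gxy[:, 0] + sy * gxy[:, 1] + rng.normal(0.0, config.noise_sd, n_ground)

    # Plants: plot-constant mean-height offsets from a smooth fertility trend
    # (random-phase sinusoid surface sampled at plot centers, so neighbouring
    # plots stay similar and canopy spill across borders is mild), plus a
    # per-plot defoliation stage jittered around the configured stage.
    pos = _plant_positions(config)
    if config.plot_buffer > 0.0:
        # Unplanted alleys between plots keep one plot's canopy from
        # overhanging its neighbours (plots are 5 m squares).
        keep = np.ones(len(pos), dtype=bool)
        for axis in (0, 1):
            frac = np.mod(pos[:, axis], 5.0)
            keep &= np.minimum(frac, 5.0 - frac) >= config.plot_buffer
        pos = pos[keep]
    n_plants = pos.shape[0]
    ph_x, ph_y = rng.uniform(0.0, 2.0 * np.pi, 2)
    mean_height = np.full(n_plants, config.plant_height_mean)
    stage = np.full(n_plants, config.stage)
    radius = np.full(n_plants, config.canopy_radius)
    plot_stage = {}
    for plot in layout.plots:
        in_plot = _in_bounds(pos, plot.bounds)
        cx = (plot.bounds[0] + plot.bounds[2]) / 2.0
        cy = (plot.bounds[1] + plot.bounds[3]) / 2.0
        mean_height[in_plot] += config.height_trend_amp * np.sin(
            2.0 * np.pi * cx / ex + ph_x
        ) * np.cos(2.0 * np.pi * cy / ey + ph_y)
        s = float(
            np.clip(
                config.stage + rng.uniform(-config.stage_spread, config.stage_spread),
                0.0,
                1.0,
            )
        )
        plot_stage[plot.id] = s
        stage[in_plot] = s
        # Per-plot canopy width varies independently of defoliation so the
        # diameter descriptor is not collinear with the density descriptor.
        radius[in_plot] *= 1.0 + rng.uniform(
            -config.canopy_radius_spread, config.canopy_radius_spread
        )
    heights = np.clip(rng.normal(mean_height, config.plant_height_sd), 0.05, None)

    # Stems: vertical jittered columns topped by the exact apex point.
    n_stem = max(6, config.points_per_plant // 25)
    stem_plant = np.repeat(np.arange(n_plants), n_stem)
    stem_rel = rng.uniform(0.0, 1.0, stem_plant.size) * heights[stem_plant]
    apex = np.arange(n_plants) * n_stem  # first stem point of each plant
    stem_rel[apex] = heights  # guarantee the true apex exists in the cloud
    stem_xy = pos[stem_plant] + rng.normal(0.0, 0.01, (stem_plant.size, 2))

    # Apex cluster: the plant top is a small surface, not a point, so the
    # upper DSM percentile can see it.  Branch/boll structure survives
    # defoliation, so its size does not scale with stage.
    n_top = max(10, config.points_per_plant // 8)
    top_plant = np.repeat(np.arange(n_plants), n_top)
    top_r = 0.4 * radius[top_plant, None]
    top_xy = pos[top_plant] + rng.uniform(-1.0, 1.0, (top_plant.size, 2)) * top_r
    top_rel = heights[top_plant] - rng.uniform(0.0, 0.01, top_plant.size)

    # Leaves: Gaussian blob clipped to the canopy radius, count scaled by
    # (1 - stage) so defoliation strips leaf points only; the horizontal blob
    # extent contracts as the canopy thins.
    n_leaf_per = np.round(config.points_per_plant * (1.0 - stage)).astype(np.int64)
    leaf_plant = np.repeat(np.arange(n_plants), n_leaf_per)
    r_eff = radius[leaf_plant, None] * (1.0 - 0.3 * stage[leaf_plant, None])
    leaf_xy = pos[leaf_plant] + np.clip(
        rng.normal(0.0, r_eff / 2.0, (leaf_plant.size, 2)), -r_eff, r_eff
    )
    # Lowest leaves sit well above the soil so above-ground segmentation is
    # unambiguous at small thresholds.
    leaf_floor = np.minimum(0.15, 0.5 * heights[leaf_plant])
    leaf_rel = np.clip(
        rng.normal(0.55 * heights[leaf_plant], 0.22 * heights[leaf_plant]),
        leaf_floor,
        heights[leaf_plant],
    )

    plant_xy = np.vstack([stem_xy, top_xy, leaf_xy])
    plant_rel = np.concatenate([stem_rel, top_rel, leaf_rel])
    plant_z = (
        base
        + sx * plant_xy[:, 0]
        + sy * plant_xy[:, 1]
        + plant_rel
        + rng.normal(0.0, config.noise_sd, plant_rel.size)
    )

    local = np.vstack(
        [
            np.column_stack([gxy, gz]),
            np.column_stack([plant_xy, plant_z]),
        ]
    )

    # Per-quadrat truth: descriptors computed from the noiseless plant geometry
    # using the same above-ground segmentation convention as the pipeline.
    coef = np.asarray(config.lai_coefficients, dtype=float)
    qrows = []
    meas_rows = []
    for plot in layout.plots:
        for q in plot.quadrats:
            m = _in_bounds(plant_xy, q.bounds) & (plant_rel > config.descriptor_threshold)
            pts = np.column_stack([plant_xy[m], plant_rel[m]])
            sub = CanopyCloud(points=pts, e=plant_rel[m])
            g = occupancy_ratio(density_grid(sub, eps=config.feature_eps))
            d_t = canopy_diameter(sub)
            plant_mask = _in_bounds(pos, q.bounds)
            h_true = float(heights[plant_mask].max()) if plant_mask.any() else float(
                plant_rel[m].max()
            )
            lai_true = float(
                (coef @ np.array([g, d_t, h_true]) + config.lai_intercept)
                / config.lai_row_spacing
            )
            qrows.append(
                {
                    "quadrat_id": q.id,
                    "plot_id": plot.id,
                    "g": g,
                    "d_t": d_t,
                    "h": h_true,
                    "lai_true": lai_true,
                    "stage": plot_stage[plot.id],
                    "ground_elev": base
                    + sx * (q.bounds[0] + q.bounds[2]) / 2.0
                    + sy * (q.bounds[1] + q.bounds[3]) / 2.0,
                }
            )
            meas_rows.append(
                {
                    "quadrat_id": q.id,
                    "plot_id": plot.id,
                    "xmin": q.bounds[0],
                    "ymin": q.bounds[1],
                    "xmax": q.bounds[2],
                    "ymax": q.bounds[3],
                    "h_c": h_true + rng.normal(0.0, config.sd_height),
                    "lai": lai_true + rng.normal(0.0, config.sd_lai),
                }
            )
    quadrats = pd.DataFrame(qrows)
    measurements = pd.DataFrame(meas_rows)

    plot_truth = []
    for plot in layout.plots:
        sub = quadrats[quadrats["plot_id"] == plot.id]
        plant_mask = _in_bounds(pos, plot.bounds)
        plot_truth.append(
            {
                "plot_id": plot.id,
                "ground_elev": float(sub["ground_elev"].mean()),
                "tallest": float(heights[plant_mask].max()),
            }
        )

    truth = GroundTruth(
        config=config,
        layout=layout,
        plane=(base, sx, sy),
        plots=pd.DataFrame(plot_truth),
        quadrats=quadrats,
        lai_coefficients={
            "coefficients": coef.tolist(),
            "intercept": config.lai_intercept,
            "row_spacing": config.lai_row_spacing,
            "descriptors": ["g", "d_t", "h"],
        },
        n_ground_points=n_ground,
        n_plant_points=int(plant_rel.size),
        n_leaf_points=int(n_leaf_per.sum()),
        local_points=local,
    )

    frame = build_local_frame(config.origin)
    cloud_local = GeorefPointCloud(frame="LOCAL", points=local, local_frame=frame)
    cloud_wgs = delocalize_cloud(cloud_local)
    return cloud_wgs, truth, measurements
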