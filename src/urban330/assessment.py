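"""Joint 3-30-300 compliance: per-cell score, city summaries, sensitivity.

The three per-rule boolean grids are intersected at the 100 m cell
level into a 0-3 score (number of rules satisfied). City summaries are
population-weighted: POP_R3 / POP_R30 / POP_R300 marginals, the share
of population at each score, and the full-rule share (score 3). Cells
where any input is nodata are nodata and carry no population weight;
denominators use the population mass on valid cells so the score shares
always sum to one (this equals the city total on complete bundles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import CityBundle, GridLayer, require_aligned
from .rule3 import (
    ViewshedConfig,
    compute_visual_exposure,
    rule3_compliance,
    sample_viewpoints,
)
from .rule30 import Rule30Config, aggregate_neighborhood_canopy, rule30_compliance
from .rule300 import (
    Rule300Config,
    buffer_green,
    extract_green_areas,
    rule300_compliance,
)

__all__ = [
    "ComplianceGrid",
    "CityAssessment",
    "combine_rules",
    "assess_city",
    "run_assessment",
    "sensitivity_sweep",
    "aggregate_cities",
]


@dataclass
class ComplianceGrid:
    """Per-cell rule booleans and their 0-3 sum."""

    r3: GridLayer
    r30: GridLayer
    r300: GridLayer
    score: GridLayer


@dataclass
class CityAssessment:
    """Population-weighted 3-30-300 summary for one city and one config."""

    pop_r3: float
    pop_r30: float
    pop_r300: float
    share_by_score: tuple[float, float, float, float]
    config: dict = field(default_factory=dict)

    @property
    def full_rule_share(self) -> float:
        return self.share_by_score[3]


def combine_rules(r3: GridLayer, r30: GridLayer, r300: GridLayer) -> ComplianceGrid:
    """Intersect the three rule grids into the per-cell 0-3 score."""
    require_aligned(r3, r30, r300)
    mask = r3.nodata_mask | r30.nodata_mask | r300.nodata_mask
    score = (
        r3.values.astype(np.int64)
        + r30.values.astype(np.int64)
        + r300.values.astype(np.int64)
    )
    score[mask] = 0
    layer = r3.copy_with(values=score, nodata_mask=mask, variable_role="score")
    return ComplianceGrid(r3=r3, r30=r30, r300=r300, score=layer)


def _summarize(compliance: ComplianceGrid, population: GridLayer, config: dict) -> CityAssessment:
    mask = compliance.score.nodata_mask | population.nodata_mask
    pop = np.where(mask, 0.0, population.values).astype(float)
    denom = pop.sum()
    if not denom > 0:
        raise ValueError("no population on valid cells")
    score = compliance.score.values
    shares = tuple(float(pop[(score == k) & ~mask].sum() / denom) for k in range(4))
    return CityAssessment(
        pop_r3=float(pop[compliance.r3.values.astype(bool) & ~mask].sum() / denom),
        pop_r30=float(pop[compliance.r30.values.astype(bool) & ~mask].sum() / denom),
        pop_r300=float(pop[compliance.r300.values.astype(bool) & ~mask].sum() / denom),
        share_by_score=shares,
        config=config,
    )


@dataclass
class AssessmentArtifacts:
    """Everything produced while assessing one city (kept for diagnostics)."""

    assessment: CityAssessment
    compliance: ComplianceGrid
    viewpoints: object
    viewshed: object
    block_canopy: GridLayer
    green_spaces: list
    buffer: object


def run_assessment(
    bundle: CityBundle,
    viewshed_cfg: ViewshedConfig | None = None,
    rule30_cfg: Rule30Config | None = None,
    rule300_cfg: Rule300Config | None = None,
) -> AssessmentArtifacts:
    """Run all three rule stages on one city and fuse the results."""
    viewshed_cfg = viewshed_cfg or ViewshedConfig()
    rule30_cfg = rule30_cfg or Rule30Config()
    rule300_cfg = rule300_cfg or Rule300Config()
    heights = bundle.layer("building_height_m")
    trees = bundle.layer("tree_count")
    tcd = bundle.layer("tree_cover_density_pct")
    population = bundle.layer("population")
    landuse = bundle.layer("landuse_class")

    points = sample_viewpoints(bundle.boundary, viewshed_cfg)
    viewshed = compute_visual_exposure(heights, points, viewshed_cfg)
    r3 = rule3_compliance(viewshed, trees, viewshed_cfg)

    block_canopy = aggregate_neighborhood_canopy(tcd, rule30_cfg, bundle.boundary)
    r30 = rule30_compliance(block_canopy, rule30_cfg, tcd)

    greens = extract_green_areas(landuse, rule300_cfg, bundle.boundary)
    buffer = buffer_green(greens, rule300_cfg)
    r300 = rule300_compliance(buffer, population)

    compliance = combine_rules(r3, r30, r300)
    fingerprint = {
        "city_id": bundle.city_id,
        "d_m": viewshed_cfg.min_spacing_d_m,
        "r_m": viewshed_cfg.radius_r_m,
        "observer_height_m": viewshed_cfg.observer_height_m,
        "tree_threshold": viewshed_cfg.tree_threshold,
        "seed": viewshed_cfg.seed,
        "block_m": rule30_cfg.block_size_m,
        "canopy_threshold_pct": rule30_cfg.canopy_threshold_pct,
        "buffer_m": rule300_cfg.buffer_m,
        "min_area_m2": rule300_cfg.min_area_m2,
    }
    assessment = _summarize(compliance, population, fingerprint)
    return AssessmentArtifacts(
        assessment=assessment,
        compliance=compliance,
        viewpoints=points,
        viewshed=viewshed,
        block_canopy=block_canopy,
        green_spaces=greens,
        buffer=buffer,
    )


def assess_city(
    bundle: CityBundle,
    viewshed_cfg: ViewshedConfig | None = None,
    rule30_cfg: Rule30Config | None = None,
    rule300_cfg: Rule300Config | None = None,
) -> CityAssessment:
    """City-level 3-30-300 summary under one parameter configuration."""
    return run_assessment(bundle, viewshed_cfg, rule30_cfg, rule300_cfg).assessment


def sensitivity_sweep(
    bundle: CityBundle,
    d_values=(100.0, 250.0, 500.0),
    r_values=(100.0, 250.0),
    block_values=(1000.0, 500.0, 250.0, 100.0),
    viewshed_cfg: ViewshedConfig | None = None,
    rule30_cfg: Rule30Config | None = None,
    rule300_cfg: Rule300Config | None = None,
) -> pd.DataFrame:
    """Full-rule share across the (d, r, block) configuration grid.

    One row per configuration (Cartesian product), each a complete,
    self-describing :class:`CityAssessment`. The viewshed (per (d, r))
    and Rule-300 stages are computed once and reused across block
    sizes, which leaves per-row results identical to independent runs.
    """
    if not (len(d_values) and len(r_values) and len(block_values)):
        raise ValueError("d_values, r_values and block_values must be non-empty")
    base_vs = viewshed_cfg or ViewshedConfig()
    base30 = rule30_cfg or Rule30Config()
    rule300_cfg = rule300_cfg or Rule300Config()

    trees = bundle.layer("tree_count")
    tcd = bundle.layer("tree_cover_density_pct")
    population = bundle.layer("population")
    heights = bundle.layer("building_height_m")
    landuse = bundle.layer("landuse_class")

    greens = extract_green_areas(landuse, rule300_cfg, bundle.boundary)
    buffer = buffer_green(greens, rule300_cfg)
    r300 = rule300_compliance(buffer, population)

    r30_by_block = {}
    for b in block_values:
        cfg30 = replace(base30, block_size_m=b)
        block_canopy = aggregate_neighborhood_canopy(tcd, cfg30, bundle.boundary)
        r30_by_block[b] = (cfg30, rule30_compliance(block_canopy, cfg30, tcd))

    rows = []
    for d in d_values:
        for r in r_values:
            vs_cfg = replace(base_vs, min_spacing_d_m=d, radius_r_m=r)
            points = sample_viewpoints(bundle.boundary, vs_cfg)
            viewshed = compute_visual_exposure(heights, points, vs_cfg)
            r3 = rule3_compliance(viewshed, trees, vs_cfg)
            for b in block_values:
                cfg30, r30 = r30_by_block[b]
                compliance = combine_rules(r3, r30, r300)
                fingerprint = {
                    "city_id": bundle.city_id,
                    "d_m": d,
                    "r_m": r,
                    "block_m": b,
                    "canopy_threshold_pct": cfg30.canopy_threshold_pct,
                    "buffer_m": rule300_cfg.buffer_m,
                    "min_area_m2": rule300_cfg.min_area_m2,
                    "seed": vs_cfg.seed,
                }
                a = _summarize(compliance, population, fingerprint)
                rows.append(
                    {
                        "d_m": d,
                        "r_m": r,
                        "block_m": b,
                        "pop_r3": a.pop_r3,
                        "pop_r30": a.pop_r30,
                        "pop_r300": a.pop_r300,
                        "share0": a.share_by_score[0],
                        "share1": a.share_by_score[1],
                        "share2": a.share_by_score[2],
                        "share3": a.share_by_score[3],
                        "full_rule_share": a.full_rule_share,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_cities(assessments: list[CityAssessment], pop_weights) -> dict:
    """Population-weighted pooling of score shares across cities."""
    if not assessments:
        raise ValueError("no assessments to aggregate")
    w = np.asarray(pop_weights, dtype=float)
    if len(w) != len(assessments) or np.any(w <= 0):
        raise ValueError("pop_weights must be positive, one per city")
    w = w / w.sum()
    shares = np.array([a.share_by_score for a in assessments])
    pooled = tuple(float(x) for x in (w[:, None] * shares).sum(axis=0))
    return {
        "share_by_score": pooled,
        "full_rule_share": pooled[3],
        "pop_r3": float(np.dot(w, [a.pop_r3 for a in assessments])),
        "pop_r30": float(np.dot(w, [a.pop_r30 for a in assessments])),
        "pop_r300": float(np.dot(w, [a.pop_r300 for a in assessments])),
        "n_cities": len(assessments),
    }
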