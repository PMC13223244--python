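"""Model/Results surface for the 3-30-300 assessment.

`ThreeThirtyThree` wraps a :class:`~urban330.grid.CityBundle` plus the
three stage configurations; ``fit()`` runs the full pipeline and
returns a :class:`ThreeThirtyThreeResults` carrying the per-rule
population shares, the score-share breakdown, the per-cell grids and
diagnostics, with ``summary()`` for a readable table and
``sensitivity()`` for the (d, r, block) sweep.

Example
-------
>>> from urban330 import SyntheticCitySpec, generate_city, ThreeThirtyThree
>>> bundle = generate_city(SyntheticCitySpec(seed=7))
>>> res = ThreeThirtyThree(bundle).fit()
>>> 0.0 <= res.full_rule_share <= min(res.pop_r3, res.pop_r30, res.pop_r300)
True
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assessment import run_assessment, sensitivity_sweep
from .grid import CityBundle, read_city_bundle
from .rule3 import ViewshedConfig
from .rule30 import Rule30Config
from .rule300 import Rule300Config

__all__ = ["ThreeThirtyThree", "ThreeThirtyThreeResults"]


class ThreeThirtyThree:
    """3-30-300 assessment model for one city bundle."""

    def __init__(
        self,
        bundle: CityBundle,
        viewshed_config: ViewshedConfig | None = None,
        rule30_config: Rule30Config | None = None,
        rule300_config: Rule300Config | None = None,
    ) -> None:
        self.bundle = bundle
        self.viewshed_config = viewshed_config or ViewshedConfig()
        self.rule30_config = rule30_config or Rule30Config()
        self.rule300_config = rule300_config or Rule300Config()

    @classmethod
    def from_directory(cls, directory: str | Path, **configs) -> "ThreeThirtyThree":
        """Build the model from a city directory written by the CLI."""
        return cls(read_city_bundle(directory), **configs)

    def fit(self) -> "ThreeThirtyThreeResults":
        artifacts = run_assessment(
            self.bundle, self.viewshed_config, self.rule30_config, self.rule300_config
        )
        return ThreeThirtyThreeResults(self, artifacts)


class ThreeThirtyThreeResults:
    """Fitted 3-30-300 assessment: shares, grids, and diagnostics."""

    def __init__(self, model: ThreeThirtyThree, artifacts) -> None:
        self.model = model
        self.artifacts = artifacts
        self.assessment = artifacts.assessment

    # -- headline estimates -------------------------------------------------
    @property
    def pop_r3(self) -> float:
        return self.assessment.pop_r3

    @property
    def pop_r30(self) -> float:
        return self.assessment.pop_r30

    @property
    def pop_r300(self) -> float:
        return self.assessment.pop_r300

    @property
    def share_by_score(self) -> tuple[float, float, float, float]:
        return self.assessment.share_by_score

    @property
    def full_rule_share(self) -> float:
        return self.assessment.full_rule_share

    # -- grids and diagnostics ----------------------------------------------
    @property
    def score_layer(self):
        return self.artifacts.compliance.score

    @property
    def n_viewpoints(self) -> int:
        return self.artifacts.viewpoints.count

    @property
    def n_green_spaces(self) -> int:
        return len(self.artifacts.green_spaces)

    def sensitivity(
        self,
        d_values=(100.0, 250.0, 500.0),
        r_values=(100.0, 250.0),
        block_values=(1000.0, 500.0, 250.0, 100.0),
    ) -> pd.DataFrame:
        """Sweep the viewpoint spacing, radius and neighborhood size."""
        return sensitivity_sweep(
            self.model.bundle,
            d_values,
            r_values,
            block_values,
            viewshed_cfg=self.model.viewshed_config,
            rule30_cfg=self.model.rule30_config,
            rule300_cfg=self.model.rule300_config,
        )

    def summary(self) -> str:
        a = self.assessment
        cfg = a.config
        lines = [
            "          3-30-300 urban greening assessment",
            "=" * 60,
            f"City:            {cfg.get('city_id', '?')}",
            f"Viewpoints:      {self.n_viewpoints}  (d = {cfg.get('d_m')} m, r = {cfg.get('r_m')} m)",
            f"Green spaces:    {self.n_green_spaces}  (>= {cfg.get('min_area_m2', 0) / 1e4:g} ha)",
            f"Neighborhood:    {cfg.get('block_m')} m blocks, threshold {cfg.get('canopy_threshold_pct')}%",
            "-" * 60,
            f"POP_R3   (3 trees visible)        {100 * a.pop_r3:6.1f} %",
            f"POP_R30  (30% neighborhood cover) {100 * a.pop_r30:6.1f} %",
            f"POP_R300 (park within 300 m)      {100 * a.pop_r300:6.1f} %",
            "-" * 60,
            "Population share by number of rules met:",
        ]
        for k in range(4):
            lines.append(f"    {k} rules: {100 * a.share_by_score[k]:6.1f} %")
        lines.append("-" * 60)
        lines.append(f"Full 3-30-300 compliance:         {100 * a.full_rule_share:6.1f} %")
        return "\n".join(lines)

    def plot_score(self, ax=None):
        """Map of the 0-3 per-cell score (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        layer = self.score_layer
        vals = np.ma.masked_array(layer.values, layer.nodata_mask)
        xmin, ymin, xmax, ymax = layer.bounds
        im = ax.imshow(
            vals, extent=(xmin, xmax, ymin, ymax), vmin=0, vmax=3, cmap="RdYlGn"
        )
        ax.set_title("rules satisfied per 100 m cell")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        plt.colorbar(im, ax=ax, ticks=[0, 1, 2, 3], label="score")
        return ax

    def to_dict(self) -> dict:
        a = self.assessment
        return {
            "pop_r3": a.pop_r3,
            "pop_r30": a.pop_r30,
            "pop_r300": a.pop_r300,
            "share_by_score": list(a.share_by_score),
            "full_rule_share": a.full_rule_share,
            "n_viewpoints": self.n_viewpoints,
            "n_green_spaces": self.n_green_spaces,
            "config": a.config,
        }
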