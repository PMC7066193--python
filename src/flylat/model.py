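"""Statsmodels-style front end: a model built from tracking data whose
``fit()`` returns a results object carrying estimates, uncertainties and a
summary table.

Example
-------
>>> from flylat.model import LateralizationModel
>>> from flylat.synthetic_flies import SimConfig, TABLE1_DESIGN
>>> from flylat.track_data import ArenaConfig
>>> cfg = SimConfig(seed=7, arena=ArenaConfig(duration=120.0))
>>> model = LateralizationModel.from_simulation(cfg, design={"RAL-69": {"F": 4, "FF": 4}})
>>> res = model.fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline as pl
from .pipeline import PipelineConfig
from .synthetic_flies import SimConfig, simulate_experiment
from .track_data import FlyMeta, Track, read_metadata, read_tracks


class LateralizationModel:
    """Lateralization analysis of a tracked-fly experiment.

    Parameters
    ----------
    tracks
        Mapping fly_id -> :class:`~flylat.track_data.Track`.
    meta
        Mapping fly_id -> :class:`~flylat.track_data.FlyMeta`.
    config
        Pipeline knobs; defaults mirror the study conditions.
    """

    def __init__(
        self,
        tracks: dict[str, Track],
        meta: dict[str, FlyMeta],
        config: PipelineConfig | None = None,
    ) -> None:
        self.tracks = tracks
        self.meta = meta
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(
        cls,
        tracks_path: str | Path,
        meta_path: str | Path,
        config: PipelineConfig | None = None,
        convention: str = "y-up",
    ) -> "LateralizationModel":
        """Build the model from canonical tracks.csv / meta.csv files."""
        return cls(
            read_tracks(tracks_path, convention=convention),
            read_metadata(meta_path),
            config,
        )

    @classmethod
    def from_simulation(
        cls,
        sim_config: SimConfig,
        design: dict[str, dict[str, int]],
        config: PipelineConfig | None = None,
        strain_overrides: dict[str, dict] | None = None,
    ) -> "LateralizationModel":
        """Build the model from a synthetic experiment with known ground truth.

        The simulated ground-truth table is attached to the model as
        ``model.ground_truth``.
        """
        exp = simulate_experiment(design, sim_config, strain_overrides=strain_overrides)
        if config is None:
            config = PipelineConfig(arena=sim_config.arena, seed=sim_config.seed)
        m = cls(exp.tracks, exp.meta, config)
        m.ground_truth = exp.ground_truth
        return m

    def fit(self) -> "LateralizationResults":
        """Compute per-fly indices, dyad geometry and the statistical report."""
        dmap = pl.compute_dyad_map(self.tracks, self.meta, self.config)
        metrics = pl.run_metrics(self.tracks, self.meta, self.config, dyad_map=dmap)
        report = pl.run_stats(metrics, self.config, dyad_map=dmap, meta=self.meta)
        return LateralizationResults(self, metrics, dmap, report)


class LateralizationResults:
    """Fitted lateralization analysis.

    Attributes
    ----------
    metrics : pandas.DataFrame
        One row per fly: indices, velocity, dyad summaries, design labels.
    report : dict
        Full statistical report (t-tests, ANOVA + omega-squared, bootstrap
        Position densities, null overlays, exclusion counts).
    """

    def __init__(self, model, metrics: pd.DataFrame, dyad_map, report: dict):
        self.model = model
        self.metrics = metrics
        self.dyad_map = dyad_map
        self.report = report

    # -- accessors ---------------------------------------------------------
    @property
    def ttests(self) -> dict:
        return self.report["ttests"]

    @property
    def anova(self) -> dict:
        return self.report["anova"]

    def dyads(self) -> pd.DataFrame:
        return pl.dyad_table(self.dyad_map)

    def meaningful_effects(self, response: str = "absC") -> list[str]:
        """ANOVA terms passing both the significance and omega^2 screens."""
        return self.report["anova"].get(response, {}).get("meaningful_terms", [])

    # -- output ------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of the pooled tests and screened ANOVA."""
        lines = []
        n = self.report["n_flies"]
        lines.append("Lateralization analysis summary")
        lines.append("=" * 62)
        lines.append(f"Flies analyzed: {n}")
        lines.append("")
        lines.append("One-sample t-tests vs 0 (population asymmetry if signed,")
        lines.append("individual asymmetry if absolute):")
        hdr = f"{'index':>6} {'n':>6} {'mean':>9} {'sd':>8} {'t':>9} {'p':>10} {'d':>7}"
        lines.append(hdr)
        for name in ("C", "absC", "W", "absW"):
            tt = self.ttests.get(name, {})
            if not tt or "error" in tt:
                lines.append(f"{name:>6} {'-':>6} (undefined: {tt.get('error', 'n/a')})")
                continue
            lines.append(
                f"{name:>6} {tt['n']:>6d} {tt['mean']:>9.4f} {tt['sd']:>8.4f} "
                f"{tt['t']:>9.2f} {tt['p']:>10.3g} {tt['cohen_d']:>7.2f}"
            )
        thr = self.model.config.omega_sq_threshold
        lines.append("")
        lines.append(f"ANOVA terms with p < 0.05 and omega^2 >= {thr} by response:")
        for name in ("C", "absC", "W", "absW"):
            block = self.anova.get(name, {})
            terms = block.get("meaningful_terms")
            lines.append(f"  {name}: {', '.join(terms) if terms else '(none)'}")
        sb = self.report.get("position", {}).get("side_bias_ttest")
        if sb and "error" not in sb:
            lines.append("")
            lines.append(
                f"Position side bias (dyads): mean {sb['mean']:.4f}, "
                f"t({sb['df']}) = {sb['t']:.2f}, p = {sb['p']:.3g}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path, figures: bool = False) -> list[Path]:
        """Write stats_report.json, metrics.csv, dyads.csv, TSVs, figures."""
        return pl.render_report(
            self.report, outdir, metrics=self.metrics, dyads=self.dyads(), figures=figures
        )

    # -- plots -------------------------------------------------------------
    def plot_index_distributions(self):
        """Histograms of C/|C|/W/|W| with their no-asymmetry null overlays.

        Returns the matplotlib figure.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hists = self.report.get("histograms", {})
        overlays = self.report.get("null_overlays", {})
        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        for ax, name in zip(axes.ravel(), ("absC", "C", "absW", "W")):
            h = hists.get(name)
            if not h:
                ax.set_visible(False)
                continue
            edges = np.asarray(h["bin_edges"], dtype=float)
            ax.bar(edges[:-1], h["density"], width=np.diff(edges), align="edge",
                   color="#7fa8d0", edgecolor="white")
            o = overlays.get(name)
            if o:
                ax.plot(o["grid"], o["density"], "k--", lw=1.5)
            ax.set_xlabel(name)
            ax.set_ylabel("density")
        fig.tight_layout()
        return fig

    def plot_polar_heatmap(self, context: str, ax=None):
        """Polar heatmap of partner (Position, Distance) occupancy for one context."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from . import dyad_metrics as dyad

        angles, dists = [], []
        for fid, ds in self.dyad_map.items():
            if self.model.meta[fid].context == context:
                angles.append(ds.position)
                dists.append(ds.distance)
        if not angles:
            raise ValueError(f"no dyads in context {context!r}")
        hist = dyad.polar_joint_density(
            np.concatenate(angles),
            np.concatenate(dists),
            angle_bins=self.model.config.angle_bin_deg,
            radius_bins=self.model.config.radius_bin_mm,
            max_radius=self.model.config.arena.diameter,
        )
        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="polar")
        th = np.radians(hist.angle_bin_edges)
        rr = hist.radius_bin_edges
        ax.pcolormesh(th, rr, hist.density.T, shading="auto")
        ax.set_title(f"Position x Distance, {context}")
        return ax
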