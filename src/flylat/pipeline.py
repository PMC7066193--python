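"""Pipeline stages: tracks -> per-fly metrics -> statistics -> report.

Each stage reads and writes only documented CSV/JSON artifacts so the stages
are independently testable and scriptable:

* ``run_metrics``   — per-fly index table (metrics.csv) from tracks + metadata.
* ``dyad_table``    — per-frame dyadic geometry (dyads.csv).
* ``run_stats``     — t-tests, factorial ANOVA with omega-squared screening,
  Position bootstrap densities and null overlays (stats_report.json).
* ``render_report`` — JSON/TSV artifacts and optional figures.

Exclusions (stationary flies, undefined indices, missing tracks) are never
silently dropped: they are counted in the report's ``exclusions`` block and
logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry_stats as astats
from . import dyad_metrics as dyad
from . import individual_metrics as indiv
from .errors import AliasingError, DegenerateSampleError, InsufficientDataError
from .track_data import ArenaConfig, FlyMeta, Track, read_metadata, read_tracks

logger = logging.getLogger(__name__)

RESPONSES = {
    "C": "C_signed",
    "absC": "C_abs",
    "W": "W_signed",
    "absW": "W_abs",
}

DEFAULT_ANOVA_TERMS = [
    "Context",
    "Sex",
    "Strain",
    "Context:Sex",
    "Context:Strain",
    "Sex:Strain",
    "Context:Sex:Strain",
]


@dataclass
class PipelineConfig:
    """Knobs of the analysis pipeline (units in field comments)."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    min_step: float = indiv.DEFAULT_MIN_STEP  # mm, turn-step threshold
    min_open: float = 0.0  # deg, wing-opening threshold
    heading_source: str = "body"  # {body, displacement}
    n_boot: int = 100  # bootstrap replicates for densities
    seed: int = 0  # root seed for all stochastic stages
    ss_type: str = "II"  # ANOVA sum-of-squares type {I, II}
    omega_sq_threshold: float = 0.06  # medium effect-size screen
    window_minutes: float = 10.0  # stability-check window
    kde_max_frames_per_fly: int = 100  # Position frames per fly fed to the KDE
    angle_bin_deg: float = 5.0  # polar heatmap angular bin
    radius_bin_mm: float = 1.0  # polar heatmap radial bin

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _context_label(context: str) -> str:
    return "SINGLE" if context in ("F", "M") else context


def compute_dyad_map(
    tracks: dict[str, Track],
    meta: dict[str, FlyMeta],
    config: PipelineConfig,
) -> dict[str, dyad.DyadSeries]:
    """Per-frame dyadic geometry with every dyad member as focal fly."""
    out: dict[str, dyad.DyadSeries] = {}
    for fid, m in meta.items():
        if not m.is_dyad:
            continue
        if fid not in tracks or m.partner_id not in tracks:
            continue
        out[fid] = dyad.dyad_series(
            tracks[fid], tracks[m.partner_id], heading_source=config.heading_source
        )
    return out


def dyad_table(dyad_map: dict[str, dyad.DyadSeries]) -> pd.DataFrame:
    """Long-format dyads table (one row per focal fly per common frame)."""
    parts = []
    for fid, ds in dyad_map.items():
        parts.append(
            pd.DataFrame(
                {
                    "focal_id": fid,
                    "partner_id": ds.partner_id,
                    "frame": ds.frame,
                    "distance_mm": ds.distance,
                    "position_deg": ds.position,
                    "orientation_deg": ds.orientation,
                    "valid": ds.valid,
                }
            )
        )
    cols = [
        "focal_id", "partner_id", "frame",
        "distance_mm", "position_deg", "orientation_deg", "valid",
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=cols)


def run_metrics(
    tracks: dict[str, Track],
    meta: dict[str, FlyMeta],
    config: PipelineConfig | None = None,
    dyad_map: dict[str, dyad.DyadSeries] | None = None,
) -> pd.DataFrame:
    """One row per fly: C, |C|, W, |W|, mean velocity, and dyad summaries.

    Flies listed in the metadata but lacking track rows are skipped (and
    counted); undefined indices are NaN, never 0.
    """
    config = config or PipelineConfig()
    if dyad_map is None:
        dyad_map = compute_dyad_map(tracks, meta, config)
    rows = []
    skipped = []
    for fid, m in meta.items():
        tr = tracks.get(fid)
        if tr is None or len(tr) == 0:
            skipped.append(fid)
            continue
        turns = indiv.compute_turn_series(tr, config.min_step)
        c = indiv.circling_index(turns)
        w = indiv.wing_index(indiv.wing_signed_sums(tr, config.min_open), fid)
        vel = indiv.velocity_series(tr)
        row = {
            "fly_id": fid,
            "arena_id": m.arena_id,
            "strain": m.strain,
            "sex": m.sex,
            "context": m.context,
            "Context": _context_label(m.context),
            "Sex": m.sex,
            "Strain": m.strain,
            "Dyad": "dyad" if m.is_dyad else "single",
            "partner_id": m.partner_id,
            "n_turns": c.n_events,
            "C_signed": c.signed,
            "C_abs": c.absolute,
            "n_wing_frames": w.n_events,
            "W_signed": w.signed,
            "W_abs": w.absolute,
            "mean_velocity_mm_s": vel.mean,
            "pos_side_bias": np.nan,
            "median_distance_mm": np.nan,
            "median_orientation_deg": np.nan,
        }
        ds = dyad_map.get(fid)
        if ds is not None and len(ds.frame):
            row["pos_side_bias"] = dyad.position_side_bias(ds.position)
            row["median_distance_mm"] = float(np.median(ds.distance))
            ok = np.isfinite(ds.orientation)
            if np.any(ok):
                row["median_orientation_deg"] = float(np.median(ds.orientation[ok]))
        rows.append(row)
    if skipped:
        logger.warning("run_metrics: %d flies in metadata had no track rows: %s",
                       len(skipped), ", ".join(skipped[:10]))
    df = pd.DataFrame(rows)
    df.attrs["skipped_flies"] = skipped
    return df


def _nan_to_none(obj):
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _nan_to_none(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _anova_block(metrics: pd.DataFrame, response_col: str, config: PipelineConfig) -> dict:
    """Largest estimable subset of the full-factorial ANOVA for one response."""
    block: dict = {"terms": None, "dropped_terms": [], "error": None}
    terms = []
    dropped = []
    usable = metrics.dropna(subset=[response_col])
    for t in DEFAULT_ANOVA_TERMS:
        factors = [f.strip() for f in t.split(":")]
        try:
            for f in factors:
                if usable[f].nunique() < 2:
                    raise InsufficientDataError(f"factor {f!r} has < 2 levels")
            astats.check_estimable(usable, factors)
            terms.append(t)
        except (AliasingError, InsufficientDataError) as exc:
            dropped.append({"term": t, "reason": str(exc)})
    if not terms:
        block["error"] = "no estimable terms"
        block["dropped_terms"] = dropped
        return block
    try:
        tab = astats.factorial_anova(metrics, response_col, terms, ss_type=config.ss_type)
        block["terms"] = tab.to_records()
        block["ss_type"] = tab.ss_type
        block["ss_total"] = tab.ss_total
        block["n_obs"] = tab.n_obs
        block["meaningful_terms"] = tab.meaningful_terms(config.omega_sq_threshold)
    except (AliasingError, InsufficientDataError, DegenerateSampleError) as exc:
        block["error"] = str(exc)
    block["dropped_terms"] = dropped
    return block


def run_stats(
    metrics: pd.DataFrame,
    config: PipelineConfig | None = None,
    dyad_map: dict[str, dyad.DyadSeries] | None = None,
    meta: dict[str, FlyMeta] | None = None,
) -> dict:
    """Statistical report for a per-fly metrics table.

    For each of C, |C|, W, |W|: a pooled one-sample t-test against 0, the
    factorial Context x Sex x Strain ANOVA (inestimable terms dropped, not
    fatal) with omega-squared screening, and the dyad-vs-single one-factor
    contrast. When per-frame dyad geometry is supplied, adds bootstrap
    kernel-density bands of Position per context (fly-level resampling) and
    a pooled side-bias t-test; always adds observed-vs-null overlay data for
    the index histograms.
    """
    config = config or PipelineConfig()
    report: dict = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "n_flies": int(len(metrics)),
        "ttests": {},
        "anova": {},
        "dyad_contrast": {},
        "null_overlays": {},
        "histograms": {},
        "position": {},
        "exclusions": {},
    }
    report["exclusions"]["skipped_flies"] = list(metrics.attrs.get("skipped_flies", []))
    for name, col in RESPONSES.items():
        vals = metrics[col] if col in metrics else pd.Series(dtype=float)
        report["exclusions"][f"undefined_{name}"] = int(vals.isna().sum())
        try:
            report["ttests"][name] = astats.one_sample_t(vals.to_numpy(), 0.0).to_dict()
        except (InsufficientDataError, DegenerateSampleError) as exc:
            report["ttests"][name] = {"error": str(exc)}
        report["anova"][name] = _anova_block(metrics, col, config)
        try:
            if metrics["Dyad"].nunique() == 2:
                tab = astats.factorial_anova(metrics, col, ["Dyad"], ss_type=config.ss_type)
                report["dyad_contrast"][name] = tab.to_records()
            else:
                report["dyad_contrast"][name] = {"error": "only one Dyad level present"}
        except (AliasingError, InsufficientDataError, DegenerateSampleError, KeyError) as exc:
            report["dyad_contrast"][name] = {"error": str(exc)}
    # observed histograms + no-asymmetry overlays (signed: normal; absolute:
    # half-normal folded from the same sigma-hat)
    for signed_name, abs_name, signed_col in (
        ("C", "absC", "C_signed"),
        ("W", "absW", "W_signed"),
    ):
        vals = metrics.get(signed_col, pd.Series(dtype=float)).dropna().to_numpy()
        if vals.size >= 2 and np.std(vals, ddof=1) > 0:
            edges_s = np.linspace(-1.0, 1.0, 41)
            edges_a = np.linspace(0.0, 1.0, 21)
            hist_s, _ = np.histogram(vals, bins=edges_s, density=True)
            hist_a, _ = np.histogram(np.abs(vals), bins=edges_a, density=True)
            g_s, d_s = astats.null_overlay(vals, "signed", grid=np.linspace(-1, 1, 201))
            g_a, d_a = astats.null_overlay(vals, "absolute", grid=np.linspace(0, 1, 101))
            report["histograms"][signed_name] = {"bin_edges": edges_s, "density": hist_s}
            report["histograms"][abs_name] = {"bin_edges": edges_a, "density": hist_a}
            report["null_overlays"][signed_name] = {"grid": g_s, "density": d_s}
            report["null_overlays"][abs_name] = {"grid": g_a, "density": d_a}
    if dyad_map:
        report["position"] = _position_block(metrics, dyad_map, config)
    return _nan_to_none(report)


def _downsample(a: np.ndarray, k: int) -> np.ndarray:
    a = a[np.isfinite(a)]
    if a.size <= k:
        return a
    idx = np.linspace(0, a.size - 1, k).round().astype(int)
    return a[idx]


def _position_block(metrics: pd.DataFrame, dyad_map, config: PipelineConfig) -> dict:
    """Bootstrap Position densities per context (and per context x strain)."""
    by_fly = {}
    for fid, ds in dyad_map.items():
        by_fly[fid] = _downsample(ds.position, config.kde_max_frames_per_fly)
    sub = metrics[metrics["Dyad"] == "dyad"]
    block: dict = {"by_context": {}, "by_context_strain": {}, "side_bias_ttest": None}
    grid = np.linspace(-180.0, 180.0, 181)
    root = np.random.SeedSequence(config.seed)
    kde_seeds = iter(root.generate_state(1 + 4 * 30).tolist())
    for ctx, g in sub.groupby("context"):
        flies = [by_fly[f] for f in g["fly_id"] if f in by_fly and by_fly[f].size]
        if len(flies) < 2:
            continue
        kde = astats.bootstrap_kde(
            flies, n_boot=config.n_boot, grid=grid,
            seed=int(next(kde_seeds)) % (2**31), circular=True,
        )
        block["by_context"][ctx] = {
            "grid": kde.grid, "mean_density": kde.mean_density,
            "se_density": kde.se_density, "n_flies": len(flies),
            "bandwidth": kde.bandwidth,
        }
        for strain, gs in g.groupby("strain"):
            flies_s = [by_fly[f] for f in gs["fly_id"] if f in by_fly and by_fly[f].size]
            if len(flies_s) < 2:
                continue
            kde_s = astats.bootstrap_kde(
                flies_s, n_boot=config.n_boot, grid=grid,
                seed=int(next(kde_seeds)) % (2**31), circular=True,
            )
            block["by_context_strain"][f"{ctx}|{strain}"] = {
                "grid": kde_s.grid, "mean_density": kde_s.mean_density,
                "se_density": kde_s.se_density, "n_flies": len(flies_s),
                "bandwidth": kde_s.bandwidth,
            }
    biases = sub["pos_side_bias"].dropna().to_numpy()
    try:
        block["side_bias_ttest"] = astats.one_sample_t(biases, 0.0).to_dict()
    except (InsufficientDataError, DegenerateSampleError) as exc:
        block["side_bias_ttest"] = {"error": str(exc)}
    return block


def render_report(
    report: dict,
    outdir: str | Path,
    metrics: pd.DataFrame | None = None,
    dyads: pd.DataFrame | None = None,
    figures: bool = False,
) -> list[Path]:
    """Write stats_report.json, TSV tables, optional CSVs and figures.

    Returns the list of files written; the set of files is deterministic for
    a given report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    jpath = outdir / "stats_report.json"
    jpath.write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
    written.append(jpath)
    ttest_rows = []
    for resp, tt in report.get("ttests", {}).items():
        if "error" not in tt:
            ttest_rows.append({"response": resp, **tt})
    tpath = outdir / "ttests.tsv"
    pd.DataFrame(ttest_rows).to_csv(tpath, sep="\t", index=False)
    written.append(tpath)
    anova_rows = []
    for resp, block in report.get("anova", {}).items():
        for rec in block.get("terms") or []:
            anova_rows.append({"response": resp, **rec})
    apath = outdir / "anova.tsv"
    pd.DataFrame(anova_rows).to_csv(apath, sep="\t", index=False)
    written.append(apath)
    if metrics is not None:
        mpath = outdir / "metrics.csv"
        metrics.to_csv(mpath, index=False)
        written.append(mpath)
    if dyads is not None:
        dpath = outdir / "dyads.csv"
        dyads.to_csv(dpath, index=False)
        written.append(dpath)
    if figures:
        written.extend(_render_figures(report, outdir))
    return written


def _render_figures(report: dict, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    hists = report.get("histograms", {})
    overlays = report.get("null_overlays", {})
    if hists:
        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        for ax, name in zip(axes.ravel(), ("absC", "C", "absW", "W")):
            h = hists.get(name)
            o = overlays.get(name)
            if not h:
                ax.set_visible(False)
                continue
            edges = np.asarray(h["bin_edges"], dtype=float)
            ax.bar(edges[:-1], h["density"], width=np.diff(edges), align="edge",
                   color="#7fa8d0", edgecolor="white")
            if o:
                ax.plot(o["grid"], o["density"], "k--", lw=1.5, label="no-asymmetry null")
                ax.legend(frameon=False, fontsize=8)
            ax.set_xlabel(name)
            ax.set_ylabel("density")
        fig.tight_layout()
        p = outdir / "index_distributions.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    pos = report.get("position", {}).get("by_context", {})
    if pos:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for ctx, blk in sorted(pos.items()):
            g = np.asarray(blk["grid"], dtype=float)
            m = np.asarray(blk["mean_density"], dtype=float)
            se = np.asarray(blk["se_density"], dtype=float)
            ax.plot(g, m, label=f"{ctx} (n={blk['n_flies']})")
            ax.fill_between(g, m - se, m + se, alpha=0.25)
        ax.set_xlabel("Position (deg)")
        ax.set_ylabel("density")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        p = outdir / "position_density.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def run_pipeline(
    tracks_path: str | Path,
    meta_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    convention: str = "y-up",
    figures: bool = False,
) -> dict:
    """Full pipeline from canonical CSVs to a rendered report directory."""
    config = config or PipelineConfig()
    tracks = read_tracks(tracks_path, convention=convention)
    meta = read_metadata(meta_path)
    dmap = compute_dyad_map(tracks, meta, config)
    metrics = run_metrics(tracks, meta, config, dyad_map=dmap)
    report = run_stats(metrics, config, dyad_map=dmap, meta=meta)
    render_report(report, outdir, metrics=metrics, dyads=dyad_table(dmap), figures=figures)
    return report


def reproduce_from_deposit(
    deposit_dir: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Re-run the full analysis on the study's deposited tracking tables.

    ``deposit_dir`` must contain canonical ``tracks.csv`` and ``meta.csv``
    (converted from the public archive of the original recordings). Raises
    FileNotFoundError when the deposit is not present locally.
    """
    deposit_dir = Path(deposit_dir)
    tracks = deposit_dir / "tracks.csv"
    meta = deposit_dir / "meta.csv"
    if not tracks.exists() or not meta.exists():
        raise FileNotFoundError(
            f"deposit not found under {deposit_dir}: expected tracks.csv and meta.csv "
            "(download the archived recordings and convert them to the canonical dialect)"
        )
    return run_pipeline(tracks, meta, outdir, config=config, convention="y-down")
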