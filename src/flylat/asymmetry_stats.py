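"""Statistical layer: one-sample t-tests with Cohen's d, factorial ANOVA
screened by the omega-squared effect size, fly-level bootstrap kernel-density
bands, and no-asymmetry null overlays.

Conventions
-----------
* All tests are two-sided at alpha = 0.05.
* Effect sizes: Cohen's d = (mean - mu0) / SD for one-sample tests;
  omega^2 = (SS_eff - df_eff * MS_err) / (SS_tot + MS_err), floored at 0,
  for ANOVA terms.
* The bootstrap resamples *flies* (trials), never frames — frames within a
  trial are strongly autocorrelated, so frame-level resampling would
  understate the standard error.
* The null overlays describe the index distribution expected with no
  asymmetry at either level: a normal centred at 0 for signed indices, and
  its folded (half-normal) counterpart for absolute indices, both using the
  standard deviation estimated from the observed signed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import AliasingError, DegenerateSampleError, InsufficientDataError

ALPHA = 0.05


@dataclass
class TTestResult:
    """One-sample t-test against mu0 with Cohen's d and a 95% CI for the mean."""

    n: int
    mean: float
    sd: float
    t: float
    p: float
    cohen_d: float
    ci95: tuple[float, float]
    mu0: float = 0.0

    @property
    def df(self) -> int:
        return self.n - 1

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "df": self.df,
            "mean": self.mean,
            "sd": self.sd,
            "t": self.t,
            "p": self.p,
            "cohen_d": self.cohen_d,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "mu0": self.mu0,
        }


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    NaNs are dropped. Raises :class:`InsufficientDataError` for n < 2 and
    :class:`DegenerateSampleError` for zero-variance samples.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"one_sample_t needs >= 2 values, got {n}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("one_sample_t: sample has zero variance")
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    tcrit = sps.t.ppf(1 - ALPHA / 2, n - 1)
    return TTestResult(
        n=n,
        mean=mean,
        sd=sd,
        t=float(t),
        p=float(p),
        cohen_d=float((mean - mu0) / sd),
        ci95=(mean - tcrit * se, mean + tcrit * se),
        mu0=mu0,
    )


def omega_squared(ss_eff: float, df_eff: float, ms_err: float, ss_tot: float) -> float:
    """Classical omega-squared effect size for one ANOVA term, floored at 0.

    omega^2 = (SS_eff - df_eff * MS_err) / (SS_tot + MS_err).
    """
    denom = ss_tot + ms_err
    if denom == 0:
        return np.nan
    return max((ss_eff - df_eff * ms_err) / denom, 0.0)


@dataclass
class AnovaTable:
    """Per-term ANOVA decomposition with omega-squared effect sizes.

    ``table`` has one row per model term plus a ``Residual`` row, with
    columns ``sum_sq, df, F, p, omega_sq``; ``ss_total`` is the corrected
    total sum of squares of the response.
    """

    response: str
    ss_type: str
    table: pd.DataFrame
    ss_total: float
    n_obs: int
    dropped_terms: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def meaningful_terms(self, threshold: float = 0.06) -> list[str]:
        """Terms that are both significant and at least medium-sized."""
        t = self.table.drop(index="Residual")
        sel = (t["p"] < ALPHA) & (t["omega_sq"] >= threshold)
        return list(t.index[sel])

    def to_records(self) -> list[dict]:
        out = []
        for name, row in self.table.iterrows():
            rec = {"term": name}
            rec.update({k: (None if not np.isfinite(v) else float(v)) for k, v in row.items()})
            out.append(rec)
        return out


def _term_factors(term: str) -> list[str]:
    return [f.strip() for f in term.split(":")]


def check_estimable(data: pd.DataFrame, factors: list[str]) -> None:
    """Raise :class:`AliasingError` if the factor cross has an empty cell.

    An interaction among ``factors`` is inestimable when some combination of
    levels (each present marginally) never occurs in the data.
    """
    if len(factors) < 2:
        return
    counts = data.groupby(factors).size()
    levels = [sorted(map(str, data[f].unique())) for f in factors]
    full = pd.MultiIndex.from_product(levels, names=factors)
    counts = counts.reindex(full, fill_value=0)
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        desc = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
        raise AliasingError(
            f"interaction {':'.join(factors)} inestimable: empty cell ({desc})"
        )


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    ss_type: str = "II",
) -> AnovaTable:
    """Factorial ANOVA with omega-squared per term.

    Parameters
    ----------
    data
        One row per fly: the response column plus categorical factor columns.
    terms
        Model terms, e.g. ``["Context", "Strain", "Context:Strain"]``;
        interactions use ``:``.
    ss_type
        ``"I"`` (sequential) or ``"II"``; for balanced designs the two agree.

    Raises :class:`AliasingError` when a requested interaction has an empty
    design cell, and :class:`InsufficientDataError` when a factor has fewer
    than two observed levels.
    """
    if ss_type not in ("I", "II"):
        raise ValueError(f"ss_type must be 'I' or 'II', got {ss_type!r}")
    cols = sorted({f for t in terms for f in _term_factors(t)})
    df = data[[response] + cols].dropna(subset=[response]).copy()
    if len(df) < len(cols) + 2:
        raise InsufficientDataError(f"too few rows ({len(df)}) for ANOVA")
    for c in cols:
        df[c] = df[c].astype(str)
        if df[c].nunique() < 2:
            raise InsufficientDataError(f"factor {c!r} has < 2 levels present")
    for t in terms:
        check_estimable(df, _term_factors(t))
    rhs = " + ".join(_patsy_term(t) for t in terms)
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=df).fit()
    aov = anova_lm(model, typ=1 if ss_type == "I" else 2)
    # normalise statsmodels row labels back to plain term names
    aov.index = [_plain_term(ix) for ix in aov.index]
    resid_ss = float(aov.loc["Residual", "sum_sq"])
    resid_df = float(aov.loc["Residual", "df"])
    ms_err = resid_ss / resid_df
    y = df[response].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows = {}
    for name in aov.index:
        row = aov.loc[name]
        rec = {
            "sum_sq": float(row["sum_sq"]),
            "df": float(row["df"]),
            "F": float(row["F"]) if np.isfinite(row.get("F", np.nan)) else np.nan,
            "p": float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else np.nan,
            "omega_sq": (
                omega_squared(float(row["sum_sq"]), float(row["df"]), ms_err, ss_total)
                if name != "Residual"
                else np.nan
            ),
        }
        rows[name] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    return AnovaTable(
        response=response,
        ss_type=ss_type,
        table=table,
        ss_total=ss_total,
        n_obs=len(df),
    )


def _patsy_term(term: str) -> str:
    return ":".join(f"C(Q('{f}'))" for f in _term_factors(term))


def _plain_term(label: str) -> str:
    if label == "Residual":
        return label
    return ":".join(
        part.replace("C(Q('", "").replace("'))", "") for part in label.split(":")
    )


@dataclass
class BootstrapKDE:
    """Pointwise mean and standard error of a kernel density across
    fly-level bootstrap resamples."""

    grid: np.ndarray
    mean_density: np.ndarray
    se_density: np.ndarray
    n_boot: int
    seed: int | None
    bandwidth: float


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 and sd > 0 else max(sd, iqr / 1.34)
    if scale <= 0:
        raise DegenerateSampleError("KDE bandwidth undefined: zero spread")
    return 0.9 * scale * n ** (-1 / 5)


def _gaussian_kde_fixed(
    values: np.ndarray, weights: np.ndarray, grid: np.ndarray, h: float
) -> np.ndarray:
    """Weighted Gaussian KDE with fixed bandwidth h, exact or binned.

    Uses exact kernel sums for small samples; for large samples on a uniform
    grid, bins the weights at the grid resolution and convolves with the
    kernel (error negligible when h spans several grid steps).
    """
    g = np.asarray(grid, dtype=float)
    if values.size * g.size <= 2_000_000 or not _uniform(g):
        z = (g[:, None] - values[None, :]) / h
        k = np.exp(-0.5 * z**2) / (h * np.sqrt(2 * np.pi))
        return k @ weights
    step = g[1] - g[0]
    edges = np.concatenate([g - step / 2, [g[-1] + step / 2]])
    inside = (values >= edges[0]) & (values < edges[-1])
    binned, _ = np.histogram(values[inside], bins=edges, weights=weights[inside])
    half = int(np.ceil(6 * h / step))
    offs = np.arange(-half, half + 1) * step
    kern = np.exp(-0.5 * (offs / h) ** 2) / (h * np.sqrt(2 * np.pi))
    out = np.convolve(binned, kern, mode="full")[half : half + g.size]
    # kernel mass from points just outside the grid window
    outside = ~inside
    if np.any(outside):
        z = (g[:, None] - values[None, outside]) / h
        out = out + (np.exp(-0.5 * z**2) / (h * np.sqrt(2 * np.pi))) @ weights[outside]
    return out


def _uniform(g: np.ndarray) -> bool:
    d = np.diff(g)
    return d.size > 0 and np.allclose(d, d[0])


def bootstrap_kde(
    values_by_fly,
    n_boot: int = 100,
    grid: np.ndarray | None = None,
    seed: int | None = None,
    circular: bool = False,
) -> BootstrapKDE:
    """Bootstrap standard error of a kernel density estimate, resampling flies.

    Parameters
    ----------
    values_by_fly
        Sequence with one entry per fly: a scalar (per-fly index) or an
        array of per-frame values (e.g. Position angles). Each fly carries
        equal total weight regardless of its frame count.
    n_boot
        Number of with-replacement fly resamples (100 in the study design).
    grid
        Evaluation points; defaults to 361 points on [-180, 180] when
        ``circular`` else 256 points spanning the data with 3-bandwidth
        padding.
    circular
        Treat values as angles in degrees: data are replicated at +/-360 so
        the density is continuous across the wrap and normalizes on the
        circle.

    The Gaussian bandwidth is fixed from the full pooled sample (Silverman's
    rule) and reused for every replicate, so the band reflects sampling
    variation only, not bandwidth re-estimation.
    """
    flies = [np.atleast_1d(np.asarray(v, dtype=float)).ravel() for v in values_by_fly]
    flies = [f[np.isfinite(f)] for f in flies]
    flies = [f for f in flies if f.size > 0]
    n_flies = len(flies)
    if n_flies < 2:
        raise InsufficientDataError(
            "bootstrap_kde needs >= 2 flies for a standard error"
        )
    pooled = np.concatenate(flies)
    h = _silverman_bandwidth(pooled)
    if grid is None:
        if circular:
            grid = np.linspace(-180.0, 180.0, 361)
        else:
            lo, hi = pooled.min() - 3 * h, pooled.max() + 3 * h
            grid = np.linspace(lo, hi, 256)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    dens = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, n_flies, size=n_flies)
        vals = []
        wts = []
        for i in idx:
            f = flies[i]
            vals.append(f)
            wts.append(np.full(f.size, 1.0 / (n_flies * f.size)))
        v = np.concatenate(vals)
        w = np.concatenate(wts)
        if circular:
            v = np.concatenate([v - 360.0, v, v + 360.0])
            w = np.tile(w, 3)
        dens[b] = _gaussian_kde_fixed(v, w, grid, h)
    return BootstrapKDE(
        grid=grid,
        mean_density=dens.mean(axis=0),
        se_density=dens.std(axis=0, ddof=1),
        n_boot=n_boot,
        seed=seed,
        bandwidth=h,
    )


def null_overlay(
    index_values,
    kind: str = "signed",
    grid: np.ndarray | None = None,
    match_absolute_variance: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Density expected under no asymmetry, scaled to the observed variance.

    ``kind="signed"`` returns a normal N(0, sigma^2) density — the
    no-population-asymmetry reference for a signed index. ``kind="absolute"``
    returns the half-normal density of |N(0, sigma^2)| — the
    no-individual-asymmetry reference for the absolute index. By default
    sigma is the sample SD of the signed values passed in; with
    ``match_absolute_variance`` the parent sigma is instead derived from the
    spread of the absolute values (sd(|x|) / sqrt(1 - 2/pi)).

    Returns ``(grid, density)``.
    """
    x = np.asarray(index_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError("null_overlay needs >= 2 values")
    if match_absolute_variance:
        sd_abs = np.std(np.abs(x), ddof=1)
        sigma = sd_abs / np.sqrt(1 - 2 / np.pi)
    else:
        sigma = np.std(x, ddof=1)
    if sigma == 0:
        raise DegenerateSampleError("null_overlay: zero variance")
    if kind == "signed":
        if grid is None:
            grid = np.linspace(-4 * sigma, 4 * sigma, 401)
        dens = sps.norm.pdf(grid, loc=0.0, scale=sigma)
    elif kind == "absolute":
        if grid is None:
            grid = np.linspace(0.0, 4 * sigma, 401)
        dens = sps.halfnorm.pdf(grid, loc=0.0, scale=sigma)
    else:
        raise ValueError(f"kind must be 'signed' or 'absolute', got {kind!r}")
    return np.asarray(grid, dtype=float), dens
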