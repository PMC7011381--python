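"""Sloan neutral community model: fit, confidence band, OTU classification.

The model treats the local relative abundance of a taxon whose source-pool
proportion is ``p`` as Beta(N·m·p, N·m·(1−p)) distributed, where ``N`` is
the community size (here: reads per sample) and ``m`` the migration rate —
the probability that a death in the local community is replaced by an
immigrant rather than a local birth.  The probability of detecting the
taxon at a depth-``N`` sample with detection limit ``d`` reads is then

    F(p; m, N, d) = 1 − I_{d/N}(N·m·p, N·m·(1−p))

with ``I`` the regularized incomplete beta function.  ``m`` is estimated by
nonlinear least squares of observed occurrence frequencies on F, and each
taxon is classified *neutral / above / below* against a Wilson score band
around its predicted frequency: taxa occurring more often than neutrality
predicts for their abundance are candidates for host selection, those
occurring less often are dispersal-limited or actively excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_io import CountTable, relative_abundance

__all__ = [
    "NCMFit",
    "occurrence_frequency",
    "mean_relative_abundance",
    "predict_frequency",
    "wilson_interval",
    "fit_ncm",
    "fit_ncm_by_stratum",
    "neutral_fraction_summary",
]


@dataclass
class NCMFit:
    """Result of one Sloan-model fit.

    ``otus`` has one row per fitted OTU: ``p`` (mean relative abundance),
    ``f_obs``, ``f_pred``, ``ci_low``, ``ci_high`` and ``classification``
    (neutral / above / below).  ``r2`` is NaN when all observed frequencies
    are identical (SS_tot = 0); classification is still performed.
    """

    m: float
    N: float
    d: int
    r2: float
    n_samples: int
    otus: pd.DataFrame = field(repr=False)
    ci_level: float = 0.95
    m_ci: tuple[float, float] | None = None
    n_excluded: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        """Percentage of OTUs in each class (sums to 100)."""
        counts = self.otus["classification"].value_counts()
        total = len(self.otus)
        return {
            c: 100.0 * counts.get(c, 0) / total if total else np.nan
            for c in ("neutral", "above", "below")
        }


def occurrence_frequency(table: CountTable, d: int = 1) -> pd.Series:
    """Fraction of samples in which each OTU has at least ``d`` reads."""
    if d < 1:
        raise ValueError("detection limit d must be >= 1")
    if table.n_samples == 0 or table.n_otus == 0:
        raise ValueError("empty count table")
    f = (table.counts >= d).mean(axis=0)
    return pd.Series(f, index=table.otu_ids, name="f_obs")


def mean_relative_abundance(table: CountTable) -> pd.Series:
    """Per-OTU mean of within-sample relative abundances (sums to 1)."""
    props = relative_abundance(table)
    return pd.Series(props.mean(axis=0), index=table.otu_ids, name="p")


def predict_frequency(p, m: float, N: float, d: int = 1):
    """Sloan prediction F(p; m, N, d); accepts scalar or array ``p``.

    Continuous limits F(0) = 0 and F(1) = 1 are applied at the endpoints.
    """
    if not (0.0 < m <= 1.0):
        raise ValueError("m must be in (0, 1]")
    if not np.isfinite(N) or N <= d:
        raise ValueError("community size N must be finite and > d")
    p_arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p_arr)) or np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must be finite and in [0, 1]")
    Nm = N * m
    out = np.empty_like(p_arr, dtype=float)
    interior = (p_arr > 0) & (p_arr < 1)
    out[p_arr <= 0] = 0.0
    out[p_arr >= 1] = 1.0
    if interior.any():
        a = Nm * p_arr[interior]
        b = Nm * (1.0 - p_arr[interior])
        out[interior] = 1.0 - special.betainc(a, b, d / N)
    return out if out.ndim else float(out)


def wilson_interval(f: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion ``f`` with ``n`` trials."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > 1):
        raise ValueError("f must be in [0, 1]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z * z / n
    center = (f_arr + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(f_arr * (1.0 - f_arr) / n + z * z / (4.0 * n * n)) / denom
    low = np.where(f_arr == 0.0, 0.0, np.clip(center - half, 0.0, 1.0))
    high = np.where(f_arr == 1.0, 1.0, np.clip(center + half, 0.0, 1.0))
    if f_arr.ndim == 0:
        return float(low), float(high)
    return low, high


def _sse(m: float, p: np.ndarray, f_obs: np.ndarray, N: float, d: int) -> float:
    resid = f_obs - predict_frequency(p, m, N, d)
    return float(np.dot(resid, resid))


def _sse_grid(m_grid: np.ndarray, p: np.ndarray, f_obs: np.ndarray, N: float, d: int) -> np.ndarray:
    # vectorized over (grid, otus)
    Nm = N * np.asarray(m_grid)[:, None]
    a = Nm * p[None, :]
    b = Nm * (1.0 - p[None, :])
    pred = 1.0 - special.betainc(a, b, d / N)
    resid = f_obs[None, :] - pred
    return (resid * resid).sum(axis=1)


def _estimate_m(
    p: np.ndarray, f_obs: np.ndarray, N: float, d: int, grid_step: float = 1e-3
) -> float:
    """Coarse grid scan over (0, 1] followed by bounded scalar refinement.

    The grid guarantees the global basin is found (the SSE surface can be
    multimodal for pathological inputs); the refinement gives sub-grid
    accuracy within the winning bracket.
    """
    grid = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    sse = _sse_grid(grid, p, f_obs, N, d)
    k = int(np.argmin(sse))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if lo >= hi:
        return float(grid[k])
    res = optimize.minimize_scalar(
        _sse, bounds=(lo, hi), args=(p, f_obs, N, d), method="bounded",
        options={"xatol": 1e-7},
    )
    if not res.success:
        raise RuntimeError(f"migration-rate optimizer failed: {res.message}")
    # keep whichever is better; the bracket minimum can sit on an edge
    return float(res.x) if res.fun <= sse[k] else float(grid[k])


def fit_ncm(
    table: CountTable,
    d: int = 1,
    ci_level: float = 0.95,
    bootstrap: int = 0,
    N_stat: str = "mean",
    seed: int = 0,
) -> NCMFit:
    """Fit the Sloan model to a count table and classify every detected OTU.

    ``N`` is the mean (or median, ``N_stat="median"``) sample read total.
    OTUs absent from every sample are excluded (no information); OTUs
    present everywhere are retained.  ``bootstrap > 0`` resamples samples
    with replacement to give a percentile CI for ``m``.
    """
    if table.n_samples < 10:
        warnings.warn(f"only {table.n_samples} samples; the fit may be unstable")
    totals = table.sample_totals()
    N = float(np.mean(totals) if N_stat == "mean" else np.median(totals))
    if N <= d:
        raise ValueError("mean sample depth must exceed the detection limit")
    p_all = mean_relative_abundance(table)
    f_all = occurrence_frequency(table, d)
    detected = f_all > 0
    n_excluded = int((~detected).sum())
    p = p_all[detected].to_numpy()
    f_obs = f_all[detected].to_numpy()
    otu_ids = list(f_all.index[detected])
    n_informative = int(((f_obs > 0) & (f_obs < 1)).sum())
    if n_informative < 2:
        warnings.warn("fewer than 2 OTUs with intermediate occurrence; fit is degenerate")

    m_hat = _estimate_m(p, f_obs, N, d)
    f_pred = predict_frequency(p, m_hat, N, d)
    ss_res = float(np.sum((f_obs - f_pred) ** 2))
    ss_tot = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    ci_low, ci_high = wilson_interval(f_pred, table.n_samples, ci_level)
    classification = np.where(
        f_obs > ci_high, "above", np.where(f_obs < ci_low, "below", "neutral")
    )
    otus = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "p": p,
            "f_obs": f_obs,
            "f_pred": f_pred,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "classification": classification,
        }
    )

    m_ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        ms = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, table.n_samples, table.n_samples)
            sub = CountTable(
                [f"b{j}" for j in range(table.n_samples)],
                list(table.otu_ids),
                table.counts[idx],
            )
            pb = mean_relative_abundance(sub)
            fb = occurrence_frequency(sub, d)
            det = fb > 0
            ms[b] = _estimate_m(
                pb[det].to_numpy(), fb[det].to_numpy(), N, d, grid_step=5e-3
            )
        m_ci = (float(np.quantile(ms, 0.025)), float(np.quantile(ms, 0.975)))

    return NCMFit(
        m=m_hat,
        N=N,
        d=d,
        r2=r2,
        n_samples=table.n_samples,
        otus=otus,
        ci_level=ci_level,
        m_ci=m_ci,
        n_excluded=n_excluded,
    )


def fit_ncm_by_stratum(
    table: CountTable,
    metadata: pd.DataFrame,
    strata: list[str],
    d: int = 1,
    ci_level: float = 0.95,
) -> dict[tuple, NCMFit | None]:
    """One fit per level-combination of the ``strata`` metadata columns.

    Strata whose fit is degenerate (all samples empty, < 2 detected OTUs)
    map to None rather than being dropped.
    """
    meta = metadata.set_index("sample_id")
    fits: dict[tuple, NCMFit | None] = {}
    for key, grp in meta.groupby(strata, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        ids = [s for s in grp.index if s in set(table.sample_ids)]
        if not ids:
            fits[key] = None
            continue
        sub = table.select_samples(ids).drop_empty_samples()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[key] = fit_ncm(sub, d=d, ci_level=ci_level)
        except (ValueError, RuntimeError):
            fits[key] = None
    return fits


def neutral_fraction_summary(fits: Mapping, strata_names: list[str] | None = None) -> pd.DataFrame:
    """Tabulate %neutral / %above / %below, m and R² per stratum.

    Empty or failed strata appear as flagged rows (NaNs), never dropped.
    """
    rows = []
    for key, fit in fits.items():
        key = key if isinstance(key, tuple) else (key,)
        names = strata_names or [f"stratum_{i + 1}" for i in range(len(key))]
        row = dict(zip(names, key))
        if fit is None or len(fit.otus) == 0:
            row.update(
                n_otus=0, pct_neutral=np.nan, pct_above=np.nan, pct_below=np.nan,
                m=np.nan, r2=np.nan, ok=False,
            )
        else:
            frac = fit.fractions
            row.update(
                n_otus=len(fit.otus),
                pct_neutral=frac["neutral"],
                pct_above=frac["above"],
                pct_below=frac["below"],
                m=fit.m,
                r2=fit.r2,
                ok=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
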