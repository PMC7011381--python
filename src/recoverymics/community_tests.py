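"""Permutation tests on distance matrices and rank tests with FDR control.

PERMANOVA partitions squared inter-sample distances among groups and
assesses the pseudo-F by permuting sample labels; MRPP compares the
group-size-weighted mean within-group distance δ to its permutation
distribution (chance-corrected effect size A); the dispersion-homogeneity
test ("betadisper") embeds samples by principal-coordinate analysis —
keeping negative eigenvalues as imaginary axes — and applies a one-way F
test to distances from group centroids.  All permutation p values use the
(1 + b) / (1 + B) convention and an exhaustive-enumeration mode for small
n.  Rank tests (Kruskal–Wallis, Wilcoxon rank-sum, Fisher exact) and
Benjamini–Hochberg adjustment wrap the standard SciPy / statsmodels
routines behind one surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .core_io import CountTable, relative_abundance

__all__ = [
    "PermutationTestResult",
    "permanova",
    "mrpp",
    "PCoAResult",
    "pcoa",
    "betadisper",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "bh_adjust",
    "differential_abundance",
    "pairwise_permutation_tests",
]

_EXACT_N_MAX = 9  # n! enumeration guard


@dataclass
class PermutationTestResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    groups: str
    effect_size: float | None = None  # MRPP chance-corrected A
    permuted_stats: np.ndarray | None = field(default=None, repr=False)


def _align_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    """Group labels aligned to dm.ids; accepts a Series keyed by id or a
    positional sequence."""
    if isinstance(groups, (pd.Series, dict)):
        g = pd.Series(groups)
        missing = [i for i in dm.ids if i not in g.index]
        if missing:
            raise ValueError(f"no group label for sample(s): {missing}")
        labels = g.loc[list(dm.ids)].to_numpy()
    else:
        labels = np.asarray(groups)
        if labels.size != len(dm.ids):
            raise ValueError("group vector length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton group(s): {bad}")
    return labels


def _permute(
    stat_fn, labels: np.ndarray, n_perm: int, seed: int, tail: str,
    method: str = "auto", strata: np.ndarray | None = None,
) -> tuple[float, float, int, np.ndarray]:
    """Shared permutation engine.

    ``method='exact'`` enumerates every distinct labelling (n <= 9, no
    strata) and returns the exact tail probability; otherwise ``n_perm``
    random permutations with p = (1 + b) / (1 + B).
    """
    obs = stat_fn(labels)
    n = labels.size
    if method == "exact":
        if strata is not None:
            raise ValueError("exact enumeration does not support strata")
        if n > _EXACT_N_MAX:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_N_MAX}")
        seen = set()
        perm_stats = []
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            perm_stats.append(stat_fn(np.asarray(perm)))
        perm_stats = np.asarray(perm_stats)
        if tail == "upper":
            p = float(np.mean(perm_stats >= obs - 1e-12))
        else:
            p = float(np.mean(perm_stats <= obs + 1e-12))
        return obs, p, perm_stats.size, perm_stats
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    idx = np.arange(n)
    for b in range(n_perm):
        if strata is None:
            rng.shuffle(idx)
        else:
            idx = np.arange(n)
            for s in np.unique(strata):
                sel = np.flatnonzero(strata == s)
                idx[sel] = sel[rng.permutation(sel.size)]
        perm_stats[b] = stat_fn(labels[idx])
    if tail == "upper":
        b_ge = int(np.sum(perm_stats >= obs - 1e-12))
    else:
        b_ge = int(np.sum(perm_stats <= obs + 1e-12))
    p = (1.0 + b_ge) / (1.0 + n_perm)
    return obs, p, n_perm, perm_stats


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    ss_total = d2.sum() / (2.0 * n)  # Σ_{i<j} d²/n
    ss_within = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    a = uniq.size
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "auto",
    strata=None,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA (pseudo-F on squared distances).

    ``strata`` restricts label permutations to within-stratum shuffles
    (e.g. within tanks).  ``method='exact'`` enumerates all labellings.
    """
    labels = _align_groups(dm, groups)
    strata_arr = None if strata is None else _as_strata(dm, strata)
    d2 = dm.data**2
    obs, p, nperm, perm_stats = _permute(
        lambda lab: _pseudo_f(d2, lab), labels, n_perm, seed, "upper", method, strata_arr
    )
    return PermutationTestResult(
        "pseudo-F", obs, p, nperm, _describe_groups(labels), permuted_stats=perm_stats
    )


def _as_strata(dm: DistanceMatrix, strata) -> np.ndarray:
    if isinstance(strata, (pd.Series, dict)):
        s = pd.Series(strata)
        return s.loc[list(dm.ids)].to_numpy()
    arr = np.asarray(strata)
    if arr.size != len(dm.ids):
        raise ValueError("strata length does not match distance matrix")
    return arr


def _describe_groups(labels: np.ndarray) -> str:
    uniq, counts = np.unique(labels, return_counts=True)
    return ", ".join(f"{u} (n={c})" for u, c in zip(uniq, counts))


def _mrpp_delta(d: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    delta = 0.0
    for g in np.unique(labels):
        mask = labels == g
        ng = int(mask.sum())
        within = d[np.ix_(mask, mask)].sum() / 2.0
        mean_within = within / (ng * (ng - 1) / 2.0)
        delta += (ng / n) * mean_within
    return delta


def mrpp(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "auto",
    strata=None,
) -> PermutationTestResult:
    """Multi-response permutation procedure.

    δ is the group-size-weighted mean within-group distance (lower-tail
    test); A = 1 − δ_obs / mean(δ_perm) is the chance-corrected effect.
    """
    labels = _align_groups(dm, groups)
    strata_arr = None if strata is None else _as_strata(dm, strata)
    d = dm.data
    obs, p, nperm, perm_stats = _permute(
        lambda lab: _mrpp_delta(d, lab), labels, n_perm, seed, "lower", method, strata_arr
    )
    A = 1.0 - obs / float(np.mean(perm_stats))
    return PermutationTestResult(
        "MRPP delta", obs, p, nperm, _describe_groups(labels),
        effect_size=A, permuted_stats=perm_stats,
    )


@dataclass
class PCoAResult:
    """Principal coordinates with negative eigenvalues kept as imaginary
    axes, so squared original distances are recoverable as
    Σ_real Δ² − Σ_imag Δ²."""

    ids: list[str]
    eigenvalues: np.ndarray
    coords_real: np.ndarray  # n × k_pos
    coords_imag: np.ndarray  # n × k_neg
    has_negative: bool


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PCoAResult:
    """Gower-centered eigendecomposition of −½ D²."""
    D2 = dm.data**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.abs(evals)
    tol = eig_tol * max(scale.max(), 1.0)
    pos = evals > tol
    neg = evals < -tol
    coords_real = evecs[:, pos] * np.sqrt(evals[pos])
    coords_imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return PCoAResult(list(dm.ids), evals, coords_real, coords_imag, bool(neg.any()))


def _centroid_distances(res: PCoAResult, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in the mixed
    real/imaginary PCoA geometry (clamped at zero)."""
    z = np.empty(labels.size)
    for g in np.unique(labels):
        mask = labels == g
        cr = res.coords_real[mask].mean(axis=0)
        ci = res.coords_imag[mask].mean(axis=0) if res.coords_imag.size else 0.0
        dr = ((res.coords_real[mask] - cr) ** 2).sum(axis=1)
        di = (
            ((res.coords_imag[mask] - ci) ** 2).sum(axis=1)
            if res.coords_imag.size
            else 0.0
        )
        z[mask] = np.sqrt(np.maximum(dr - di, 0.0))
    return z


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        v = values[labels == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    a = uniq.size
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def betadisper(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "auto",
    strata=None,
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions.

    The embedding is computed once from the observed distance matrix;
    permutations reshuffle group labels over the fixed sample coordinates
    (centroids and centroid distances are recomputed per permutation).
    """
    labels = _align_groups(dm, groups)
    strata_arr = None if strata is None else _as_strata(dm, strata)
    res = pcoa(dm)

    def stat(lab: np.ndarray) -> float:
        return _anova_f(_centroid_distances(res, lab), lab)

    obs, p, nperm, perm_stats = _permute(
        stat, labels, n_perm, seed, "upper", method, strata_arr
    )
    return PermutationTestResult(
        "dispersion F", obs, p, nperm, _describe_groups(labels), permuted_stats=perm_stats
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = a − 1)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in uniq]
    if np.unique(values).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum.

    Returns the rank-sum W of ``x`` (average ranks under ties); exact p for
    small tie-free samples, normal approximation with continuity and tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    w = float(u) + x.size * (x.size + 1) / 2.0
    return w, float(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds ratio, p)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative entries")
    orat, p = stats.fisher_exact(t, alternative="two-sided")
    return float(orat), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    table: CountTable,
    metadata: pd.DataFrame,
    factor: str = "treatment",
    contrast: tuple[str, str] | None = None,
    test: str = "wilcoxon",
    d: int = 1,
) -> pd.DataFrame:
    """Per-OTU two-group (or multi-group) abundance test with BH control.

    Rank tests run on relative abundances; ``fisher_presence`` tests the
    2×2 presence/absence table at detection limit ``d``.  One row per OTU
    is always returned (no silent drops).
    """
    meta = metadata.set_index("sample_id")
    labels = meta.loc[list(table.sample_ids), factor].to_numpy()
    levels = list(np.unique(labels))
    if contrast is not None:
        for lev in contrast:
            if lev not in levels:
                raise ValueError(f"contrast level {lev!r} absent from {factor!r}")
        keep = np.isin(labels, contrast)
        sub = CountTable(
            [s for s, k in zip(table.sample_ids, keep) if k],
            list(table.otu_ids),
            table.counts[keep],
        )
        labels = labels[keep]
    else:
        if test != "kruskal":
            raise ValueError("contrast is required unless test='kruskal'")
        sub = table
    props = relative_abundance(sub)
    rows = []
    for j, otu in enumerate(sub.otu_ids):
        if test == "wilcoxon":
            xa = props[labels == contrast[0], j]
            xb = props[labels == contrast[1], j]
            if np.unique(np.concatenate([xa, xb])).size == 1:
                statv, p = np.nan, 1.0
            else:
                statv, p = wilcoxon_rank_sum(xa, xb)
        elif test == "kruskal":
            statv, p = kruskal_wallis(props[:, j], labels)
        elif test == "fisher_presence":
            pres = sub.counts[:, j] >= d
            t2 = [
                [int(pres[labels == lev].sum()), int((~pres[labels == lev]).sum())]
                for lev in contrast
            ]
            statv, p = fisher_exact_2x2(t2)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"otu_id": otu, "statistic": statv, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def pairwise_permutation_tests(
    dm: DistanceMatrix,
    groups,
    tests=("permanova", "mrpp", "betadisper"),
    n_perm: int = 999,
    seed: int = 0,
    strata=None,
) -> pd.DataFrame:
    """All pairwise group contrasts for each test, BH-adjusted per test
    family across the pairs (the divergence-table layout)."""
    labels = pd.Series(_align_groups(dm, groups), index=list(dm.ids))
    funcs = {"permanova": permanova, "mrpp": mrpp, "betadisper": betadisper}
    rows = []
    levels = sorted(labels.unique())
    for test in tests:
        fn = funcs[test]
        for a, b in itertools.combinations(levels, 2):
            ids = labels.index[labels.isin([a, b])].tolist()
            sub = dm.filter(ids)
            sub_strata = None
            if strata is not None:
                sub_strata = pd.Series(strata).loc[ids].to_numpy()
            res = fn(sub, labels.loc[ids], n_perm=n_perm, seed=seed, strata=sub_strata)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "test": test,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "effect_size": res.effect_size,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for test in tests:
        mask = out["test"] == test
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
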