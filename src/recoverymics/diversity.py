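"""Alpha diversity and generalized UniFrac phylogenetic beta diversity.

Alpha metrics are richness (detected OTUs), Shannon entropy H (natural
log), the Shannon effective number exp(H) and Pielou-type evenness
H / ln(richness).  Beta diversity is the generalized UniFrac distance

    d(A, B) = Σ_b l_b (p_A + p_B)^α |p_A − p_B| / (p_A + p_B)
              ─────────────────────────────────────────────────
              Σ_b l_b (p_A + p_B)^α

over tree branches b with length l_b, where p_X(b) is the fraction of
sample X's reads descending from b.  The exponent α ∈ [0, 1] interpolates
between emphasizing rare (α = 0) and abundant (α = 1) lineages; α = 0.5 is
the conventional compromise default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .core_io import CountTable, relative_abundance

__all__ = [
    "alpha_diversity",
    "rarefy",
    "branch_proportions",
    "gunifrac",
    "gunifrac_alpha_family",
]


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness, Shannon (nat log), effective number, evenness.

    Evenness is undefined (NaN) for samples with richness <= 1; the ratio
    richness / effective-number is the heterogeneity measure used as a
    response variable in mixed-model trend analyses.
    """
    props = relative_abundance(table)
    richness = (table.counts >= 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    shannon = -plogp.sum(axis=1)
    effective = np.exp(shannon)
    evenness = np.where(richness > 1, shannon / np.log(np.maximum(richness, 2)), np.nan)
    return pd.DataFrame(
        {
            "richness": richness.astype(int),
            "shannon": shannon,
            "shannon_effective": effective,
            "evenness": evenness,
            "ratio_richness_over_effective": richness / effective,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample each sample without replacement to a common depth
    (default: the minimum sample total).  Seeded and deterministic."""
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if (totals < depth).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t < depth]
        raise ValueError(f"samples shallower than rarefaction depth: {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CountTable(list(table.sample_ids), list(table.otu_ids), out)


def branch_proportions(
    table: CountTable, tree: TreeNode, prune_missing: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """One postorder pass: per-branch descendant read fraction per sample.

    Returns ``(lengths, P)`` where ``lengths`` has one entry per non-root
    branch and ``P[b, i]`` is the fraction of sample i's reads below branch
    b.  The root branch is excluded: it carries every read of both samples
    and cannot discriminate.  OTUs with nonzero counts that are missing
    from the tree raise unless ``prune_missing`` (then their reads are
    dropped and proportions renormalized).
    """
    tip_names = {t.name for t in tree.tips()}
    present = table.counts.sum(axis=0) > 0
    missing = [o for o, pr in zip(table.otu_ids, present) if pr and o not in tip_names]
    counts = table.counts.astype(float)
    if missing:
        if not prune_missing:
            raise ValueError(f"OTU(s) not in tree: {missing}")
        warnings.warn(f"pruning {len(missing)} OTU(s) absent from the tree")
        keep = [o in tip_names for o in table.otu_ids]
        counts = counts[:, keep]
        otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    else:
        otu_ids = list(table.otu_ids)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s) after pruning: {bad}")
    props = counts / totals[:, None]
    col = {o: j for j, o in enumerate(otu_ids)}

    n = table.n_samples
    lengths: list[float] = []
    vectors: list[np.ndarray] = []
    node_vec: dict[int, np.ndarray] = {}
    if len(list(tree.children)) > 2:
        warnings.warn("root is multifurcating; treating it as the rooting point")
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            j = col.get(node.name)
            v = props[:, j].copy() if j is not None else np.zeros(n)
        else:
            v = np.zeros(n)
            for child in node.children:
                v += node_vec.pop(id(child))
        node_vec[id(node)] = v
        if node is not tree:  # root branch excluded
            lengths.append(float(node.length or 0.0))
            vectors.append(v)
    return np.asarray(lengths), np.asarray(vectors)


def _pairwise_gunifrac(lengths: np.ndarray, P: np.ndarray, alpha: float) -> np.ndarray:
    n = P.shape[1]
    out = np.zeros((n, n))
    for i in range(n - 1):
        a = P[:, i : i + 1]
        b = P[:, i + 1 :]
        s = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(s > 0, np.abs(a - b) / np.where(s > 0, s, 1.0), 0.0)
            weight = np.where(s > 0, s**alpha, 0.0) * lengths[:, None]
        num = (weight * ratio).sum(axis=0)
        den = weight.sum(axis=0)
        if (den == 0).any():
            raise ValueError("degenerate sample pair with no shared tree mass")
        out[i, i + 1 :] = num / den
        out[i + 1 :, i] = out[i, i + 1 :]
    return out


def gunifrac(
    table: CountTable, tree: TreeNode, alpha: float = 0.5, prune_missing: bool = False
) -> DistanceMatrix:
    """Generalized UniFrac distance matrix between all sample pairs."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    lengths, P = branch_proportions(table, tree, prune_missing)
    return DistanceMatrix(_pairwise_gunifrac(lengths, P, alpha), ids=table.sample_ids)


def gunifrac_alpha_family(
    table: CountTable,
    tree: TreeNode,
    alphas=(0.0, 0.5, 1.0),
    prune_missing: bool = False,
) -> dict[float, DistanceMatrix]:
    """GUniFrac at several α values sharing one tree traversal."""
    for a in alphas:
        if not (0.0 <= a <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
    lengths, P = branch_proportions(table, tree, prune_missing)
    return {
        float(a): DistanceMatrix(_pairwise_gunifrac(lengths, P, a), ids=table.sample_ids)
        for a in alphas
    }
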