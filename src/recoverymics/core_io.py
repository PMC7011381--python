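"""Domain types and file IO for count tables, sample metadata and trees.

The package's universal input is an integer sample × OTU count table plus a
per-sample design table (treatment / habitat / timepoint / tank / replicate)
and, for phylogenetic distances, a rooted Newick tree whose leaves are the
OTU ids.  Everything here is plain text: tab-separated tables, UTF-8,
decimal point ``.``.  Matrices are addressed by id at every API boundary;
row/column order is preserved as read but never load-bearing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "TREATMENTS",
    "HABITATS",
    "TIMEPOINTS",
    "CountTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_newick",
    "write_newick",
    "relative_abundance",
    "read_distance_matrix",
    "write_distance_matrix",
    "DistanceMatrix",
]

#: Factor levels of the experimental design: control, constant-cadmium and
#: variable-cadmium exposure regimes.
TREATMENTS = ("Ctrl", "CC", "CV")
#: Sampled community habitats.
HABITATS = ("water", "skin", "gut")
#: Sampling schedule: T0 start, T3 end of exposure, TR1-TR4 recovery
#: samplings, T5 terminal.
TIMEPOINTS = ("T0", "T3", "TR1", "TR2", "TR3", "TR4", "T5")

METADATA_COLUMNS = ("sample_id", "treatment", "habitat", "timepoint", "tank", "replicate")


@dataclass
class CountTable:
    """Integer abundance matrix of shape (n_samples, n_otus).

    Parameters
    ----------
    sample_ids, otu_ids
        Unique ordered identifiers for rows and columns.
    counts
        Non-negative integer matrix, one row per sample.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.allclose(self.counts, np.round(self.counts)):
                self.counts = np.round(self.counts).astype(np.int64)
            else:
                raise ValueError("non-integer counts; use allow_float to round on read")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    # -- container conveniences -------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, ids) -> "CountTable":
        """Subset (and reorder) to the given sample ids."""
        idx = [self.sample_ids.index(str(s)) for s in ids]
        return CountTable([self.sample_ids[i] for i in idx], list(self.otu_ids), self.counts[idx])

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def drop_empty_samples(self) -> "CountTable":
        keep = self.sample_totals() > 0
        return CountTable(
            [s for s, k in zip(self.sample_ids, keep) if k], list(self.otu_ids), self.counts[keep]
        )


def read_count_table(
    path, orientation: str = "samples_as_rows", allow_float: bool = False
) -> CountTable:
    """Read a tab-separated count table.

    ``orientation`` is ``samples_as_rows`` or ``otus_as_rows``; the result is
    always samples × OTUs.  Non-integer cells are an error unless
    ``allow_float`` is set, in which case they are rounded with a warning.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.isna().any().any():
        raise ValueError("ragged or missing cells in count table")
    if orientation == "otus_as_rows":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric cells in count table")
    if not np.issubdtype(values.dtype, np.integer):
        if np.allclose(values, np.round(values)):
            values = np.round(values).astype(np.int64)
        elif allow_float:
            warnings.warn("rounding non-integer counts to nearest integer")
            values = np.round(values).astype(np.int64)
        else:
            raise ValueError("non-integer counts; pass allow_float=True to round")
    if (values < 0).any():
        raise ValueError("negative count")
    return CountTable([str(i) for i in df.index], [str(c) for c in df.columns], values)


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame in place and return it.

    Checks required columns, factor levels, tank/replicate ranges and
    sample-id uniqueness; raises ``ValueError`` naming the offending value.
    """
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required metadata column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    for col, levels in (("treatment", TREATMENTS), ("habitat", HABITATS), ("timepoint", TIMEPOINTS)):
        bad = sorted(set(df[col].astype(str)) - set(levels))
        if bad:
            raise ValueError(f"unknown {col} level(s): {bad}; allowed {levels}")
    df["tank"] = df["tank"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    if (df["tank"] < 1).any() or (df["tank"] > 8).any():
        raise ValueError("tank must be an integer in 1..8")
    if (df["replicate"] < 1).any():
        raise ValueError("replicate must be >= 1")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a tab-separated sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_metadata(df)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree, validating leaf-label uniqueness.

    Branches without a length get length 0.0 with a warning; interior
    zero-length branches are common in denoised trees and are harmless for
    UniFrac-type sums.
    """
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf label(s): {dups}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on {node.name!r}")
    if n_missing:
        warnings.warn(f"{n_missing} branch(es) had no length; set to 0.0")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def relative_abundance(table: CountTable) -> np.ndarray:
    """Row-normalized proportions; each row sums to 1.

    Raises on any zero-total sample (the sample carries no composition).
    """
    totals = table.sample_totals()
    zero = np.asarray(totals == 0).nonzero()[0]
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"zero-total sample(s): {bad}")
    return table.counts / totals[:, None]


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="id", float_format="%.12g"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
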