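"""Count matrices, CPM normalization, expression thresholds, abundance shares.

Library size is the per-sample total of miRNA-assigned reads (the matrix
column sum), not the raw read count: normalization happens within the miRNA
compartment, so per-group percentage shares sum to 100 across miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .isomir import IsomiRCall, IsomiRCatalog

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Features x samples raw counts with per-sample library sizes."""

    counts: pd.DataFrame  # features x samples, non-negative
    level: str  # {canonical, isomir}

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.level not in ("canonical", "isomir"):
            raise ValueError(f"bad level {self.level!r}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def build_matrix(
    calls_per_sample: dict[str, list[IsomiRCall]],
    catalog: IsomiRCatalog,
    level: str = "canonical",
    strict: bool = False,
) -> CountMatrix:
    """Aggregate per-sample calls into a count matrix.

    canonical level: one row per mature id; by default a parent's count
    includes all its isomiR reads, ``strict=True`` restricts to exact
    canonical sequences. isomir level: one row per catalog name (canonical
    sequences keep the plain mature id as their name).
    """
    names_in_catalog = {(c.parent_mature_id, c.sequence) for c in catalog.calls.values()}
    columns = {}
    for sample, calls in calls_per_sample.items():
        col: dict[str, float] = {}
        for c in calls:
            if (c.parent_mature_id, c.sequence) not in names_in_catalog:
                raise ValueError(
                    f"sample {sample}: call {c.sequence[:20]}... absent from catalog"
                )
            if level == "canonical":
                if strict and not c.canonical:
                    continue
                key = c.parent_mature_id
            else:
                key = catalog.lookup(c.parent_mature_id, c.sequence).name
            col[key] = col.get(key, 0) + c.multiplicity
        columns[sample] = col

    if level == "isomir":
        features = sorted(catalog.names())
    else:
        features = sorted({c.parent_mature_id for c in catalog.calls.values()})
    mat = pd.DataFrame(
        {s: [columns[s].get(f, 0) for f in features] for s in calls_per_sample},
        index=pd.Index(features, name="feature"),
    )
    empty = mat.columns[mat.sum(axis=0) == 0]
    if len(empty):
        log.warning("samples with zero assigned reads: %s", list(empty))
    if np.allclose(mat.values, np.round(mat.values)):
        mat = mat.round().astype(np.int64)
    return CountMatrix(mat, level)


def cpm(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million of the sample's assigned library."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        log.warning("dropping zero-library samples from CPM: %s", list(zero))
        counts = counts.drop(columns=zero)
        lib = lib.drop(zero)
    return counts.div(lib, axis=1) * 1e6


def expression_filter(
    matrix: CountMatrix | pd.DataFrame, min_mean_percent: float = 0.001
) -> list[str]:
    """Features whose mean percentage of library across samples exceeds the
    threshold (default 0.001%, strict inequality)."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    lib = counts.sum(axis=0)
    keep_cols = lib.index[lib > 0]
    pct = counts[keep_cols].div(lib[keep_cols], axis=1) * 100
    mean_pct = pct.mean(axis=1)
    return list(mean_pct.index[mean_pct > min_mean_percent])


def abundance_shares(
    matrix: CountMatrix | pd.DataFrame,
    groups: pd.Series,
    top_n: int = 20,
) -> pd.DataFrame:
    """Per-group pooled percentage shares of the top ``top_n`` features.

    share(f) = sum of f's counts over the group / group library total x 100
    (pooled counts, not the mean of per-sample shares).
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise ValueError(f"samples without group label: {sorted(missing)}")
    rows = []
    for group in pd.unique(groups.loc[counts.columns]):
        samples = [s for s in counts.columns if groups[s] == group]
        pooled = counts[samples].sum(axis=1)
        total = pooled.sum()
        share = (pooled / total * 100) if total > 0 else pooled * 0.0
        ranked = share.sort_values(ascending=False, kind="mergesort").head(top_n)
        cum = ranked.cumsum()
        for rank, (feat, pct) in enumerate(ranked.items(), start=1):
            rows.append(
                {"group": group, "rank": rank, "feature": feat,
                 "share_percent": pct, "cumulative_percent": cum[feat]}
            )
    return pd.DataFrame(rows)


def load_manifest(path: str | Path) -> pd.Series:
    """sample_id -> group from a two-column TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("manifest needs columns sample_id, group")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    return df.set_index("sample_id")["group"]
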