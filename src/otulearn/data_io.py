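"""Community tables, targets, rarefaction, scaling and replicate-aware splits.

The central containers are :class:`OtuTable` (a samples x taxa count matrix
with sample, replicate-group and taxon identifiers) and :class:`TargetVector`
(one continuous function value per sample, e.g. dissolved organic carbon).
All downstream regression and feature-selection code consumes these two
objects.

Replicate microcosms inoculated from the same source community are not
independent, so train/test splitting is performed at the level of replicate
*groups*: no group ever straddles the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("otulearn")

__all__ = [
    "OtuTable",
    "TargetVector",
    "StandardizationStats",
    "read_table",
    "write_table",
    "rarefy",
    "group_split",
    "standardize",
]

#: Reserved CSV column names (everything else in the header is a taxon id).
SAMPLE_COL = "sample_id"
GROUP_COL = "group_id"
TARGET_COL = "target"


@dataclass
class OtuTable:
    """Sample x taxon abundance matrix with identifiers.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``counts``.
    taxon_ids
        Unique taxon (OTU) identifiers, one per column of ``counts``.
    counts
        ``N x M`` matrix. Non-negative integers for raw/rarefied data;
        arbitrary reals once ``standardized`` is set.
    group_ids
        Replicate-group label per sample (same length as ``sample_ids``).
        Samples sharing a label came from the same source community and must
        not be separated across a train/test split.
    standardized
        True once the matrix holds z-scores rather than counts.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    group_ids: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} rows of counts"
            )
        if len(self.taxon_ids) != m:
            raise ValueError(
                f"{len(self.taxon_ids)} taxon ids but {m} columns of counts"
            )
        if len(set(self.sample_ids)) != n:
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(set(self.taxon_ids)) != m:
            raise ValueError("duplicate taxon ids")
        if self.group_ids is not None and len(self.group_ids) != n:
            raise ValueError("group_ids length must match sample count")
        if not self.standardized and np.any(self.counts < 0):
            raise ValueError("negative counts in non-standardized table")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "OtuTable":
        """Row subset (by positional index), preserving order of ``idx``."""
        idx = np.asarray(idx)
        return OtuTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            taxon_ids=list(self.taxon_ids),
            counts=self.counts[idx],
            group_ids=None
            if self.group_ids is None
            else [self.group_ids[i] for i in idx],
            standardized=self.standardized,
        )

    def subset_taxa(self, taxa: list[str]) -> "OtuTable":
        """Column subset by taxon id, preserving the order of ``taxa``."""
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        cols = [pos[t] for t in taxa]
        return replace(
            self, taxon_ids=list(taxa), counts=self.counts[:, cols]
        )

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised matrix; all-zero rows stay zero."""
        if self.standardized:
            raise ValueError("relative abundance undefined for z-scored data")
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name=SAMPLE_COL),
            columns=self.taxon_ids,
        )
        return df


@dataclass
class TargetVector:
    """Continuous per-sample target (e.g. DOC), aligned with an OtuTable."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("target must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite target values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StandardizationStats:
    """Per-taxon location/scale computed from training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    ddof: int = 0
    source: str = "training"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd < 0):
            raise ValueError("negative standard deviation")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Z-score with training stats; constant training columns -> 0."""
        sd = np.where(self.sd == 0, 1.0, self.sd)
        Z = (np.asarray(X, dtype=float) - self.mean) / sd
        Z[:, self.sd == 0] = 0.0
        return Z

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        """Map z-scores back to the original count scale.

        Exact round-trip for non-constant features; constant features are
        restored to their (constant) training mean.
        """
        sd = np.where(self.sd == 0, 1.0, self.sd)
        X = np.asarray(Z, dtype=float) * sd + self.mean
        X[:, self.sd == 0] = self.mean[self.sd == 0]
        return X


# ---------------------------------------------------------------------------
# I/O

def _derive_groups(sample_ids: list[str], delimiter: str) -> list[str]:
    # group = everything before the last delimiter-separated token, so
    # "soil17_rep2" -> "soil17"; ids without the delimiter are their own group
    out = []
    for s in sample_ids:
        head, _, tail = s.rpartition(delimiter)
        out.append(head if head else s)
    return out


def read_table(
    path,
    target_column: str | None = TARGET_COL,
    group_column: str | None = GROUP_COL,
    sep: str = ",",
    group_delimiter: str = "_",
) -> tuple[OtuTable, TargetVector | None]:
    """Read a samples-x-taxa CSV (first column = sample id).

    Columns named ``group_id`` / ``target`` (configurable) are treated as
    metadata; every other column is a taxon. When no group column is present
    replicate groups are derived from the sample-id prefix before the last
    ``group_delimiter``-separated token.

    Returns the table and the target vector (``None`` if no target column).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"empty table: {path}")
    sample_ids = [str(s) for s in df.index]
    if pd.Index(sample_ids).duplicated().any():
        dupes = pd.Index(sample_ids)
        raise ValueError(
            f"duplicate sample ids in {path}: "
            f"{sorted(set(dupes[dupes.duplicated()]))}"
        )

    target = None
    if target_column is not None and target_column in df.columns:
        target = TargetVector(df.pop(target_column).to_numpy(dtype=float))
    elif target_column not in (None, TARGET_COL):
        raise ValueError(f"missing target column {target_column!r} in {path}")

    if group_column is not None and group_column in df.columns:
        group_ids = [str(g) for g in df.pop(group_column)]
    else:
        group_ids = _derive_groups(sample_ids, group_delimiter)

    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"non-numeric abundance column(s): {bad}")
    counts = df.to_numpy()
    standardized = bool(
        np.any(counts < 0) or not np.allclose(counts, np.round(counts))
    )
    table = OtuTable(
        sample_ids=sample_ids,
        taxon_ids=[str(c) for c in df.columns],
        counts=counts if standardized else counts.astype(np.int64),
        group_ids=group_ids,
        standardized=standardized,
    )
    return table, target


def write_table(
    table: OtuTable,
    path,
    target: TargetVector | None = None,
    sep: str = ",",
) -> None:
    """Write a table (and optional target/group columns) in the CSV dialect
    accepted by :func:`read_table`."""
    df = table.to_dataframe()
    if table.group_ids is not None:
        df.insert(0, GROUP_COL, table.group_ids)
    if target is not None:
        if len(target) != table.n_samples:
            raise ValueError("target length mismatch")
        df.insert(0, TARGET_COL, target.values)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Rarefaction

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample without replacement to a fixed read depth.

    Samples with fewer than ``depth`` reads are dropped (with a warning).
    Draws are multivariate hypergeometric, the standard ecological
    rarefaction model.
    """
    if table.standardized:
        raise ValueError("cannot rarefy standardized data")
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    counts = np.asarray(table.counts, dtype=np.int64)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    rows = []
    dropped = []
    for i in range(table.n_samples):
        total = int(counts[i].sum())
        if total < depth:
            dropped.append(table.sample_ids[i])
            continue
        rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        keep.append(i)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
        logger.warning("rarefy dropped samples: %s", dropped)
    out = table.subset_samples(np.array(keep, dtype=int))
    out.counts = np.asarray(rows, dtype=np.int64).reshape(len(keep), table.n_taxa)
    return out


# ---------------------------------------------------------------------------
# Replicate-group-aware splitting

def group_split(
    table: OtuTable,
    target: TargetVector,
    test_fraction: float,
    seed: int,
) -> tuple[tuple[OtuTable, TargetVector], tuple[OtuTable, TargetVector]]:
    """Split samples into train/test at the replicate-group level.

    Groups are shuffled and a prefix is assigned to the test partition, cut
    at the point whose cumulative size is closest to
    ``test_fraction * N``. No group id ever appears on both sides, which
    keeps replicate microcosms from leaking between train and test.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if table.group_ids is None:
        raise ValueError("group_ids required for a replicate-aware split")
    if len(target) != table.n_samples:
        raise ValueError("target/table length mismatch")
    groups = list(dict.fromkeys(table.group_ids))  # order-preserving unique
    if len(groups) < 2:
        raise ValueError("cannot split a single replicate group")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    sizes = pd.Series(table.group_ids).value_counts()
    target_n = test_fraction * table.n_samples
    cum = 0
    test_groups: set[str] = set()
    for gi in order:
        g = groups[gi]
        if abs(cum + sizes[g] - target_n) <= abs(cum - target_n):
            test_groups.add(g)
            cum += sizes[g]
        else:
            break
    is_test = np.array([g in test_groups for g in table.group_ids])
    tr = np.flatnonzero(~is_test)
    te = np.flatnonzero(is_test)
    return (
        (table.subset_samples(tr), TargetVector(target.values[tr])),
        (table.subset_samples(te), TargetVector(target.values[te])),
    )


# ---------------------------------------------------------------------------
# Standardization

def standardize(
    train: OtuTable,
    others: list[OtuTable] | None = None,
    ddof: int = 0,
) -> tuple[list[OtuTable], StandardizationStats]:
    """Z-score taxa using statistics from the training table only.

    Returns ``[scaled_train, *scaled_others]`` and the fitted stats. Held-out
    tables are scaled with the training mean/sd — never with their own —
    matching the contract that all preprocessing is learned from training
    data. Constant training columns scale to all-zero columns.
    """
    others = others or []
    for other in others:
        if other.taxon_ids != train.taxon_ids:
            raise ValueError("taxon ids differ between tables")
    X = np.asarray(train.counts, dtype=float)
    stats = StandardizationStats(
        mean=X.mean(axis=0), sd=X.std(axis=0, ddof=ddof), ddof=ddof
    )
    scaled = []
    for t in [train, *others]:
        scaled.append(
            replace(
                t,
                counts=stats.transform(np.asarray(t.counts, dtype=float)),
                standardized=True,
            )
        )
    return scaled, stats
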