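"""Pre-model filters: missing-value filtering, redundant-site handling,
and the monophosphorylated subset used for enrichment analyses.

Phosphopeptides carrying more than one phosphate yield several site records
with exactly the same quantification vector.  To avoid biasing the multiple-
testing correction, such redundant rows are collapsed to one representative
before model fitting and the statistics are copied back to every group
member afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import QuantTable

__all__ = [
    "RedundancyMap",
    "filter_missing",
    "collapse_redundant",
    "expand_redundant",
    "monophospho_subset",
    "MAX_MISSING_PRESETS",
]

logger = logging.getLogger(__name__)

# paper-matched presets: tolerate at most one whole biological replicate
MAX_MISSING_PRESETS = {"mating": 10, "fusion": 5}


@dataclass
class RedundancyMap:
    """representative feature_id -> duplicate feature_ids (exact-value groups)."""

    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep, dups in self.groups.items():
            if rep in dups:
                raise ValueError(f"representative {rep!r} listed among its own duplicates")
            for d in dups:
                if d in seen or d in self.groups:
                    raise ValueError(f"duplicate feature {d!r} appears more than once")
                seen.add(d)

    @property
    def n_duplicates(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(rep, d) for rep, dups in self.groups.items() for d in dups]
        return pd.DataFrame(rows, columns=["representative", "duplicate"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RedundancyMap":
        groups: dict[str, list[str]] = {}
        for rep, dup in zip(df["representative"], df["duplicate"]):
            groups.setdefault(str(rep), []).append(str(dup))
        return cls(groups)


def filter_missing(table: QuantTable, max_missing: int) -> QuantTable:
    """Keep features with at most ``max_missing`` missing values.

    The published thresholds equal one whole biological replicate: 10 of 30
    for the mating design, 5 of 15 for the fusion design
    (``MAX_MISSING_PRESETS``).
    """
    n_samples = table.values.shape[1]
    if not 0 <= max_missing < n_samples:
        raise ValueError(f"max_missing must be in [0, {n_samples - 1}], got {max_missing}")
    n_missing = table.values.isna().sum(axis=1)
    keep = n_missing <= max_missing
    logger.info("filter_missing: kept %d of %d features (max_missing=%d)",
                int(keep.sum()), len(keep), max_missing)
    return table.subset(table.feature_ids[keep])


def collapse_redundant(table: QuantTable) -> tuple[QuantTable, RedundancyMap]:
    """Group features whose value vectors (including the missing pattern) are
    bit-identical; retain the lexicographically smallest feature_id of each
    group and return the mapping for post-hoc re-expansion."""
    vals = table.values
    # exact byte-level grouping: NaN patterns must match too
    key = pd.util.hash_pandas_object(
        vals.fillna(np.inf), index=False
    ).reset_index(drop=True)  # fast pre-grouping; exact equality verified within buckets
    groups: dict[str, list[str]] = {}
    drop: list[str] = []
    for _, idx in key.groupby(key).groups.items():
        if len(idx) < 2:
            continue
        block = vals.iloc[idx]
        arr = block.to_numpy()
        members = list(block.index)
        # partition bucket by exact equality (hash collisions are possible)
        remaining = list(range(len(members)))
        while remaining:
            i = remaining[0]
            same = [j for j in remaining
                    if np.array_equal(arr[i], arr[j], equal_nan=True)]
            if len(same) > 1:
                ids = sorted(members[j] for j in same)
                groups[ids[0]] = ids[1:]
                drop.extend(ids[1:])
            remaining = [j for j in remaining if j not in same]
    keep = [f for f in table.feature_ids if f not in set(drop)]
    rmap = RedundancyMap(groups)
    logger.info("collapse_redundant: %d features -> %d representatives (%d duplicates)",
                len(table.feature_ids), len(keep), rmap.n_duplicates)
    return table.subset(keep), rmap


def expand_redundant(stats: pd.DataFrame, rmap: RedundancyMap) -> pd.DataFrame:
    """Copy each representative's statistics to its duplicates (post-hoc
    re-addition).  ``stats`` is indexed by feature_id; the result covers the
    original feature universe."""
    missing = [rep for rep in rmap.groups if rep not in stats.index]
    if missing:
        raise ValueError(f"representatives absent from stats: {missing[:5]}")
    extra = []
    for rep, dups in rmap.groups.items():
        for d in dups:
            row = stats.loc[rep].copy()
            extra.append(pd.Series(row, name=d))
    if not extra:
        return stats.copy()
    out = pd.concat([stats, pd.DataFrame(extra)], axis=0)
    out.index.name = stats.index.name
    return out


def monophospho_subset(table: QuantTable) -> QuantTable:
    """Keep only sites detected on monophosphorylated peptides
    (multiplicity 1)."""
    mult = table.features["multiplicity"]
    bad = table.feature_ids[mult.isna()]
    if len(bad):
        raise ValueError(f"features without multiplicity annotation: {list(bad[:5])}")
    keep = table.feature_ids[(mult == 1).to_numpy(dtype=bool)]
    return table.subset(keep)
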