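"""Data model and I/O for wide quantitative (phospho)proteomics tables.

The central container is :class:`QuantTable`: a features x samples matrix of
log2 abundances with an explicit missing mask (NaN), feature annotations
(protein, residue, position, multiplicity, sequence window) and sample keys
(condition, time in minutes, biological replicate).  Samples are TMT channels
from a time-course design; one table holds one quantification layer
(proteome or phosphoproteome).

Sample columns are named ``<condition>_<time>min_R<replicate>``, e.g.
``mating_45min_R2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "SampleKey",
    "QuantTable",
    "read_quant_table",
    "write_quant_table",
    "log2_transform",
    "median_center_by_replicate",
    "pca_qc",
    "windows_from_fasta",
]

FEATURE_COLUMNS = ["feature_id", "protein_id", "residue", "position", "multiplicity", "window"]

_SAMPLE_RE = re.compile(r"^(?P<condition>[A-Za-z][A-Za-z0-9]*)_(?P<time>\d+)min_R(?P<replicate>[A-Za-z0-9]+)$")

WINDOW_LENGTH = 11
PAD_CHAR = "_"


@dataclass(frozen=True, order=True)
class SampleKey:
    """One TMT channel: (condition, time in minutes, biological replicate)."""

    condition: str
    time_min: int
    replicate: str

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.time_min}min_R{self.replicate}"

    @classmethod
    def parse(cls, name: str) -> "SampleKey":
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(
                f"sample header {name!r} does not match the pattern "
                "'<condition>_<time>min_R<replicate>' (e.g. 'mating_45min_R2')"
            )
        return cls(m.group("condition"), int(m.group("time")), m.group("replicate"))


@dataclass
class QuantTable:
    """Features x samples matrix of log2 abundances with missing mask.

    Parameters
    ----------
    values:
        DataFrame indexed by feature_id, one column per sample (canonical
        sample names); missing entries are NaN.
    features:
        Feature metadata indexed by feature_id, aligned with ``values``;
        columns ``protein_id``, ``residue``, ``position``, ``multiplicity``,
        ``window`` (proteome rows carry NA residue/position/window).
    """

    values: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.features.index):
            raise ValueError("values and features must be indexed by the same feature_ids")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature_id(s): {dups[:5]}")
        keys = [SampleKey.parse(c) for c in self.values.columns]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (condition, time, replicate) sample keys")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite (inf) values present; missing data must be NaN")
        win = self.features.get("window")
        if win is not None and win.notna().any():
            strs = win.dropna().astype(str)
            bad = strs.loc[strs.str.len() != WINDOW_LENGTH]
            if len(bad):
                raise ValueError(f"windows must have length {WINDOW_LENGTH}: {bad.index[:5].tolist()}")

    # -- convenience -----------------------------------------------------
    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey.parse(c) for c in self.values.columns]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def sample_frame(self) -> pd.DataFrame:
        """Sample annotations as a DataFrame indexed by column name."""
        keys = self.sample_keys
        return pd.DataFrame(
            {
                "condition": [k.condition for k in keys],
                "time_min": [k.time_min for k in keys],
                "replicate": [k.replicate for k in keys],
            },
            index=self.values.columns,
        )

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.features.copy())

    def subset(self, feature_ids: Iterable[str]) -> "QuantTable":
        idx = pd.Index(feature_ids)
        return QuantTable(self.values.loc[idx], self.features.loc[idx])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_quant_table(path: str | Path, dialect: str = "tsv", sheet: str | int = 0) -> QuantTable:
    """Read a wide quantification table.

    ``tsv``: UTF-8 tab-separated, ``NA`` (or empty) for missing, feature
    metadata columns first, then one column per sample named by the canonical
    pattern.  ``supplementary_xlsx``: the published supplementary layout with
    per-replicate columns followed by per-condition average columns; only the
    replicate columns (those whose header parses as a sample key) are loaded,
    averages are recomputed downstream rather than trusted.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"feature_id": str}, na_values=["NA"], keep_default_na=True)
    elif dialect == "supplementary_xlsx":
        df = pd.read_excel(path, sheet_name=sheet, na_values=["NA"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_table(df, dialect=dialect)


def _frame_to_table(df: pd.DataFrame, dialect: str) -> QuantTable:
    if "feature_id" not in df.columns:
        raise ValueError("table must contain a 'feature_id' column")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature_id(s): {dups[:5]}")

    sample_cols, meta_cols = [], []
    for col in df.columns:
        if col in FEATURE_COLUMNS:
            meta_cols.append(col)
            continue
        try:
            SampleKey.parse(str(col))
            sample_cols.append(col)
        except ValueError:
            if dialect == "supplementary_xlsx":
                # average / annotation columns in the supplementary layout
                continue
            raise ValueError(f"unparseable sample header {col!r}") from None
    if not sample_cols:
        raise ValueError("no sample columns found")

    feats = pd.DataFrame(index=pd.Index(df["feature_id"].astype(str), name="feature_id"))
    for col in FEATURE_COLUMNS[1:]:
        if col in df.columns:
            if col in ("protein_id", "residue", "window"):
                feats[col] = df[col].astype(object).where(pd.notna(df[col]), pd.NA).to_numpy()
            else:
                feats[col] = df[col].to_numpy()
        else:
            feats[col] = pd.NA
    if "position" in feats:
        feats["position"] = pd.array(feats["position"], dtype="Int64")
    if "multiplicity" in feats:
        feats["multiplicity"] = pd.array(feats["multiplicity"], dtype="Int64")

    values = df[sample_cols].astype(float)
    values.index = feats.index
    values.columns = [SampleKey.parse(str(c)).name for c in sample_cols]
    return QuantTable(values, feats)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write the wide TSV dialect (``NA`` for missing)."""
    out = table.features.reset_index()
    out = pd.concat([out, table.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log2_transform(table: QuantTable, pseudocount: float = 0.0) -> QuantTable:
    """log2(value + pseudocount); masked entries stay masked."""
    vals = table.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if (vals[obs] < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    with np.errstate(divide="ignore"):
        out = np.where(obs, np.log2(vals + pseudocount), np.nan)
    if np.isneginf(out[obs]).any():
        raise ValueError("log2 of zero; use a positive pseudocount")
    return QuantTable(pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
                      table.features.copy())


def median_center_by_replicate(table: QuantTable) -> QuantTable:
    """Subtract, per feature and per replicate, the median over all of that
    replicate's time points (all conditions pooled).

    This removes per-replicate batch offsets exactly: after centering, every
    feature's median within every replicate is zero.  Features entirely
    missing within a replicate are left untouched there.
    """
    samples = table.sample_frame()
    vals = table.values.copy()
    for _, cols in samples.groupby("replicate").groups.items():
        block = vals[cols]
        med = block.median(axis=1, skipna=True)  # NaN when all missing
        vals[cols] = block.sub(med.fillna(0.0), axis=0)
    return QuantTable(vals, table.features.copy())


def pca_qc(table: QuantTable, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on complete-case features (no imputation).

    Returns (scores, explained_variance_ratio).  ``scores`` is indexed by
    sample name with columns ``PC1..PCn``; features are mean-centered across
    samples; components are ordered by decreasing explained variance.
    """
    if table.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    complete = table.values.dropna(axis=0)
    if complete.shape[0] < n_components:
        raise ValueError(
            f"only {complete.shape[0]} complete-case features; need >= n_components={n_components}"
        )
    X = complete.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=table.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Sequence windows
# ---------------------------------------------------------------------------

def windows_from_fasta(features: pd.DataFrame, fasta_path: str | Path) -> pd.Series:
    """Derive +/-5-residue windows around each phosphosite from protein FASTA.

    Termini are padded with ``_`` so every window has length 11 and the
    phosphoresidue sits at the center.  Raises if the annotated residue does
    not match the sequence.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = {}
    for fid, row in features.iterrows():
        prot, pos, residue = row["protein_id"], row["position"], row["residue"]
        if pd.isna(pos) or prot not in seqs:
            out[fid] = pd.NA
            continue
        seq = seqs[prot]
        i = int(pos) - 1  # 1-based residue index
        if i < 0 or i >= len(seq):
            raise ValueError(f"{fid}: position {pos} outside protein {prot} (length {len(seq)})")
        if not pd.isna(residue) and seq[i] != residue:
            raise ValueError(f"{fid}: sequence has {seq[i]} at position {pos}, annotation says {residue}")
        lo, hi = i - 5, i + 6
        window = (PAD_CHAR * max(0, -lo)) + seq[max(0, lo):min(len(seq), hi)] + (PAD_CHAR * max(0, hi - len(seq)))
        out[fid] = window
    return pd.Series(out, name="window")
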