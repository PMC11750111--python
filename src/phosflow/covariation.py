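"""Phosphosite-protein covariation analysis.

A phosphosite whose abundance change merely mirrors its parent protein's
abundance change is not a regulatory phosphorylation event.  For each
significant site with protein-level data, log2 fold changes of both layers
(relative to each replicate's t = 0 sample) are pooled into one multiple
linear regression

    delta = b0 + b1 * layer + b2 * time + b3 * layer x time

where ``layer`` is 0 for the protein series and 1 for the phosphosite
series.  The interaction coefficient b3 is the difference in slope between
the two layers (log2 units per minute); its two-sided t-test p-value,
BH-adjusted across tested sites, decides the call: adjusted p above alpha
means the site co-varies with its protein, at or below alpha it changes
independently.  Sites whose protein shows no significant change are called
independent without testing, and sites without protein data cannot be
tested at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diff_model import bh_adjust
from .tables_io import QuantTable

__all__ = [
    "CovariationResult",
    "fold_changes",
    "covariation_test",
    "classify_covariation",
    "covariation_analysis",
]

logger = logging.getLogger(__name__)

LABELS = ("covarying", "independent", "independent_no_protein_change", "no_protein_data")


@dataclass
class CovariationResult:
    """Per-site interaction estimate and call."""

    feature_id: str
    interaction: float | None  # slope difference, log2 units per minute
    p: float | None
    adj_p: float | None
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label in ("independent_no_protein_change", "no_protein_data") and self.p is not None:
            raise ValueError(f"label {self.label} cannot carry a p-value")


def fold_changes(table: QuantTable, baseline_time: int = 0,
                 correct_against: str | None = None) -> pd.DataFrame:
    """Per-replicate log2 fold changes against the replicate's baseline sample.

    Returns a long DataFrame (feature_id, condition, time_min, replicate,
    delta); the baseline delta is 0 by construction and deltas are missing
    wherever either endpoint is missing.  A replicate lacking its baseline
    sample is dropped for that feature.  With ``correct_against`` set (e.g.
    the starvation control), deltas of that condition are subtracted from the
    matching (time, replicate) deltas of every other condition and only the
    corrected conditions are returned.
    """
    samples = table.sample_frame()
    if baseline_time not in set(samples["time_min"]):
        raise ValueError(f"baseline time {baseline_time} not present in table")
    rows = []
    for (condition, replicate), cols in samples.groupby(["condition", "replicate"]).groups.items():
        sub = samples.loc[cols].sort_values("time_min")
        base_col = sub.index[sub["time_min"] == baseline_time]
        if len(base_col) == 0:
            logger.info("fold_changes: replicate %s/%s lacks baseline, dropped", condition, replicate)
            continue
        base = table.values[base_col[0]]
        for col, t in zip(sub.index, sub["time_min"]):
            delta = table.values[col] - base
            rows.append(pd.DataFrame({
                "feature_id": table.feature_ids,
                "condition": condition,
                "time_min": int(t),
                "replicate": replicate,
                "delta": delta.to_numpy(),
            }))
    long = pd.concat(rows, ignore_index=True)
    if correct_against is not None:
        ctrl = long[long["condition"] == correct_against]
        rest = long[long["condition"] != correct_against]
        merged = rest.merge(
            ctrl[["feature_id", "time_min", "replicate", "delta"]],
            on=["feature_id", "time_min", "replicate"], suffixes=("", "_ctrl"),
        )
        merged["delta"] = merged["delta"] - merged["delta_ctrl"]
        long = merged.drop(columns="delta_ctrl")
    return long.dropna(subset=["delta"]).reset_index(drop=True)


def covariation_test(protein_deltas: pd.DataFrame, phospho_deltas: pd.DataFrame
                     ) -> tuple[float, float] | None:
    """Interaction slope b3 and its two-sided p for one site.

    Inputs are long frames with columns (time_min, delta) of replicate-level
    points.  Requires at least 3 distinct time points with data in each
    layer; returns None when the fit is not possible.
    """
    if protein_deltas["time_min"].nunique() < 3 or phospho_deltas["time_min"].nunique() < 3:
        return None
    t = np.concatenate([protein_deltas["time_min"].to_numpy(float),
                        phospho_deltas["time_min"].to_numpy(float)])
    y = np.concatenate([protein_deltas["delta"].to_numpy(float),
                        phospho_deltas["delta"].to_numpy(float)])
    layer = np.concatenate([np.zeros(len(protein_deltas)), np.ones(len(phospho_deltas))])
    X = sm.add_constant(np.column_stack([layer, t, layer * t]))
    if len(y) <= X.shape[1]:
        return None
    res = sm.OLS(y, X).fit()
    b3 = float(res.params[3])
    p = float(res.pvalues[3])
    if res.ssr <= 1e-12 * max(1.0, float(y @ y)):
        # perfect fit: the t statistic degenerates; the slope difference is
        # exact, so p collapses to 0 (reported below machine resolution)
        p = 0.0 if abs(b3) > 1e-12 else 1.0
    return b3, p


def classify_covariation(phospho_deltas: pd.DataFrame, protein_deltas: pd.DataFrame,
                         site_protein: pd.Series, protein_significant: pd.Series,
                         alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Run the interaction test for every site and label the outcome.

    ``site_protein`` maps feature_id -> protein_id for the sites under test;
    ``protein_significant`` is a boolean Series over protein_ids.  Sites of
    non-significant proteins are ``independent_no_protein_change`` without a
    test; sites of proteins absent from the protein layer are
    ``no_protein_data``.  Interaction p-values are BH-adjusted over the
    tested sites only.

    Returns (results, summary); summary reports the fraction of independent
    sites under two denominator conventions: over sites with any protein
    information (no-protein-change counts as independent, per the decision
    rule) and over tested sites only.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    prot_groups = {k: g for k, g in protein_deltas.groupby("feature_id")}
    phos_groups = {k: g for k, g in phospho_deltas.groupby("feature_id")}
    records = []
    for fid, prot in site_protein.items():
        if prot not in prot_groups:
            records.append((fid, np.nan, np.nan, "no_protein_data"))
            continue
        if not bool(protein_significant.get(prot, False)):
            records.append((fid, np.nan, np.nan, "independent_no_protein_change"))
            continue
        if fid not in phos_groups:
            records.append((fid, np.nan, np.nan, "no_protein_data"))
            continue
        fit = covariation_test(prot_groups[prot], phos_groups[fid])
        if fit is None:
            records.append((fid, np.nan, np.nan, "no_protein_data"))
        else:
            records.append((fid, fit[0], fit[1], "tested"))
    res = pd.DataFrame(records, columns=["feature_id", "interaction", "p", "label"]
                       ).set_index("feature_id")
    tested = res["label"] == "tested"
    res["adj_p"] = np.nan
    res.loc[tested, "adj_p"] = bh_adjust(res.loc[tested, "p"])
    res.loc[tested, "label"] = np.where(res.loc[tested, "adj_p"] > alpha,
                                        "covarying", "independent")

    n_indep = int(res["label"].isin(["independent", "independent_no_protein_change"]).sum())
    n_with_info = int((res["label"] != "no_protein_data").sum())
    n_tested = int(tested.sum())
    n_indep_tested = int((res.loc[tested.to_numpy(), "label"] == "independent").sum())
    summary = {
        "alpha": alpha,
        "n_sites": len(res),
        "n_tested": n_tested,
        "n_no_protein_data": int((res["label"] == "no_protein_data").sum()),
        "pct_independent": 100.0 * n_indep / n_with_info if n_with_info else None,
        "pct_independent_tested_only": 100.0 * n_indep_tested / n_tested if n_tested else None,
    }
    return res, summary


def covariation_analysis(phospho: QuantTable, proteome: QuantTable,
                         site_ids: pd.Index, protein_significant: pd.Series,
                         alpha: float = 0.05, baseline_time: int = 0,
                         correct_against: str | None = None,
                         condition: str | None = None) -> tuple[pd.DataFrame, dict]:
    """End-to-end covariation stage for a set of significant phosphosites.

    Computes per-replicate fold changes in both layers and classifies every
    site in ``site_ids``.  For a starvation analysis pass
    ``condition='control'`` to restrict both layers to the control samples;
    for the corrected mating analysis pass ``correct_against='control'`` so
    starvation dynamics are subtracted before the interaction test.
    """
    phos_fc = fold_changes(phospho.subset(site_ids), baseline_time, correct_against)
    prot_fc = fold_changes(proteome, baseline_time, correct_against)
    if condition is not None:
        phos_fc = phos_fc[phos_fc["condition"] == condition]
        prot_fc = prot_fc[prot_fc["condition"] == condition]
        if phos_fc.empty or prot_fc.empty:
            raise ValueError(f"condition {condition!r} not present in the tables")
    site_protein = phospho.features.loc[site_ids, "protein_id"]
    return classify_covariation(phos_fc, prot_fc, site_protein, protein_significant, alpha)
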