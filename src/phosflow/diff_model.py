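"""Per-feature moderated linear models for TMT time courses.

Each feature (phosphosite or protein) is fit with a group-means model: one
coefficient per (condition, time) design cell, estimated on the feature's
non-missing samples.  Residual variances are shrunk toward a common prior by
empirical Bayes (the limma model): s2 ~ s0^2 * F(d, d0), giving the
posterior variance

    s2_tilde = (d0 * s0^2 + d * s2) / (d0 + d)

with (d0, s0^2) estimated by moment-matching on log s2.  Significance of a
named contrast set is a joint moderated F over its contrasts (accounting for
their correlation), with Benjamini-Hochberg control of the FDR across
features.

Built-in contrast sets follow the time-course design: stepwise changes in
the starvation control (Ctrl_45-0 ... Ctrl_180-135), starvation-corrected
differences-of-differences for mating
(Diff_45-0 = (Mating.45-Mating.0) - (Ctrl.45-Ctrl.0), ...), and stepwise
changes for the fusion course (Diff_11-0 ... Diff_44-33).  The correction
removes signal shared with the starvation-only control so that only
pheromone-specific dynamics remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .site_processing import (MAX_MISSING_PRESETS, RedundancyMap,
                              collapse_redundant, expand_redundant, filter_missing)
from .tables_io import QuantTable, median_center_by_replicate

__all__ = [
    "DesignSpec",
    "ContrastSet",
    "ModerationParams",
    "GroupFit",
    "ContrastFit",
    "fit_groups",
    "apply_contrasts",
    "ebayes_moderate",
    "moderated_F",
    "bh_adjust",
    "classify_sites",
    "cluster_profiles",
    "run_pipeline",
    "stepwise_contrasts",
    "corrected_contrasts",
    "PRESET_ALPHAS",
]

logger = logging.getLogger(__name__)

PRESET_ALPHAS = {"mating": 0.05, "fusion": 0.001}

Cell = tuple[str, int]  # (condition, time_min)


@dataclass(frozen=True)
class DesignSpec:
    """Group-means design: one cell per (condition, time)."""

    cells: tuple[Cell, ...]

    @classmethod
    def from_table(cls, table: QuantTable) -> "DesignSpec":
        samples = table.sample_frame()
        cells = sorted({(c, int(t)) for c, t in zip(samples["condition"], samples["time_min"])})
        return cls(tuple(cells))

    def cell_of_sample(self, table: QuantTable) -> pd.Series:
        samples = table.sample_frame()
        mapping = {c: i for i, c in enumerate(self.cells)}
        idx = [mapping[(c, int(t))] for c, t in zip(samples["condition"], samples["time_min"])]
        return pd.Series(idx, index=samples.index)


@dataclass(frozen=True)
class ContrastSet:
    """Named contrast vectors over design cells; every vector sums to zero."""

    name: str
    contrast_names: tuple[str, ...]
    matrix: np.ndarray  # k x n_cells
    cells: tuple[Cell, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.contrast_names), len(self.cells)):
            raise ValueError("contrast matrix shape mismatch")
        if not np.allclose(self.matrix.sum(axis=1), 0.0):
            raise ValueError("every contrast vector must sum to zero over cells")


def stepwise_contrasts(design: DesignSpec, condition: str, prefix: str = "Ctrl",
                       name: str | None = None) -> ContrastSet:
    """Consecutive time differences within one condition,
    e.g. Ctrl_45-0 = Ctrl.45min - Ctrl.0min."""
    times = sorted(t for c, t in design.cells if c == condition)
    if len(times) < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 time points")
    k = len(times) - 1
    L = np.zeros((k, len(design.cells)))
    names = []
    cell_idx = {c: i for i, c in enumerate(design.cells)}
    for i in range(k):
        L[i, cell_idx[(condition, times[i + 1])]] = 1.0
        L[i, cell_idx[(condition, times[i])]] = -1.0
        names.append(f"{prefix}_{times[i + 1]}-{times[i]}")
    return ContrastSet(name or prefix.lower(), tuple(names), L, design.cells)


def corrected_contrasts(design: DesignSpec, treated: str = "mating", control: str = "control",
                        prefix: str = "Diff", name: str = "mating") -> ContrastSet:
    """Starvation-corrected differences-of-differences, e.g.
    Diff_45-0 = (Mating.45min - Mating.0min) - (Ctrl.45min - Ctrl.0min)."""
    times = sorted(t for c, t in design.cells if c == treated)
    if times != sorted(t for c, t in design.cells if c == control):
        raise ValueError("treated and control conditions must share time points")
    if len(times) < 2:
        raise ValueError("need at least 2 time points")
    k = len(times) - 1
    L = np.zeros((k, len(design.cells)))
    names = []
    cell_idx = {c: i for i, c in enumerate(design.cells)}
    for i in range(k):
        L[i, cell_idx[(treated, times[i + 1])]] = 1.0
        L[i, cell_idx[(treated, times[i])]] = -1.0
        L[i, cell_idx[(control, times[i + 1])]] = -1.0
        L[i, cell_idx[(control, times[i])]] = 1.0
        names.append(f"{prefix}_{times[i + 1]}-{times[i]}")
    return ContrastSet(name, tuple(names), L, design.cells)


# ---------------------------------------------------------------------------
# Group-means fit
# ---------------------------------------------------------------------------

@dataclass
class GroupFit:
    design: DesignSpec
    cell_means: pd.DataFrame   # features x cells (NaN for unobserved cells)
    cell_counts: pd.DataFrame  # features x cells (ints)
    s2: pd.Series              # residual variance (NaN when df = 0)
    df: pd.Series              # residual degrees of freedom


def fit_groups(table: QuantTable, design: DesignSpec | None = None) -> GroupFit:
    """Least-squares cell means on available samples per feature.

    residual df = n_obs - n_observed_cells; features with df = 0 get NaN
    residual variance and are excluded from the empirical-Bayes moment
    estimation (they still receive a shrunken variance, fully determined by
    the prior).
    """
    if design is None:
        design = DesignSpec.from_table(table)
    cell_idx = design.cell_of_sample(table)
    vals = table.values.to_numpy(dtype=float)
    n_feat = vals.shape[0]
    n_cells = len(design.cells)
    means = np.full((n_feat, n_cells), np.nan)
    counts = np.zeros((n_feat, n_cells), dtype=int)
    rss = np.zeros(n_feat)
    for j in range(n_cells):
        cols = np.flatnonzero(cell_idx.to_numpy() == j)
        if cols.size == 0:
            continue
        block = vals[:, cols]
        obs = ~np.isnan(block)
        n = obs.sum(axis=1)
        counts[:, j] = n
        with np.errstate(invalid="ignore"):
            m = np.nansum(block, axis=1) / np.where(n > 0, n, np.nan)
        means[:, j] = m
        dev = np.where(obs, block - m[:, None], 0.0)
        rss += np.nansum(dev ** 2, axis=1)
    n_obs = counts.sum(axis=1)
    n_cells_obs = (counts > 0).sum(axis=1)
    df = n_obs - n_cells_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.where(df > 0, df, 1), np.nan)
    cols = pd.Index([f"{c}.{t}min" for c, t in design.cells])
    fid = table.feature_ids
    n_zero = int((df == 0).sum())
    if n_zero:
        logger.info("fit_groups: %d features with zero residual df", n_zero)
    return GroupFit(
        design,
        pd.DataFrame(means, index=fid, columns=cols),
        pd.DataFrame(counts, index=fid, columns=cols),
        pd.Series(s2, index=fid, name="s2"),
        pd.Series(df.astype(float), index=fid, name="df"),
    )


@dataclass
class ContrastFit:
    contrasts: ContrastSet
    estimates: pd.DataFrame  # features x k (NaN for undefined contrasts)
    defined: pd.DataFrame    # features x k bool: all touched cells observed
    cell_counts: pd.DataFrame


def apply_contrasts(fit: GroupFit, contrasts: ContrastSet) -> ContrastFit:
    """Contrast estimates = L . cell_means.

    A contrast is undefined for a feature when any cell it touches has no
    observation; such features are excluded from that contrast only.
    """
    if contrasts.cells != fit.design.cells:
        raise ValueError("contrast set was built for a different design")
    L = contrasts.matrix
    means = fit.cell_means.to_numpy()
    counts = fit.cell_counts.to_numpy()
    touched = L != 0.0  # k x cells
    defined = ~((counts == 0)[:, None, :] & touched[None, :, :]).any(axis=2)
    est = np.where(defined, np.nan_to_num(means) @ L.T, np.nan)
    n_undef = int((~defined).any(axis=1).sum())
    if n_undef:
        logger.info("apply_contrasts[%s]: %d features with >=1 undefined contrast",
                    contrasts.name, n_undef)
    return ContrastFit(
        contrasts,
        pd.DataFrame(est, index=fit.cell_means.index, columns=list(contrasts.contrast_names)),
        pd.DataFrame(defined, index=fit.cell_means.index, columns=list(contrasts.contrast_names)),
        fit.cell_counts,
    )


# ---------------------------------------------------------------------------
# Empirical Bayes moderation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModerationParams:
    """Prior df d0 (possibly inf) and prior variance s0^2 in (log2 units)^2."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s02 > 0):
            raise ValueError("d0 and s0^2 must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def posterior_variance(s2: np.ndarray | float, df: np.ndarray | float,
                       params: ModerationParams) -> np.ndarray | float:
    """Shrunken variance (d0*s0^2 + d*s2) / (d0 + d); equals s0^2 when d0 is
    infinite."""
    if np.isinf(params.d0):
        return np.full_like(np.asarray(s2, dtype=float), params.s02) if np.ndim(s2) else params.s02
    return (params.d0 * params.s02 + np.asarray(df, dtype=float) * np.asarray(s2, dtype=float)) \
        / (params.d0 + np.asarray(df, dtype=float))


def ebayes_moderate(s2: pd.Series, df: pd.Series) -> tuple[ModerationParams, pd.Series]:
    """Estimate (d0, s0^2) by moment-matching of log s2 against a scaled F
    distribution and return the shrunken variances.

    Under the hierarchical model s2 | sigma2 ~ sigma2 * chi2_d / d and
    1/sigma2 ~ chi2_d0 / (d0 s0^2):  E[log s2] and Var[log s2] have closed
    forms in digamma/trigamma, inverted here (no variance trend, no
    robustification).  d0 may come out infinite, in which case every
    shrunken variance equals s0^2.
    """
    s2v = s2.to_numpy(dtype=float)
    dfv = df.to_numpy(dtype=float)
    ok = np.isfinite(s2v) & (dfv > 0) & (s2v > 0)
    if np.nanmax(np.where(np.isfinite(s2v), s2v, 0.0), initial=0.0) == 0.0:
        raise ValueError("all residual variances are zero: input looks noiseless")
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 features with positive residual df and variance, have {int(ok.sum())}")
    z = np.log(s2v[ok])
    d = dfv[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0, s02 = np.inf, float(np.exp(emean))
    params = ModerationParams(d0, s02)
    dfz = np.where(np.isfinite(dfv), dfv, 0.0)
    s2z = np.where(np.isfinite(s2v), s2v, 0.0)
    post = posterior_variance(s2z, dfz, params)
    return params, pd.Series(np.asarray(post, dtype=float), index=s2.index, name="s2_post")


# ---------------------------------------------------------------------------
# Moderated F
# ---------------------------------------------------------------------------

def moderated_F(cfit: ContrastFit, s2_post: pd.Series, params: ModerationParams,
                df_resid: pd.Series) -> pd.DataFrame:
    """Joint moderated F over the defined contrasts of each feature.

    F = b' C^-1 b / (k_eff * s2_tilde) with C = L diag(1/n_cell) L' built
    from the feature's per-cell replicate counts, so correlation between
    consecutive-difference contrasts is accounted for.  p is the upper tail
    of F(k_eff, d0 + d).  Features with no defined contrast get NaN.
    """
    L_full = cfit.contrasts.matrix
    est = cfit.estimates.to_numpy()
    defined = cfit.defined.to_numpy()
    counts = cfit.cell_counts.to_numpy().astype(float)
    s2p = s2_post.reindex(cfit.estimates.index).to_numpy(dtype=float)
    dres = df_resid.reindex(cfit.estimates.index).to_numpy(dtype=float)
    n_feat = est.shape[0]
    F = np.full(n_feat, np.nan)
    k_eff = defined.sum(axis=1)

    # group features by (defined pattern, relevant cell counts) to reuse C^-1
    touched_any = (L_full != 0.0).any(axis=0)
    sig = [
        (tuple(defined[i]), tuple(counts[i, touched_any]))
        for i in range(n_feat)
    ]
    sig_arr = pd.Series(sig)
    for _, idx in sig_arr.groupby(sig_arr).groups.items():
        rows = np.asarray(idx)
        dmask = defined[rows[0]]
        if not dmask.any():
            continue
        L = L_full[dmask]
        n = counts[rows[0]]
        # defined contrasts only touch cells with n > 0
        C = (L / np.where(n > 0, n, 1.0)) @ L.T
        Ci = np.linalg.inv(C)
        b = est[np.ix_(rows, np.flatnonzero(dmask))]
        F[rows] = np.einsum("ij,jk,ik->i", b, Ci, b) / dmask.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        F = F / s2p
    df_total = dres + (0.0 if np.isinf(params.d0) else params.d0)
    if np.isinf(params.d0):
        df_total = np.full(n_feat, np.inf)
    p = np.full(n_feat, np.nan)
    ok = np.isfinite(F) & (k_eff > 0)
    finite_df = ok & np.isfinite(df_total)
    p[finite_df] = stats.f.sf(F[finite_df], k_eff[finite_df], df_total[finite_df])
    inf_df = ok & ~np.isfinite(df_total)
    p[inf_df] = stats.chi2.sf(F[inf_df] * k_eff[inf_df], k_eff[inf_df])
    return pd.DataFrame({"F": F, "p": p, "k": k_eff}, index=cfit.estimates.index)


def bh_adjust(pvals: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the number of tests m and returned as
    NaN; results are monotone in the input order statistics, capped at 1,
    and independent of input ordering.
    """
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    p = arr[ok]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    if m:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index, name="adj_p")
    return out


# ---------------------------------------------------------------------------
# Classification and clustering
# ---------------------------------------------------------------------------

def classify_sites(mating_adj_p: pd.Series, starvation_adj_p: pd.Series,
                   alpha_mating: float = 0.05, alpha_starvation: float = 0.05) -> pd.Series:
    """Split sites into ns / starvation_only / mating_specific /
    both_different from the two adjusted p-value tracks.

    A site significant on the corrected (Diff) contrasts is mating-specific
    unless it is also significant on the starvation (Ctrl) contrasts, in
    which case it changes in both conditions but differently.
    """
    if not mating_adj_p.index.equals(starvation_adj_p.index):
        raise ValueError("mating and starvation statistics cover different feature universes")
    m_sig = (mating_adj_p <= alpha_mating).fillna(False)
    s_sig = (starvation_adj_p <= alpha_starvation).fillna(False)
    labels = np.where(
        m_sig & s_sig, "both_different",
        np.where(m_sig, "mating_specific", np.where(s_sig, "starvation_only", "ns")),
    )
    return pd.Series(labels, index=mating_adj_p.index, name="class")


def cluster_profiles(profiles: pd.DataFrame, k: int = 2) -> pd.Series:
    """Monotone clusters from replicate-averaged (corrected) profiles.

    k=2: sign of the net change (last - first) -> increase / decrease.
    k=3: decrease; early_increase when at least half the net increase is
    reached by the second time point; late_increase otherwise.  An exactly
    zero net change goes to the increasing cluster (logged).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    prof = profiles.to_numpy(dtype=float)
    net = prof[:, -1] - prof[:, 0]
    ties = int((net == 0).sum())
    if ties:
        logger.info("cluster_profiles: %d exact zero net changes assigned to 'increase'", ties)
    if k == 2:
        labels = np.where(net < 0, "decrease", "increase")
    else:
        early = (prof[:, 1] - prof[:, 0]) >= 0.5 * net
        labels = np.where(net < 0, "decrease", np.where(early, "early_increase", "late_increase"))
    return pd.Series(labels, index=profiles.index, name="cluster")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(table: QuantTable, preset: str = "mating",
                 alpha: float | None = None, alpha_starvation: float = 0.05,
                 normalize: bool = True, max_missing: int | None = None,
                 conditions: Mapping[str, str] | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Full per-site analysis: normalize -> filter -> collapse -> fit ->
    moderate -> adjust -> expand -> classify -> cluster.

    preset ``mating``: two-condition design; stepwise starvation contrasts on
    the control cells plus starvation-corrected Diff contrasts, BH at 0.05.
    preset ``fusion``: single-condition stepwise contrasts, BH at 0.001
    (four replicates afford the stricter threshold), 3-way clusters.

    Returns (per-site results indexed by feature_id, summary dict).
    """
    if preset not in PRESET_ALPHAS:
        raise ValueError(f"preset must be one of {sorted(PRESET_ALPHAS)}")
    alpha = PRESET_ALPHAS[preset] if alpha is None else alpha
    cond = {"control": "control", "treated": "mating", "fusion": "fusion"}
    if conditions:
        cond.update(conditions)

    work = median_center_by_replicate(table) if normalize else table
    if max_missing is None:
        max_missing = MAX_MISSING_PRESETS[preset]
    n_input = len(work.feature_ids)
    work = filter_missing(work, max_missing)
    n_filtered = len(work.feature_ids)
    work, rmap = collapse_redundant(work)
    n_collapsed = len(work.feature_ids)

    design = DesignSpec.from_table(work)
    fit = fit_groups(work, design)
    params, s2_post = ebayes_moderate(fit.s2, fit.df)

    if preset == "mating":
        sets = {
            "starvation": stepwise_contrasts(design, cond["control"], prefix="Ctrl", name="starvation"),
            "mating": corrected_contrasts(design, cond["treated"], cond["control"]),
        }
    else:
        sets = {"fusion": stepwise_contrasts(design, cond["fusion"], prefix="Diff", name="fusion")}

    results = pd.DataFrame(index=fit.cell_means.index)
    for name, cset in sets.items():
        cfit = apply_contrasts(fit, cset)
        stat = moderated_F(cfit, s2_post, params, fit.df)
        adj = bh_adjust(stat["p"])
        counts = fit.cell_counts.to_numpy(dtype=float)
        for ci, cname in enumerate(cset.contrast_names):
            results[cname] = cfit.estimates[cname]
            # per-contrast moderated t for inspection
            L = cset.matrix[ci]
            unscaled = (L ** 2 / np.where(counts > 0, counts, np.nan)).sum(axis=1)
            results[f"t_{cname}"] = cfit.estimates[cname] / np.sqrt(
                s2_post.to_numpy() * unscaled)
        results[f"F_{name}"] = stat["F"]
        results[f"p_{name}"] = stat["p"]
        results[f"adj_p_{name}"] = adj

    n_sig_collapsed = {
        name: int((results[f"adj_p_{name}"] <= alpha).sum()) for name in sets
    }
    results = expand_redundant(results, rmap)

    # classification
    if preset == "mating":
        results["class"] = classify_sites(results["adj_p_mating"], results["adj_p_starvation"],
                                          alpha, alpha_starvation)
    else:
        sig = (results["adj_p_fusion"] <= alpha).fillna(False)
        results["class"] = np.where(sig, "fusion_significant", "ns")
    # clusters on the (corrected) mean profiles of significant sites
    means_exp = expand_redundant(fit.cell_means, rmap)
    if preset == "mating":
        tcols_t = [c for c in means_exp.columns if c.startswith(f"{cond['treated']}.")]
        tcols_c = [c for c in means_exp.columns if c.startswith(f"{cond['control']}.")]
        corrected = means_exp[tcols_t].to_numpy() - means_exp[tcols_c].to_numpy()
        prof = pd.DataFrame(corrected, index=means_exp.index,
                            columns=[c.split(".", 1)[1] for c in tcols_t])
        sig_mask = results["class"].isin(["mating_specific", "both_different"])
        k = 2
    else:
        fcols = [c for c in means_exp.columns if c.startswith(f"{cond['fusion']}.")]
        prof = means_exp[fcols].rename(columns=lambda c: c.split(".", 1)[1])
        sig_mask = results["class"] == "fusion_significant"
        k = 3
    results["cluster"] = pd.NA
    if sig_mask.any():
        results.loc[sig_mask, "cluster"] = cluster_profiles(prof.loc[sig_mask], k=k)

    results.index.name = "feature_id"
    summary = {
        "preset": preset,
        "alpha": alpha,
        "n_input": n_input,
        "n_after_missing_filter": n_filtered,
        "n_representatives": n_collapsed,
        "n_duplicates": rmap.n_duplicates,
        "d0": params.d0,
        "s02": params.s02,
        "n_significant_collapsed": n_sig_collapsed,
        "n_significant_expanded": {
            name: int((results[f"adj_p_{name}"] <= alpha).sum()) for name in sets
        },
        "class_counts": results["class"].value_counts().to_dict(),
    }
    return results, summary
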