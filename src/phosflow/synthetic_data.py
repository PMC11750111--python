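"""Synthetic (proteome, phosphoproteome, truth) generator.

Emulates the statistical structure of a TMT time-course experiment in which
mating fission-yeast cells are compared with cells starved in the absence of
a partner: per-replicate batch offsets, four planted effect classes
(null / starvation-only / mating-specific / both-but-different),
phosphosite-protein coupling, MCAR missingness plus whole-replicate dropout,
redundant site groups with bit-identical quantification, planted
kinase-substrate sets, and +/-5-residue sequence windows with an optional
planted motif.

Planted temporal profiles are monotone and switch-like: flat, then a linear
transition across one uniformly chosen inter-sample interval, then flat at
the full effect size.  One global seed drives a hierarchy of independent
sub-streams (profiles, noise, missingness, redundancy, kinase sets, windows)
so each layer is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import QuantTable, SampleKey, WINDOW_LENGTH

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_experiment",
    "simulate_windows",
    "mating_config",
    "fusion_config",
]

CLASSES = ("null", "starvation_only", "mating_specific", "both_different")

# Residue alphabet and a smooth, roughly yeast-like background for windows.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BACKGROUND = {
    "A": 0.063, "C": 0.012, "D": 0.055, "E": 0.065, "F": 0.043, "G": 0.052,
    "H": 0.022, "I": 0.061, "K": 0.068, "L": 0.094, "M": 0.021, "N": 0.050,
    "P": 0.045, "Q": 0.040, "R": 0.048, "S": 0.092, "T": 0.056, "V": 0.062,
    "W": 0.011, "Y": 0.040,
}


@dataclass
class SimConfig:
    """Study-design and effect parameters for one simulated experiment.

    Defaults reproduce the mating design: 2 conditions (control = starvation,
    mating) x 5 time points at 45-min spacing x 3 biological replicates.
    Effects are planted as net log2 changes of magnitude ``effect_size_sd``
    (random sign) on top of Gaussian measurement noise of SD ``noise_sd``.
    """

    n_sites: int = 2000
    n_proteins: int | None = None
    sites_per_protein: float = 5.0
    replicates: int = 3
    timepoints: Sequence[int] = (0, 45, 90, 135, 180)
    conditions: Sequence[str] = ("control", "mating")
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.70, "starvation_only": 0.15,
            "mating_specific": 0.10, "both_different": 0.05,
        }
    )
    protein_class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.68, "starvation_only": 0.30,
            "mating_specific": 0.01, "both_different": 0.01,
        }
    )
    effect_size_sd: float = 1.0   # net planted log2 change
    noise_sd: float = 0.25        # per-measurement log2 noise
    batch_sd: float = 0.30        # per-replicate additive offset
    missing_rate: float = 0.05
    replicate_dropout_rate: float = 0.02
    coupled_fraction: float = 0.05
    redundancy_rate: float = 0.05
    n_kinase_sets: int = 3
    substrate_enrichment_odds: float = 6.0
    window_motif: Mapping | None = None
    profile_shape: str = "switch"  # or "ramp"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites <= 0 or self.replicates <= 0:
            raise ValueError("counts must be positive")
        if len(self.timepoints) < 2 or len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be >= 2 distinct values")
        if len(self.conditions) < 1 or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be distinct and non-empty")
        for name, props in (("class_proportions", self.class_proportions),
                            ("protein_class_proportions", self.protein_class_proportions)):
            if set(props) - set(CLASSES):
                raise ValueError(f"{name} keys must be among {CLASSES}")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("missing_rate", "replicate_dropout_rate", "coupled_fraction", "redundancy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.profile_shape not in ("switch", "ramp"):
            raise ValueError("profile_shape must be 'switch' or 'ramp'")

    @property
    def resolved_n_proteins(self) -> int:
        if self.n_proteins is not None:
            return self.n_proteins
        return max(1, int(round(self.n_sites / self.sites_per_protein)))


def mating_config(**overrides) -> SimConfig:
    """The mating design: 3 replicates x {control, mating} x 5 time points."""
    return SimConfig(**overrides)


def fusion_config(**overrides) -> SimConfig:
    """The fusion design: 4 replicates x one condition x 5 time points at 11 min."""
    defaults = dict(replicates=4, timepoints=(0, 11, 22, 33, 44), conditions=("fusion",))
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class GroundTruth:
    """Planted labels enabling recovery tests against the pipeline output."""

    site_class: pd.Series          # feature_id -> effect class of the site's own profile
    coupled: pd.Series             # feature_id -> bool (tracks its protein's profile)
    redundancy_group: pd.Series    # feature_id -> group id or <NA>
    kinase_sets: dict[str, set]    # kinase -> set of feature_ids
    site_profile: pd.DataFrame     # feature_id x (condition, time) true mean, coupling included
    protein_class: pd.Series       # protein_id -> effect class
    protein_profile: pd.DataFrame  # protein_id x (condition, time) true mean

    def differential_in_condition_pair(self, a: str, b: str, tol: float = 1e-12) -> pd.Series:
        """True if the site's full true profile (coupling included) differs
        between conditions ``a`` and ``b`` — the ground truth for the
        starvation-corrected (difference-of-differences) analysis."""
        pa = self.site_profile[a].to_numpy()
        pb = self.site_profile[b].to_numpy()
        diff = (pa - pa[:, :1]) - (pb - pb[:, :1])
        return pd.Series(np.abs(diff).max(axis=1) > tol, index=self.site_profile.index)

    def changing_in_condition(self, cond: str, tol: float = 1e-12) -> pd.Series:
        p = self.site_profile[cond].to_numpy()
        return pd.Series(np.abs(p - p[:, :1]).max(axis=1) > tol, index=self.site_profile.index)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def _monotone_profile(rng: np.random.Generator, times: np.ndarray, amplitude: float,
                      shape: str) -> np.ndarray:
    """A monotone profile with net change ``amplitude`` (signed).

    ``switch``: flat, then a full-amplitude transition across one uniformly
    chosen inter-sample interval.  ``ramp``: linear from a uniformly chosen
    onset knot to the final time point.
    """
    T = len(times)
    if shape == "switch":
        j = rng.integers(0, T - 1)  # transition within (t_j, t_{j+1})
        prof = np.zeros(T)
        prof[j + 1:] = amplitude
    else:
        j = rng.integers(0, T - 1)
        prof = np.zeros(T)
        prof[j:] = np.linspace(0.0, amplitude, T - j)
    return prof


def _class_profiles(rng: np.random.Generator, cls: str, conditions: Sequence[str],
                    times: np.ndarray, effect: float, shape: str) -> np.ndarray:
    """(n_conditions x T) true mean profiles for one feature of class ``cls``.

    The first condition plays the role of the starvation control.  With a
    single condition, any non-null class simply changes over time.
    """
    T = len(times)
    out = np.zeros((len(conditions), T))
    if cls == "null" or effect == 0.0:
        return out
    sign = 1.0 if rng.random() < 0.5 else -1.0
    base = _monotone_profile(rng, times, sign * effect, shape)
    if cls == "starvation_only":
        out[:] = base  # identical in every condition
    elif cls == "mating_specific":
        out[1:] = base  # control stays flat
        if len(conditions) == 1:
            out[0] = base
    elif cls == "both_different":
        out[0] = base
        # different dynamics in the treated condition: independent transition
        # point and independent sign (may be same direction, different slope)
        sign2 = 1.0 if rng.random() < 0.5 else -1.0
        other = _monotone_profile(rng, times, sign2 * effect, shape)
        if len(conditions) > 1:
            out[1:] = base + other
        else:
            out[0] = base + other
    return out


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def _draw_classes(rng: np.random.Generator, n: int, proportions: Mapping[str, float]) -> np.ndarray:
    labels = [c for c in CLASSES if proportions.get(c, 0.0) > 0]
    probs = np.array([proportions[c] for c in labels])
    return rng.choice(labels, size=n, p=probs / probs.sum())


def simulate_experiment(config: SimConfig) -> tuple[QuantTable, QuantTable, GroundTruth]:
    """Generate (proteome, phosphoproteome, truth) for one experiment.

    value(site, sample) = replicate_offset + true_profile(class, condition,
    time) + coupled * protein_profile + Normal(0, noise_sd).  Entries are
    deleted MCAR at ``missing_rate``; whole replicates are dropped per feature
    at ``replicate_dropout_rate``; ``redundancy_rate`` of sites are duplicated
    into groups with bit-identical rows.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    times = np.asarray(config.timepoints)
    conditions = list(config.conditions)
    T, R = len(times), config.replicates
    n_prot = config.resolved_n_proteins

    ss = np.random.SeedSequence(config.seed)
    (s_assign, s_profiles, s_noise, s_missing, s_redund, s_kinase, s_protnoise) = [
        np.random.default_rng(c) for c in ss.spawn(7)
    ]

    # --- true protein profiles and site classes -------------------------
    protein_ids = np.array([f"P{i:05d}" for i in range(n_prot)])
    prot_class = _draw_classes(s_profiles, n_prot, config.protein_class_proportions)
    prot_prof = np.stack([
        _class_profiles(s_profiles, c, conditions, times, config.effect_size_sd, config.profile_shape)
        for c in prot_class
    ])  # n_prot x n_cond x T

    site_class = _draw_classes(s_profiles, config.n_sites, config.class_proportions)
    # coupling: a coupled site is a pure tracker of a changing protein — its
    # own profile is null and its values inherit the protein's dynamics
    coupled = s_profiles.random(config.n_sites) < config.coupled_fraction
    site_class[coupled] = "null"
    changing_prots = np.flatnonzero(prot_class != "null")
    if coupled.any() and len(changing_prots) == 0:
        raise ValueError("coupled_fraction > 0 requires some non-null proteins")

    # --- feature bookkeeping -------------------------------------------
    site_protein = protein_ids[s_assign.integers(0, n_prot, size=config.n_sites)]
    if coupled.any():
        site_protein[coupled] = protein_ids[
            s_assign.choice(changing_prots, size=int(coupled.sum()))
        ]
    positions = np.zeros(config.n_sites, dtype=int)
    residues = s_assign.choice(list("ST"), size=config.n_sites, p=[0.7, 0.3])
    # distinct positions within each protein
    order = np.argsort(site_protein, kind="stable")
    counter: dict[str, int] = {}
    for idx in order:
        p = site_protein[idx]
        counter[p] = counter.get(p, 0) + 10 + int(s_assign.integers(0, 20))
        positions[idx] = counter[p]
    site_ids = np.array([f"{p}_{r}{pos}" for p, r, pos in zip(site_protein, residues, positions)])
    multiplicity = s_assign.choice([1, 2], size=config.n_sites, p=[0.85, 0.15])

    site_own_prof = np.stack([
        _class_profiles(s_profiles, c, conditions, times, config.effect_size_sd, config.profile_shape)
        for c in site_class
    ])  # n_sites x n_cond x T
    prot_index = {p: i for i, p in enumerate(protein_ids)}
    site_prot_idx = np.array([prot_index[p] for p in site_protein])
    site_total_prof = site_own_prof + np.where(
        coupled[:, None, None], prot_prof[site_prot_idx], 0.0
    )

    # --- sample layout ---------------------------------------------------
    keys = [
        SampleKey(cond, int(t), str(r + 1))
        for r in range(R) for cond in conditions for t in times
    ]
    cols = [k.name for k in keys]
    cond_idx = np.array([conditions.index(k.condition) for k in keys])
    time_idx = np.array([int(np.flatnonzero(times == k.time_min)[0]) for k in keys])
    rep_idx = np.array([int(k.replicate) - 1 for k in keys])

    batch = s_noise.normal(0.0, config.batch_sd, size=R)

    def build_matrix(profiles: np.ndarray, rng: np.random.Generator, n_rows: int) -> np.ndarray:
        mean = profiles[:, cond_idx, time_idx]  # n_rows x n_samples
        return mean + batch[rep_idx][None, :] + rng.normal(0.0, config.noise_sd, size=(n_rows, len(keys)))

    phospho_vals = build_matrix(site_total_prof, s_noise, config.n_sites)
    prot_vals = build_matrix(prot_prof, s_protnoise, n_prot)

    # --- missingness (phospho layer; proteome kept complete-ish) --------
    mcar = s_missing.random(phospho_vals.shape) < config.missing_rate
    phospho_vals[mcar] = np.nan
    dropout = s_missing.random(config.n_sites) < config.replicate_dropout_rate
    drop_rep = s_missing.integers(0, R, size=config.n_sites)
    for i in np.flatnonzero(dropout):
        phospho_vals[i, rep_idx == drop_rep[i]] = np.nan
    prot_mcar = s_missing.random(prot_vals.shape) < min(config.missing_rate, 0.02)
    prot_vals[prot_mcar] = np.nan

    # --- redundancy: duplicate rows with bit-identical values -----------
    n_dup = int(round(config.redundancy_rate * config.n_sites))
    dup_src = s_redund.choice(config.n_sites, size=n_dup, replace=False) if n_dup else np.array([], int)
    redundancy_group = np.full(config.n_sites + n_dup, pd.NA, dtype=object)
    dup_rows, dup_ids, dup_meta = [], [], []
    for g, i in enumerate(dup_src):
        gid = f"G{g:04d}"
        redundancy_group[i] = gid
        redundancy_group[config.n_sites + len(dup_rows)] = gid
        dup_rows.append(phospho_vals[i].copy())
        dup_ids.append(f"{site_protein[i]}_{residues[i]}{positions[i] + 2}")
        dup_meta.append((site_protein[i], residues[i], positions[i] + 2, 2,
                         site_class[i], coupled[i], site_total_prof[i]))
    all_ids = np.concatenate([site_ids, np.array(dup_ids, dtype=object)]) if n_dup else site_ids
    if pd.Index(all_ids).has_duplicates:  # rare positional collision
        seen: dict[str, int] = {}
        uniq = []
        for fid in all_ids:
            if fid in seen:
                seen[fid] += 1
                uniq.append(f"{fid}.{seen[fid]}")
            else:
                seen[fid] = 0
                uniq.append(fid)
        all_ids = np.array(uniq, dtype=object)

    values = np.vstack([phospho_vals] + [r[None, :] for r in dup_rows]) if n_dup else phospho_vals
    feats = pd.DataFrame(
        {
            "protein_id": np.concatenate([site_protein, [m[0] for m in dup_meta]]) if n_dup else site_protein,
            "residue": np.concatenate([residues, [m[1] for m in dup_meta]]) if n_dup else residues,
            "position": pd.array(
                np.concatenate([positions, [m[2] for m in dup_meta]]).astype(int) if n_dup else positions,
                dtype="Int64"),
            "multiplicity": pd.array(
                np.concatenate([multiplicity, [m[3] for m in dup_meta]]).astype(int) if n_dup else multiplicity,
                dtype="Int64"),
            "window": pd.NA,
        },
        index=pd.Index(all_ids, name="feature_id"),
    )
    # duplicated sites originate from multiply-phosphorylated peptides
    phospho = QuantTable(pd.DataFrame(values, index=feats.index, columns=cols), feats)

    prot_feats = pd.DataFrame(
        {"protein_id": protein_ids, "residue": pd.NA,
         "position": pd.array([pd.NA] * n_prot, dtype="Int64"),
         "multiplicity": pd.array([pd.NA] * n_prot, dtype="Int64"), "window": pd.NA},
        index=pd.Index(protein_ids, name="feature_id"),
    )
    proteome = QuantTable(pd.DataFrame(prot_vals, index=prot_feats.index, columns=cols), prot_feats)

    # --- truth -----------------------------------------------------------
    all_class = np.concatenate([site_class, [m[4] for m in dup_meta]]) if n_dup else site_class
    all_coupled = np.concatenate([coupled, [m[5] for m in dup_meta]]) if n_dup else coupled
    all_prof = np.vstack([site_total_prof] + [m[6][None] for m in dup_meta]) if n_dup else site_total_prof
    prof_cols = pd.MultiIndex.from_product([conditions, times], names=["condition", "time_min"])
    truth = GroundTruth(
        site_class=pd.Series(all_class, index=feats.index, name="class"),
        coupled=pd.Series(all_coupled.astype(bool), index=feats.index, name="coupled"),
        redundancy_group=pd.Series(redundancy_group, index=feats.index, name="redundancy_group"),
        kinase_sets=_plant_kinase_sets(s_kinase, feats, pd.Series(all_class, index=feats.index),
                                       config),
        site_profile=pd.DataFrame(all_prof.reshape(len(feats), -1), index=feats.index, columns=prof_cols),
        protein_class=pd.Series(prot_class, index=prot_feats.index, name="class"),
        protein_profile=pd.DataFrame(prot_prof.reshape(n_prot, -1), index=prot_feats.index, columns=prof_cols),
    )
    return proteome, phospho, truth


def _plant_kinase_sets(rng: np.random.Generator, feats: pd.DataFrame, site_class: pd.Series,
                       config: SimConfig, base_rate: float = 0.03) -> dict[str, set]:
    """Substrate sets enriched among mating-specific monophosphorylated sites.

    Membership probability is ``base_rate`` for background sites and has its
    odds multiplied by ``substrate_enrichment_odds`` for mating-specific ones.
    """
    mono = (feats["multiplicity"] == 1).to_numpy()
    is_mating = (site_class == "mating_specific").to_numpy()
    odds = base_rate / (1 - base_rate)
    p_enriched = (odds * config.substrate_enrichment_odds) / (1 + odds * config.substrate_enrichment_odds)
    p = np.where(is_mating, p_enriched, base_rate)
    sets: dict[str, set] = {}
    for k in range(config.n_kinase_sets):
        member = (rng.random(len(feats)) < p) & mono
        sets[f"kinase{k + 1}"] = set(feats.index[member])
    return sets


# ---------------------------------------------------------------------------
# Sequence windows
# ---------------------------------------------------------------------------

def simulate_windows(truth: GroundTruth, alphabet: str = AMINO_ACIDS,
                     motif_spec: Mapping | None = None, seed: int = 0) -> pd.Series:
    """Draw an 11-residue window per feature from background frequencies.

    ``motif_spec``: ``{"offset": +1, "residue": "P", "prob": 0.8,
    "classes": ["mating_specific"]}`` plants the given residue at the given
    offset (relative to the central phosphoresidue, range -5..+5, offset 0
    excluded) with the given probability for sites of the listed classes.
    The center is the phosphoresidue (S or T, 70/30).
    """
    if motif_spec is not None:
        off = int(motif_spec["offset"])
        if off == 0 or not -5 <= off <= 5:
            raise ValueError("motif offset must be in [-5, +5] and non-zero")
        if motif_spec["residue"] not in alphabet:
            raise ValueError(f"motif residue {motif_spec['residue']!r} not in alphabet")
        motif_classes = set(motif_spec.get("classes", ["mating_specific"]))
    rng = np.random.default_rng(seed)
    probs = np.array([_BACKGROUND.get(a, 0.0) for a in alphabet])
    if probs.sum() == 0:
        probs = np.ones(len(alphabet))
    probs = probs / probs.sum()
    letters = np.array(list(alphabet))

    n = len(truth.site_class)
    grid = letters[rng.choice(len(letters), size=(n, WINDOW_LENGTH), p=probs)]
    centers = rng.choice(["S", "T"], size=n, p=[0.7, 0.3])
    grid[:, 5] = centers
    if motif_spec is not None:
        hit = truth.site_class.isin(motif_classes).to_numpy()
        planted = rng.random(n) < float(motif_spec.get("prob", 1.0))
        grid[hit & planted, 5 + off] = motif_spec["residue"]
    windows = pd.Series(["".join(row) for row in grid], index=truth.site_class.index, name="window")
    return windows
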