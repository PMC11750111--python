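"""Kinase-substrate enrichment, phosphosite motif matrices, and the
microscopy screen metrics.

Enrichment asks whether the phosphosites changing in a condition are
over-represented among the known substrates of a kinase (Fisher's exact
test on a 2x2 hit x substrate table, restricted to monophosphorylated
sites).  Motif analysis aligns the +/-5-residue windows of a site set and
tabulates per-position residue probabilities, optionally excluding
proline-directed sites (P at +1) and explicit site lists to expose
secondary motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import PAD_CHAR, WINDOW_LENGTH

__all__ = [
    "SubstrateSet",
    "PositionFrequencyMatrix",
    "fisher_enrichment",
    "load_substrate_sets",
    "write_substrate_sets",
    "motif_pfm",
    "mating_efficiency",
    "fusion_efficiency",
    "zygote_fraction",
]

POSITIONS = tuple(range(-5, 6))


@dataclass
class SubstrateSet:
    """kinase label -> set of site keys (e.g. ``P00123_S45``)."""

    kinase: str
    sites: set[str]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"substrate set {self.kinase!r} is empty")


@dataclass
class PositionFrequencyMatrix:
    """Residue probabilities at positions -5..+5 around the phosphoresidue.

    ``probs`` is an 11 x alphabet DataFrame; each row sums to 1 over the
    windows contributing a real residue at that position (terminal padding
    is excluded from the denominator).
    """

    probs: pd.DataFrame
    n_windows: int

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1).to_numpy()
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("PFM rows must sum to 1")


@dataclass
class EnrichmentResult:
    kinase: str
    fold: float
    p: float
    n_hit_substrate: int
    n_hits: int
    n_substrate_bg: int
    n_background: int


def fisher_enrichment(hit_sites: Iterable[str], substrate_set: SubstrateSet,
                      background_sites: Iterable[str],
                      alternative: str = "two-sided") -> EnrichmentResult:
    """Fold enrichment of a substrate set among hits, with Fisher exact p.

    fold = (|hits ∩ substrates| / |hits|) / (|substrates ∩ background| /
    |background|).  Hits must be a subset of the background (typically all
    monophosphorylated sites quantified after filtering).  A substrate set
    disjoint from the background yields an undefined fold (NaN) with p = 1.
    """
    hits = set(hit_sites)
    background = set(background_sites)
    if not hits or not background:
        raise ValueError("hits and background must be non-empty")
    if not hits <= background:
        raise ValueError(f"{len(hits - background)} hit sites are not in the background")
    subs_bg = substrate_set.sites & background
    a = len(hits & subs_bg)                      # hit & substrate
    b = len(hits) - a                            # hit & non-substrate
    c = len(subs_bg) - a                         # non-hit & substrate
    d = len(background) - len(hits) - c          # non-hit & non-substrate
    if len(subs_bg) == 0:
        return EnrichmentResult(substrate_set.kinase, float("nan"), 1.0, a, len(hits), 0, len(background))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    fold = (a / len(hits)) / (len(subs_bg) / len(background))
    return EnrichmentResult(substrate_set.kinase, fold, float(p), a, len(hits),
                            len(subs_bg), len(background))


def load_substrate_sets(path: str | Path) -> list[SubstrateSet]:
    """Read a two-column TSV (kinase, site key); duplicates de-duplicated."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'kinase<TAB>site_key', got {line!r}")
            sets.setdefault(parts[0], set()).add(parts[1])
    if not sets:
        raise ValueError(f"{path}: no substrate entries found")
    return [SubstrateSet(k, v) for k, v in sets.items()]


def write_substrate_sets(sets: Sequence[SubstrateSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            for site in sorted(s.sites):
                fh.write(f"{s.kinase}\t{site}\n")


# ---------------------------------------------------------------------------
# Motif matrices
# ---------------------------------------------------------------------------

def motif_pfm(windows: Mapping[str, str] | pd.Series,
              exclude_proline_directed: bool = False,
              exclude_sites: Iterable[str] = (),
              alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> PositionFrequencyMatrix:
    """Per-position residue probabilities over 11-residue site windows.

    ``windows`` maps site key -> window (center = phosphoresidue, S or T).
    ``exclude_proline_directed`` drops windows with P at +1;
    ``exclude_sites`` drops the listed site keys.  Padding characters are
    excluded from each position's denominator.
    """
    win = pd.Series(windows).dropna()
    excl = set(exclude_sites)
    win = win[~win.index.isin(excl)]
    for key, w in win.items():
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"site {key}: window {w!r} does not have length {WINDOW_LENGTH}")
        if w[5] not in "ST":
            raise ValueError(f"site {key}: central residue {w[5]!r} is not S/T")
    if exclude_proline_directed:
        win = win[win.str[6] != "P"]
    counts = pd.DataFrame(0, index=pd.Index(POSITIONS, name="position"), columns=list(alphabet))
    for w in win:
        for pos, ch in zip(POSITIONS, w):
            if ch == PAD_CHAR:
                continue
            if ch not in counts.columns:
                raise ValueError(f"residue {ch!r} not in alphabet")
            counts.loc[pos, ch] += 1
    totals = counts.sum(axis=1)
    probs = counts.div(totals.where(totals > 0, 1), axis=0).astype(float)
    return PositionFrequencyMatrix(probs, n_windows=len(win))


# ---------------------------------------------------------------------------
# Microscopy screen metrics
# ---------------------------------------------------------------------------

def mating_efficiency(n_individual: int, n_pairs: int, n_zygotes: int) -> float:
    """% of cells engaged in mating:
    100 * 2(pairs + zygotes) / (individuals + 2(pairs + zygotes))."""
    _check_counts(n_individual, n_pairs, n_zygotes)
    engaged = 2 * (n_pairs + n_zygotes)
    if n_individual + engaged == 0:
        raise ValueError("all counts are zero")
    return 100.0 * engaged / (n_individual + engaged)


def fusion_efficiency(n_pairs_unfused: int, n_fused: int, literal_formula: bool = False) -> float:
    """% of mating-engaged pairs that fused.

    Default denominator counts all engaged pairs (unfused + fused), reading
    "% of paired cells that fused".  ``literal_formula`` instead divides by
    the unfused pair count alone, the printed formula's literal reading.
    """
    _check_counts(n_pairs_unfused, n_fused)
    denom = n_pairs_unfused if literal_formula else (n_pairs_unfused + n_fused)
    if denom == 0:
        raise ValueError("fusion efficiency denominator is zero")
    return 100.0 * n_fused / denom


def zygote_fraction(n_individual: int, n_pairs_unfused: int, n_fused: int) -> float:
    """% of zygotes relative to all cells:
    100 * 2*zygotes / (individuals + 2(pairs + zygotes))."""
    _check_counts(n_individual, n_pairs_unfused, n_fused)
    denom = n_individual + 2 * (n_pairs_unfused + n_fused)
    if denom == 0:
        raise ValueError("all counts are zero")
    return 100.0 * 2 * n_fused / denom


def _check_counts(*counts: int) -> None:
    for c in counts:
        if c < 0 or int(c) != c:
            raise ValueError(f"counts must be non-negative integers, got {c}")
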