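"""Signature trajectories along pseudotime and module-overlap accounting.

Pseudotime values are taken from the cell annotation as given (typically
imported from a trajectory-inference run upstream); the package never
recomputes them.  A profile is the per-bin mean of a per-cell signature
score over equal-width bins of the observed pseudotime range, and a trend
is the Spearman correlation between bin centers and bin means.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datatypes import CellAnnotation, GeneModuleSet, GeneSet, ValidationError
from .scoring import ScoreVector

logger = logging.getLogger("consig")


class Direction(enum.Enum):
    DECREASING = "DECREASING"
    INCREASING = "INCREASING"
    FLAT = "FLAT"


@dataclass(frozen=True)
class PseudotimeProfile:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_score: np.ndarray     # NaN for empty bins
    n_cells: np.ndarray
    signature_name: str
    population_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.bin_centers)
        if not (len(self.bin_edges) == n + 1
                and len(self.mean_score) == n
                and len(self.n_cells) == n):
            raise ValidationError("profile array lengths inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "mean_score": self.mean_score,
            "n_cells": self.n_cells,
            "signature": self.signature_name,
            "population": self.population_label,
        })


@dataclass(frozen=True)
class TrendStats:
    spearman_rho: float
    direction: Direction
    n_bins_used: int


@dataclass(frozen=True)
class ModuleOverlap:
    counts: dict[str, int]
    unassigned_genes: tuple[str, ...]
    multi_assigned: tuple[str, ...] = ()

    @property
    def unassigned_count(self) -> int:
        return len(self.unassigned_genes)


def profile_signature(scores: ScoreVector, ann: CellAnnotation, n_bins: int = 50,
                      *, population_label: str = "",
                      smooth_window: int | None = None) -> PseudotimeProfile:
    """Bin per-cell scores over equal-width pseudotime bins.

    Empty bins propagate as NaN (never zero).  ``smooth_window`` applies an
    optional centered rolling mean over the bin means — cosmetic only.
    """
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    if "pseudotime" not in ann.frame.columns:
        raise ValidationError("annotation carries no pseudotime column")
    t = ann.frame["pseudotime"]
    cells = scores.scores.index.intersection(t.dropna().index)
    if len(cells) < 2:
        raise ValidationError("need at least 2 cells with pseudotime")
    tv = t.loc[cells].to_numpy(float)
    sv = scores.scores.loc[cells].to_numpy(float)
    lo, hi = tv.min(), tv.max()
    if hi == lo:
        hi = lo + 1.0  # all mass falls in the first bin
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(tv, edges[1:-1]), 0, n_bins - 1)
    n_cells = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sv, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(n_cells > 0, sums / np.maximum(n_cells, 1), np.nan)
    if smooth_window is not None and smooth_window > 1:
        logger.info("smoothing profile with centered rolling mean, window=%d",
                    smooth_window)
        means = (pd.Series(means)
                 .rolling(smooth_window, center=True, min_periods=1)
                 .mean().to_numpy())
    centers = (edges[:-1] + edges[1:]) / 2.0
    return PseudotimeProfile(edges, centers, means, n_cells,
                             scores.signature_name, population_label)


def trend(profile: PseudotimeProfile, flat_rho: float = 0.3) -> TrendStats:
    """Spearman rho of (bin center, mean score) over non-empty bins.

    |rho| below ``flat_rho`` (or undefined rho on constant means)
    classifies as FLAT.
    """
    mask = profile.n_cells > 0
    if mask.sum() < 3:
        raise ValidationError("trend needs at least 3 non-empty bins")
    x = profile.bin_centers[mask]
    y = profile.mean_score[mask]
    if np.allclose(y, y[0]):
        rho = 0.0
    else:
        rho = float(spearmanr(x, y).statistic)
        if np.isnan(rho):
            rho = 0.0
    if abs(rho) < flat_rho:
        direction = Direction.FLAT
    elif rho > 0:
        direction = Direction.INCREASING
    else:
        direction = Direction.DECREASING
    return TrendStats(rho, direction, int(mask.sum()))


def module_overlap(sig: GeneSet, modules: GeneModuleSet) -> ModuleOverlap:
    """Per-module intersection counts with a signature.

    Genes in no module are reported as unassigned; genes falling in several
    (non-disjoint) modules are counted in each and listed explicitly.
    """
    counts: dict[str, int] = {m.name: 0 for m in modules}
    hits: dict[str, int] = {}
    for m in modules:
        keys = {g.casefold() for g in m.genes}
        for g in sig.genes:
            if g.casefold() in keys:
                counts[m.name] += 1
                hits[g] = hits.get(g, 0) + 1
    unassigned = tuple(g for g in sig.genes if g not in hits)
    multi = tuple(g for g, c in hits.items() if c > 1)
    if multi:
        logger.info("%d signature genes fall in several modules: %s",
                    len(multi), list(multi))
    return ModuleOverlap(counts, unassigned, multi)
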