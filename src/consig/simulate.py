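"""Synthetic marker lists and expression data with known ground truth.

The marker generator emulates the structure of published per-study marker
tables for hippocampal NSC / NP / neuroblast populations: each cell class
carries a small core of genes planted in a configured number of studies,
plus a large study-private remainder, plus decoy records drawn to fail the
fold-change / adjusted-p filter.  The expression generator draws
negative-binomial counts for cells along a latent uniform pseudotime, with
a declining quiescence program, a rising activation program, and a planted
senescent subpopulation whose senescence-program genes are mean-shifted.

All draws go through one ``numpy.random.default_rng(seed)`` stream, so a
fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import (
    CellAnnotation,
    CellClass,
    ExpressionMatrix,
    FCScale,
    GeneSet,
    LayerTag,
    MarkerTable,
    ValidationError,
)

logger = logging.getLogger("consig")


class Trend(enum.Enum):
    DECREASING = "DECREASING"
    INCREASING = "INCREASING"
    FLAT = "FLAT"


# Real symbol spellings injected into default marker cores for readability:
# the two NSC genes recurrent in all seven source studies, and the ten NP
# genes detected in every study ("Cdks6" spelled as published).
NSC_SEED_SYMBOLS = ("Fabp7", "Hopx")
NP_SEED_SYMBOLS = ("Ascl1", "Cdks6", "Ezh2", "Hmgb2", "Insm1",
                   "Lmnb1", "Neurog2", "Odc1", "Spc24", "Tox3")


@dataclass(frozen=True)
class ClassMarkerPlan:
    """Planted structure for one cell class.

    ``core_presence`` is either one study count for every core gene or a
    per-gene sequence of counts (length ``core_size``).
    """

    cell_class: CellClass
    core_size: int
    core_presence: int | tuple[int, ...]
    private_size: int = 200
    decoy_size: int = 30
    seed_symbols: tuple[str, ...] = ()

    def presence_counts(self, n_studies: int) -> tuple[int, ...]:
        if isinstance(self.core_presence, int):
            counts = (self.core_presence,) * self.core_size
        else:
            counts = tuple(self.core_presence)
            if len(counts) != self.core_size:
                raise ValidationError("core_presence length must equal core_size")
        if any(c < 1 or c > n_studies for c in counts):
            raise ValidationError(
                f"core presence counts must lie in [1, {n_studies}]")
        return counts


@dataclass(frozen=True)
class MarkerSimConfig:
    n_studies: int = 7
    class_plans: tuple[ClassMarkerPlan, ...] = ()
    ln_scale_study: int | None = 0  # index of the study reporting ln fold changes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("need at least one study")
        for plan in self.class_plans:
            plan.presence_counts(self.n_studies)


def default_marker_plans() -> tuple[ClassMarkerPlan, ...]:
    """Default planted cores mirroring the published consensus counts:
    28 NSC genes at >=5-of-7 (2 in all 7), 62 NP genes at >=3 (10 in all
    7), and a 20-gene neuroblast core at >=3."""
    return (
        ClassMarkerPlan(CellClass.NSC, core_size=28,
                        core_presence=(7,) * 2 + (6,) * 13 + (5,) * 13,
                        seed_symbols=NSC_SEED_SYMBOLS),
        ClassMarkerPlan(CellClass.NP, core_size=62,
                        core_presence=(7,) * 10 + (6,) * 13 + (5,) * 13
                                      + (4,) * 13 + (3,) * 13,
                        seed_symbols=NP_SEED_SYMBOLS),
        ClassMarkerPlan(CellClass.NEUROBLAST, core_size=20,
                        core_presence=(6,) * 5 + (5,) * 5 + (4,) * 5 + (3,) * 5),
    )


@dataclass(frozen=True)
class ExprProgram:
    name: str
    size: int
    trend: Trend
    amplitude: float


@dataclass(frozen=True)
class ExprSimConfig:
    n_cells: int = 2000
    n_genes: int = 2000
    programs: tuple[ExprProgram, ...] = (
        ExprProgram("quiescence", 50, Trend.DECREASING, 5.0),
        ExprProgram("activation", 50, Trend.INCREASING, 5.0),
        ExprProgram("senescence", 125, Trend.FLAT, 0.0),
    )
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.5
    senescent_fraction: float = 0.2
    senescence_shift: float = 4.0
    senescence_program: str = "senescence"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValidationError("dispersion and baseline mean must be positive")
        if not 0 <= self.senescent_fraction <= 1:
            raise ValidationError("senescent_fraction must lie in [0, 1]")
        if self.senescence_shift <= 0:
            raise ValidationError("senescence_shift must be positive")
        if sum(p.size for p in self.programs) > self.n_genes:
            raise ValidationError("program gene sets exceed the gene count")
        names = [p.name for p in self.programs]
        if len(set(names)) != len(names):
            raise ValidationError("program names must be unique "
                                  "(gene sets are disjoint by construction)")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    core_membership: dict[CellClass, dict[str, frozenset[str]]] = field(
        default_factory=dict)
    decoy_genes: dict[CellClass, tuple[str, ...]] = field(default_factory=dict)
    pseudotime: pd.Series | None = None
    senescent: pd.Series | None = None
    program_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def core_genes(self, cell_class: CellClass, min_studies: int = 1) -> set[str]:
        members = self.core_membership.get(cell_class, {})
        return {g for g, studies in members.items() if len(studies) >= min_studies}

    def program_gene_set(self, name: str) -> GeneSet:
        return GeneSet(name=name, genes=self.program_genes[name])


@dataclass(frozen=True)
class SimulatedExpression:
    counts: ExpressionMatrix
    lognorm: ExpressionMatrix
    annotation: CellAnnotation
    truth: GroundTruth


def simulate_marker_lists(cfg: MarkerSimConfig) -> tuple[MarkerTable, GroundTruth]:
    """Emit per-study marker records with a planted cross-study core.

    Planted records draw fold changes and adjusted p-values that pass the
    default filter; decoy records are split between low fold change and
    non-significant p-value and all fail it.
    """
    rng = np.random.default_rng(cfg.seed)
    studies = [f"study{i + 1}" for i in range(cfg.n_studies)]
    scales = {s: FCScale.LINEAR for s in studies}
    if cfg.ln_scale_study is not None:
        scales[studies[cfg.ln_scale_study]] = FCScale.LN
    rows: list[dict] = []
    membership: dict[CellClass, dict[str, frozenset[str]]] = {}
    decoys: dict[CellClass, tuple[str, ...]] = {}

    def passing_fc(scale: FCScale) -> float:
        return float(rng.uniform(0.35, 1.2) if scale is FCScale.LN
                     else rng.uniform(1.8, 4.0))

    def failing_fc(scale: FCScale) -> float:
        return float(rng.uniform(0.02, 0.2) if scale is FCScale.LN
                     else rng.uniform(1.01, 1.4))

    def add(study: str, plan: ClassMarkerPlan, gene: str, *, passes: bool) -> None:
        scale = scales[study]
        if passes:
            fc, p = passing_fc(scale), float(rng.uniform(1e-6, 0.01))
        elif rng.random() < 0.5:
            fc, p = failing_fc(scale), float(rng.uniform(1e-6, 0.01))
        else:
            fc, p = passing_fc(scale), float(rng.uniform(0.06, 0.9))
        rows.append({"study_id": study,
                     "population_label": f"{plan.cell_class.value}_c1",
                     "cell_class": plan.cell_class, "gene": gene,
                     "fc_value": fc, "fc_scale": scale, "p_adj": p})

    for plan in cfg.class_plans:
        tag = plan.cell_class.value
        counts = plan.presence_counts(cfg.n_studies)
        names = [plan.seed_symbols[i] if i < len(plan.seed_symbols)
                 else f"{tag}core{i + 1:03d}"
                 for i in range(plan.core_size)]
        members: dict[str, frozenset[str]] = {}
        for gene, k in zip(names, counts):
            carried = rng.choice(cfg.n_studies, size=k, replace=False)
            chosen = frozenset(studies[int(i)] for i in carried)
            members[gene] = chosen
            for s in sorted(chosen):
                add(s, plan, gene, passes=True)
        membership[plan.cell_class] = members
        for s in studies:
            for i in range(plan.private_size):
                add(s, plan, f"{s}{tag}priv{i + 1:04d}", passes=True)
        cls_decoys = []
        for s in studies:
            for i in range(plan.decoy_size):
                gene = f"{s}{tag}decoy{i + 1:03d}"
                cls_decoys.append(gene)
                add(s, plan, gene, passes=False)
        decoys[plan.cell_class] = tuple(cls_decoys)

    table = MarkerTable(pd.DataFrame(
        rows, columns=["study_id", "population_label", "cell_class", "gene",
                       "fc_value", "fc_scale", "p_adj"]))
    return table, GroundTruth(core_membership=membership, decoy_genes=decoys)


def _trend_factor(trend: Trend, amplitude: float, t: np.ndarray) -> np.ndarray:
    if trend is Trend.DECREASING:
        return 1.0 + amplitude * (1.0 - t)
    if trend is Trend.INCREASING:
        return 1.0 + amplitude * t
    return np.ones_like(t)


def simulate_expression(cfg: ExprSimConfig) -> SimulatedExpression:
    """Draw a counts matrix over a latent pseudotime with planted programs.

    Per-gene mean = baseline x trend factor; senescent cells additionally
    multiply the senescence-program means by ``senescence_shift``.  Counts
    are negative binomial with variance mu + mu^2 / dispersion.  A
    log-normalized layer (log1p counts-per-10k) is emitted alongside.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = tuple(f"G{i + 1:06d}" for i in range(cfg.n_genes))
    cells = tuple(f"cell{i + 1:05d}" for i in range(cfg.n_cells))
    t = rng.uniform(size=cfg.n_cells)
    senescent = rng.random(cfg.n_cells) < cfg.senescent_fraction

    program_genes: dict[str, tuple[str, ...]] = {}
    cursor = 0
    mu = np.full((cfg.n_genes, cfg.n_cells), cfg.baseline_mean)
    for prog in cfg.programs:
        idx = np.arange(cursor, cursor + prog.size)
        cursor += prog.size
        program_genes[prog.name] = tuple(genes[i] for i in idx)
        mu[idx] = cfg.baseline_mean * _trend_factor(prog.trend, prog.amplitude, t)
        if prog.name == cfg.senescence_program:
            mu[np.ix_(idx, np.flatnonzero(senescent))] *= cfg.senescence_shift

    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)
    counts_m = sparse.csr_matrix(counts)
    expr_counts = ExpressionMatrix(genes, cells, counts_m, LayerTag.COUNTS)

    libsize = counts.sum(axis=0).astype(float)
    libsize[libsize == 0] = 1.0
    lognorm = np.log1p(counts / libsize * 1e4)
    expr_lognorm = ExpressionMatrix(genes, cells, sparse.csr_matrix(lognorm),
                                    LayerTag.LOGNORM)

    tertile = np.minimum((t * 3).astype(int), 2)
    cluster = np.array(["NSC", "NP", "NEUROBLAST"])[tertile]
    ann = CellAnnotation(pd.DataFrame({
        "cluster": cluster,
        "study_id": "sim",
        "age_group": np.where(senescent, "old", "young"),
        "pseudotime": t,
    }, index=pd.Index(cells, name="cell_id")))
    truth = GroundTruth(
        pseudotime=pd.Series(t, index=list(cells), name="pseudotime"),
        senescent=pd.Series(senescent, index=list(cells), name="senescent"),
        program_genes=program_genes,
    )
    return SimulatedExpression(expr_counts, expr_lognorm, ann, truth)
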