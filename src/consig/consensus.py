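"""Cross-study marker consensus: filtering, gene-list similarity,
hierarchical clustering, exclusive intersections and k-of-n signatures.

The pipeline compares the per-population marker gene lists that independent
scRNA-seq studies published for the same cell class.  After thresholding on
fold change and adjusted p-value, each study contributes one gene set per
class; pairwise overlap between the sets drives a dendrogram of populations,
and genes recurring in at least ``min_studies`` sets form the consensus
signature for that class.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CellClass,
    FCScale,
    GeneSet,
    MarkerTable,
    ValidationError,
    canonicalize_symbols,
)

logger = logging.getLogger("consig")


class SimilarityMetric(enum.Enum):
    COMMON_COUNT = "COMMON_COUNT"
    JACCARD = "JACCARD"
    OVERLAP_COEFF = "OVERLAP_COEFF"


class DistanceMethod(enum.Enum):
    ONE_MINUS = "ONE_MINUS"
    MAX_MINUS = "MAX_MINUS"


class Linkage(enum.Enum):
    COMPLETE = "COMPLETE"
    AVERAGE = "AVERAGE"
    SINGLE = "SINGLE"


class CountingUnit(enum.Enum):
    STUDY = "STUDY"
    CLUSTER = "CLUSTER"


@dataclass(frozen=True)
class FilterParams:
    """Marker inclusion thresholds.

    Genes pass with linear fold change strictly above ``fc_min_linear``
    (log2 values are back-transformed first) — except for studies reporting
    natural-log fold changes, which are thresholded directly at
    ``ln_fc_min`` — and adjusted p-value strictly below ``p_adj_max``.
    """

    fc_min_linear: float = 1.5
    p_adj_max: float = 0.05
    ln_fc_min: float = 0.25

    def __post_init__(self) -> None:
        if not self.fc_min_linear > 1:
            raise ValidationError("fc_min_linear must exceed 1")
        if not 0 < self.p_adj_max <= 1:
            raise ValidationError("p_adj_max must lie in (0, 1]")


@dataclass(frozen=True)
class ConsensusParams:
    min_studies: int = 5
    counting_unit: CountingUnit = CountingUnit.STUDY

    def __post_init__(self) -> None:
        if self.min_studies < 1:
            raise ValidationError("min_studies must be positive")


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    metric: SimilarityMetric

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("similarity matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence.

    Node ids 0..n-1 are leaves (in ``labels`` order); merge ``k`` creates
    node ``n + k``.  ``merges`` rows are (left id, right id, height).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValidationError(f"{n} leaves require {n - 1} merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage array (left, right, height, size)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            Z[k] = (a, b, h, sizes[n + k])
        return Z

    def to_newick(self) -> str:
        """Newick string; branch lengths span merge-height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: _newick_quote(lbl) for i, lbl in enumerate(self.labels)}
        for k, (a, b, h) in enumerate(self.merges):
            left = f"{node[a]}:{h - height[a]:g}"
            right = f"{node[b]}:{h - height[b]:g}"
            node[n + k] = f"({left},{right})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def _newick_quote(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass(frozen=True)
class IntersectionTable:
    """Exclusive (UpSet-style) intersections: every union gene belongs to
    exactly one membership pattern."""

    rows: tuple[tuple[frozenset[str], tuple[str, ...]], ...]

    @property
    def total(self) -> int:
        return sum(len(genes) for _, genes in self.rows)

    def counts(self) -> dict[frozenset[str], int]:
        return {pattern: len(genes) for pattern, genes in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"pattern": "|".join(sorted(p)), "degree": len(p),
              "exclusive_count": len(g), "genes": ",".join(g)}
             for p, g in self.rows])


def linear_fold_change(fc_value: float, scale: FCScale) -> float:
    """Back-transform a reported fold change to linear scale."""
    if scale is FCScale.LINEAR:
        return fc_value
    if scale is FCScale.LOG2:
        return float(2.0 ** fc_value)
    raise ValueError("LN-scale fold changes are thresholded directly")


def filter_markers(table: MarkerTable, params: FilterParams | None = None) -> MarkerTable:
    """Apply the fold-change and adjusted-p thresholds, preserving order.

    Missing p_adj conservatively fails the p threshold.
    """
    params = params or FilterParams()
    df = table.records
    if not len(df):
        return table
    fc = df["fc_value"].to_numpy(float)
    scale = df["fc_scale"].to_numpy(object)
    pass_fc = np.empty(len(df), dtype=bool)
    for i, (v, s) in enumerate(zip(fc, scale)):
        if s is FCScale.LN:
            pass_fc[i] = v > params.ln_fc_min
        else:
            pass_fc[i] = linear_fold_change(v, s) > params.fc_min_linear
    padj = df["p_adj"].to_numpy(float)
    pass_p = np.where(np.isnan(padj), False, padj < params.p_adj_max)
    keep = pass_fc & pass_p
    out = df[keep].reset_index(drop=True)
    if not len(out):
        logger.warning("marker filter removed every record")
    return MarkerTable(out)


def gene_lists_by_class(table: MarkerTable, cell_class: CellClass,
                        counting_unit: CountingUnit = CountingUnit.STUDY,
                        ) -> dict[str, frozenset[str]]:
    """Unit id -> gene set for one cell class.

    STUDY units take the union of each study's clusters of the class;
    CLUSTER units keep each (study, population) list separate.  Symbols are
    canonicalized case-insensitively with one registry across all units.
    """
    df = table.records[table.records["cell_class"] == cell_class]
    if not len(df):
        logger.warning("no records of class %s in marker table", cell_class.value)
        return {}
    registry: dict[str, str] = {}
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        if counting_unit is CountingUnit.STUDY:
            unit = row["study_id"]
        else:
            unit = f"{row['study_id']}::{row['population_label']}"
        gene = canonicalize_symbols([row["gene"]], registry)[0]
        out.setdefault(unit, set()).add(gene)
    return {u: frozenset(g) for u, g in out.items()}


def pairwise_similarity(lists: Mapping[str, frozenset[str]],
                        metric: SimilarityMetric = SimilarityMetric.JACCARD,
                        ) -> SimilarityMatrix:
    """Pairwise gene-list similarity under the chosen metric."""
    if len(lists) < 2:
        raise ValidationError("need at least two gene lists")
    labels = tuple(lists)
    sets = [lists[l] for l in labels]
    n = len(labels)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            a, b = sets[i], sets[j]
            inter = len(a & b)
            if metric is SimilarityMetric.COMMON_COUNT:
                s = float(inter)
            elif metric is SimilarityMetric.JACCARD:
                union = len(a | b)
                if union == 0:
                    logger.warning("empty union for pair (%s, %s); Jaccard set to 0",
                                   labels[i], labels[j])
                    s = 0.0
                else:
                    s = inter / union
            else:
                m = min(len(a), len(b))
                if m == 0:
                    logger.warning("empty list in pair (%s, %s); overlap set to 0",
                                   labels[i], labels[j])
                    s = 0.0
                else:
                    s = inter / m
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(labels, S, metric)


def similarity_to_distance(S: SimilarityMatrix,
                           method: DistanceMethod | None = None) -> np.ndarray:
    """Convert similarity to a symmetric distance matrix with zero diagonal."""
    if method is None:
        method = (DistanceMethod.MAX_MINUS
                  if S.metric is SimilarityMetric.COMMON_COUNT
                  else DistanceMethod.ONE_MINUS)
    if method is DistanceMethod.ONE_MINUS:
        if S.metric is SimilarityMetric.COMMON_COUNT:
            raise ValidationError("ONE_MINUS is undefined for COMMON_COUNT "
                                  "(distances would go negative)")
        D = 1.0 - S.values
    else:
        D = S.values.max() - S.values
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return (D + D.T) / 2.0


def hierarchical_cluster(D: np.ndarray, labels: Sequence[str],
                         linkage: Linkage = Linkage.COMPLETE) -> Dendrogram:
    """Agglomerative clustering with a deterministic tie-break.

    When two candidate merges share the minimum height, the pair whose
    lexicographically smallest leaf label sorts first wins (then the other
    cluster's smallest label).  Lance–Williams updates give single,
    complete and average linkage.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 2:
        raise ValidationError("clustering needs at least two leaves")
    if D.shape != (n, n):
        raise ValidationError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")

    labels = list(labels)
    active: dict[int, dict[str, object]] = {
        i: {"size": 1, "minlab": labels[i]} for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(D[i, j])
        for i, j in itertools.combinations(range(n), 2)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for pair, d in dist.items():
            a, b = sorted(pair)
            la, lb = sorted((active[a]["minlab"], active[b]["minlab"]))
            key = (d, la, lb)
            if best is None or key < best[0]:
                best = (key, a, b)
        (h, _, _), a, b = best
        sa, sb = active[a]["size"], active[b]["size"]
        new = next_id
        next_id += 1
        for c in list(active):
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            if linkage is Linkage.SINGLE:
                d = min(dac, dbc)
            elif linkage is Linkage.COMPLETE:
                d = max(dac, dbc)
            else:
                d = (sa * dac + sb * dbc) / (sa + sb)
            dist[frozenset((new, c))] = d
        dist.pop(frozenset((a, b)))
        active[new] = {"size": sa + sb,
                       "minlab": min(active[a]["minlab"], active[b]["minlab"])}
        del active[a], active[b]
        merges.append((a, b, h))
    return Dendrogram(tuple(labels), tuple(merges))


def exclusive_intersections(lists: Mapping[str, frozenset[str]]) -> IntersectionTable:
    """Assign every union gene to its exact membership pattern."""
    if not lists:
        raise ValidationError("need at least one gene list")
    membership: dict[str, set[str]] = {}
    for unit, genes in lists.items():
        for g in genes:
            membership.setdefault(g, set()).add(unit)
    patterns: dict[frozenset[str], list[str]] = {}
    for g, units in membership.items():
        patterns.setdefault(frozenset(units), []).append(g)
    rows = sorted(
        ((p, tuple(sorted(genes))) for p, genes in patterns.items()),
        key=lambda r: (-len(r[1]), len(r[0]), tuple(sorted(r[0]))))
    return IntersectionTable(tuple(rows))


def consensus_signature(lists: Mapping[str, frozenset[str]],
                        params: ConsensusParams,
                        name: str | None = None) -> GeneSet:
    """Genes present in at least ``min_studies`` distinct units.

    Output order: descending unit count, then symbol (casefolded).
    """
    if params.min_studies > len(lists):
        raise ValidationError(
            f"min_studies={params.min_studies} exceeds the {len(lists)} "
            "units supplied")
    counts: dict[str, int] = {}
    for genes in lists.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    kept = [g for g, c in counts.items() if c >= params.min_studies]
    kept.sort(key=lambda g: (-counts[g], g.casefold()))
    if not kept:
        raise ValidationError(
            f"no gene reaches min_studies={params.min_studies}")
    return GeneSet(name=name or f"consensus_k{params.min_studies}",
                   genes=tuple(kept),
                   description=f"genes in >= {params.min_studies} of "
                               f"{len(lists)} units")
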