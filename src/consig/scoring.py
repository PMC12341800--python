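"""Per-cluster expression summaries and per-cell signature scores.

Two scoring methods are provided:

* ``zscore_signature_score`` — each signature gene is z-scored across cells
  (sample sd, n-1 denominator) and the per-cell score is the mean z over
  genes; the method behind the pseudotime trajectory profiles.
* ``rank_signature_score`` — a capped-rank Mann–Whitney-U statistic: within
  each cell all genes are ranked by decreasing expression (average ranks on
  ties), ranks beyond ``max_rank`` are truncated to ``max_rank + 1``, and

      U' = sum(signature ranks) - n_s (n_s + 1) / 2
      score = 1 - U' / (n_s * max_rank),  clipped to [0, 1].

  A score of 1 means the signature occupies the cell's top ranks; cells at
  or above the cutoff (default 0.4) are flagged as high-scoring.  Being
  rank-based, the score is invariant to any strictly monotone per-cell
  transform of expression, which makes it robust to normalization choices.

Scores are computed on log-normalized expression; raw counts are first
library-size normalized (counts per 10k, log1p), which only matters for the
z-score method since ranks are normalization-invariant within a cell.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .datatypes import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    LayerTag,
    ValidationError,
)

logger = logging.getLogger("consig")


class ScoreMethod(enum.Enum):
    ZSCORE_MEAN = "ZSCORE_MEAN"
    RANK_U = "RANK_U"


@dataclass(frozen=True)
class ScoreParams:
    """Rank-score parameters: rank cap, high-cell cutoff (inclusive >=)."""

    max_rank: int = 1500
    cutoff: float = 0.4

    def __post_init__(self) -> None:
        if self.max_rank < 2:
            raise ValidationError("max_rank must be >= 2")
        if not 0 <= self.cutoff <= 1:
            raise ValidationError("cutoff must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreVector:
    """Per-cell signature scores; ``scores`` is indexed by cell id."""

    scores: pd.Series
    method: ScoreMethod
    signature_name: str
    cutoff: float | None = None
    high_flag: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.method is ScoreMethod.RANK_U:
            s = self.scores.to_numpy(float)
            if len(s) and (s.min() < 0 or s.max() > 1):
                raise ValidationError("rank scores must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterSummary:
    """Per (gene, cluster): percent of expressing cells and mean expression
    (zeros included), as encoded by dot-plot size and color."""

    frame: pd.DataFrame  # columns: gene, cluster, pct_expressed, mean_expr
    missing_genes: tuple[str, ...] = ()


def lognorm_layer(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Return a log-normalized view: pass-through for LOGNORM input, else
    log1p of library-size-normalized counts (counts per ``scale``)."""
    if expr.layer_tag is LayerTag.LOGNORM:
        return expr
    logger.info("normalizing raw counts (log1p CPM, scale=%g) before scoring", scale)
    libsize = np.asarray(expr.values.sum(axis=0)).ravel()
    libsize[libsize == 0] = 1.0
    X = expr.values.tocsc(copy=True).astype(float)
    X = X @ sparse.diags(scale / libsize)
    X.data = np.log1p(X.data)
    return ExpressionMatrix(expr.gene_ids, expr.cell_ids,
                            sparse.csr_matrix(X), LayerTag.LOGNORM)


def _match_genes(expr: ExpressionMatrix, sig: GeneSet) -> tuple[list[int], list[str]]:
    index = expr.gene_index()
    rows, missing = [], []
    for g in sig.genes:
        i = index.get(g.casefold())
        if i is None:
            missing.append(g)
        else:
            rows.append(i)
    return rows, missing


def summarize_by_cluster(expr: ExpressionMatrix, ann: CellAnnotation,
                         genes: GeneSet) -> ClusterSummary:
    """Exact percent-expressed and mean expression per (gene, cluster)."""
    ann.validate_against(expr)
    rows, missing = _match_genes(expr, genes)
    if missing:
        logger.warning("genes absent from matrix, skipped: %s", missing)
    if not rows:
        raise ValidationError("no signature gene found in the matrix")
    sub = expr.values[rows].toarray()
    names = [expr.gene_ids[i] for i in rows]
    clusters = ann.frame["cluster"].to_numpy()
    records = []
    for cl in pd.unique(clusters):
        cols = clusters == cl
        block = sub[:, cols]
        pct = 100.0 * (block > 0).mean(axis=1)
        mean = block.mean(axis=1)
        records.extend(
            {"gene": g, "cluster": cl, "pct_expressed": float(p),
             "mean_expr": float(m)}
            for g, p, m in zip(names, pct, mean))
    return ClusterSummary(pd.DataFrame(records), tuple(missing))


def marker_specificity(summary: ClusterSummary, gene: str,
                       target_cluster: str) -> float:
    """pct_expressed in the target cluster minus the best other cluster.

    +100 means the gene is exclusive to the target; 0 means no enrichment.
    """
    df = summary.frame
    sub = df[df["gene"].str.casefold() == gene.casefold()]
    if not len(sub):
        raise ValidationError(f"gene {gene!r} not in summary")
    tgt = sub[sub["cluster"] == target_cluster]
    if not len(tgt):
        raise ValidationError(f"cluster {target_cluster!r} not in summary")
    others = sub[sub["cluster"] != target_cluster]["pct_expressed"]
    other_max = float(others.max()) if len(others) else 0.0
    return float(tgt["pct_expressed"].iloc[0]) - other_max


def zscore_signature_score(expr: ExpressionMatrix, sig: GeneSet) -> ScoreVector:
    """Mean of per-gene z-scores (across cells) over the signature genes."""
    expr = lognorm_layer(expr)
    rows, missing = _match_genes(expr, sig)
    if missing:
        logger.warning("signature genes absent from matrix: %s", missing)
    if not rows:
        raise ValidationError("no signature gene found in the matrix")
    X = expr.values[rows].toarray().astype(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.any():
        raise ValidationError("all signature genes have zero variance")
    if not keep.all():
        dropped = [expr.gene_ids[rows[i]] for i in np.flatnonzero(~keep)]
        logger.warning("dropping zero-variance signature genes: %s", dropped)
    z = (X[keep] - mean[keep]) / sd[keep]
    scores = pd.Series(z.mean(axis=0), index=list(expr.cell_ids), name="score")
    return ScoreVector(scores, ScoreMethod.ZSCORE_MEAN, sig.name)


def rank_signature_score(expr: ExpressionMatrix, sig: GeneSet,
                         params: ScoreParams | None = None,
                         *, chunk_size: int = 512) -> ScoreVector:
    """Capped-rank U-statistic module score in [0, 1] per cell.

    With sparse data all zero-expression genes of a cell tie at one large
    average rank, which the cap truncates to ``max_rank + 1``; signature
    genes a cell does not express therefore contribute the worst possible
    rank rather than an arbitrary one.
    """
    params = params or ScoreParams()
    rows, missing = _match_genes(expr, sig)
    if missing:
        logger.warning("signature genes absent from matrix: %s", missing)
    if not rows:
        raise ValidationError("no signature gene matched the matrix")
    ns = len(rows)
    if ns > params.max_rank:
        raise ValidationError(
            f"signature size {ns} exceeds max_rank {params.max_rank}")
    n_cells = len(expr.cell_ids)
    scores = np.empty(n_cells)
    clipped = 0
    X = expr.values.tocsc()
    for start in range(0, n_cells, chunk_size):
        stop = min(start + chunk_size, n_cells)
        dense = X[:, start:stop].toarray().astype(float)
        ranks = rankdata(-dense, axis=0, method="average")
        ranks = np.where(ranks > params.max_rank, params.max_rank + 1, ranks)
        U = ranks[rows].sum(axis=0) - ns * (ns + 1) / 2.0
        raw = 1.0 - U / (ns * params.max_rank)
        clipped += int(((raw < 0) | (raw > 1)).sum())
        scores[start:stop] = np.clip(raw, 0.0, 1.0)
    if clipped:
        logger.info("clipped %d rank scores into [0, 1]", clipped)
    series = pd.Series(scores, index=list(expr.cell_ids), name="score")
    flags = pd.Series(scores >= params.cutoff, index=series.index, name="high_flag")
    return ScoreVector(series, ScoreMethod.RANK_U, sig.name,
                       cutoff=params.cutoff, high_flag=flags)


def threshold_cells(scores: ScoreVector, cutoff: float,
                    ann: CellAnnotation | None = None,
                    group_col: str = "cluster") -> ScoreVector:
    """Re-flag high-scoring cells at ``cutoff`` (inclusive >=); when an
    annotation is given, log the count of high cells per group."""
    if scores.method is not ScoreMethod.RANK_U:
        raise ValidationError("thresholding applies to rank scores")
    flags = scores.scores >= cutoff
    flags.name = "high_flag"
    if ann is not None:
        groups = ann.frame.loc[scores.scores.index, group_col]
        counts = flags.groupby(groups).sum()
        logger.info("high-scoring cells per %s at cutoff %.3g: %s",
                    group_col, cutoff, counts.to_dict())
    return replace(scores, cutoff=cutoff, high_flag=flags)


def high_fraction_by_group(scores: ScoreVector, groups: pd.Series) -> pd.Series:
    """Fraction of high-flagged cells per group label."""
    if scores.high_flag is None:
        raise ValidationError("score vector carries no high flags")
    return scores.high_flag.groupby(groups.loc[scores.high_flag.index]).mean()
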