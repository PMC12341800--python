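"""Core domain containers shared by every pipeline stage.

All gene-symbol comparisons in this package are case-insensitive (symbols
are matched after ``str.casefold`` and whitespace trimming) but the
first-seen spelling is preserved in outputs, so that counts are never
silently changed by alias resolution.  See :func:`canonicalize_symbols`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("consig")

MARKER_COLUMNS = (
    "study_id",
    "population_label",
    "cell_class",
    "gene",
    "fc_value",
    "fc_scale",
    "p_adj",
)


class CellClass(enum.Enum):
    NSC = "NSC"
    NP = "NP"
    NEUROBLAST = "NEUROBLAST"
    ASTROCYTE = "ASTROCYTE"
    OTHER = "OTHER"


class FCScale(enum.Enum):
    LINEAR = "LINEAR"
    LOG2 = "LOG2"
    LN = "LN"


class LayerTag(enum.Enum):
    COUNTS = "COUNTS"
    LOGNORM = "LOGNORM"


class ValidationError(ValueError):
    """Input violates a domain-type invariant."""


class FormatError(ValueError):
    """External file does not conform to its declared format."""


def canonicalize_symbols(genes: Iterable[str],
                         registry: dict[str, str] | None = None) -> list[str]:
    """Map symbols to a canonical spelling, case-insensitively.

    The first spelling seen for each casefolded key wins; later variant
    spellings are replaced by it (with a log message, since merging changes
    set sizes downstream).  A shared *registry* may be passed to keep the
    canonical spellings consistent across several gene lists.
    """
    if registry is None:
        registry = {}
    out = []
    for g in genes:
        g = g.strip()
        key = g.casefold()
        if key in registry:
            if registry[key] != g:
                logger.info("merging symbol spelling %r into %r", g, registry[key])
        else:
            registry[key] = g
        out.append(registry[key])
    return out


@dataclass(frozen=True)
class MarkerTable:
    """Per-study differential-expression records.

    ``records`` is a DataFrame with columns :data:`MARKER_COLUMNS`;
    ``cell_class`` holds :class:`CellClass` members and ``fc_scale``
    :class:`FCScale` members.  ``p_adj`` may be NaN (missing).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in MARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"marker table lacks columns: {missing}")
        if len(df):
            if (df["gene"].astype(str).str.strip() == "").any():
                raise ValidationError("empty gene symbol in marker table")
            if (df["study_id"].astype(str).str.strip() == "").any():
                raise ValidationError("empty study_id in marker table")
            key = df[["study_id", "population_label", "gene"]].apply(
                lambda s: s.astype(str).str.casefold() if s.name == "gene" else s)
            if key.duplicated().any():
                dups = df.loc[key.duplicated(), ["study_id", "population_label", "gene"]]
                raise ValidationError(
                    f"duplicate (study, population, gene) records: {dups.values.tolist()[:5]}")
            scales = df.groupby("study_id")["fc_scale"].nunique()
            if (scales > 1).any():
                bad = scales[scales > 1].index.tolist()
                raise ValidationError(f"mixed fc_scale within study: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def studies(self) -> list[str]:
        return list(dict.fromkeys(self.records["study_id"]))


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered gene collection with optional per-gene subset tags."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    subset_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        keys = [g.casefold() for g in self.genes]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")
        if self.subset_labels is not None and len(self.subset_labels) != len(self.genes):
            raise ValidationError("subset_labels length must match genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.casefold() in {g.casefold() for g in self.genes}


@dataclass(frozen=True)
class GeneModuleSet:
    """Ordered named modules (e.g. age-conserved expression programs)."""

    modules: tuple[GeneSet, ...]
    disjoint: bool = False

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValidationError("module names must be unique")
        if self.disjoint:
            seen: set[str] = set()
            for m in self.modules:
                keys = {g.casefold() for g in m.genes}
                if seen & keys:
                    raise ValidationError(
                        f"disjoint flag set but genes shared: {sorted(seen & keys)[:5]}")
                seen |= keys

    def __iter__(self):
        return iter(self.modules)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cells expression values (sparse CSR), one layer per object."""

    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    values: sparse.csr_matrix
    layer_tag: LayerTag = LayerTag.COUNTS

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative expression values")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValidationError("non-finite expression values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        """Casefolded symbol -> row index."""
        return {g.casefold(): i for i, g in enumerate(self.gene_ids)}

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        return (self.gene_ids == other.gene_ids
                and self.cell_ids == other.cell_ids
                and self.layer_tag == other.layer_tag
                and self.shape == other.shape
                and abs(self.values - other.values).max() <= atol)


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata; index is cell_id, columns include ``cluster`` and
    ``study_id`` and optionally ``age_group``, ``pseudotime``, ``x``, ``y``."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("cluster", "study_id"):
            if col not in self.frame.columns:
                raise ValidationError(f"cell annotation lacks column {col!r}")
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate cell ids in annotation")
        if "pseudotime" in self.frame.columns:
            t = self.frame["pseudotime"].dropna()
            if len(t) and not np.all(np.isfinite(t.to_numpy(float))):
                raise ValidationError("non-finite pseudotime values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cell_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        if tuple(self.frame.index) != expr.cell_ids:
            raise ValidationError("annotation cell ids do not match expression matrix")
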