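"""Signed panel activity scores, the gene x model matrix, and activation calls.

The score formalizes the visual reading of a signed marker-panel heatmap.
For a panel with genes g carrying sign s_g (+1 induced, -1 repressed by the
pathway) and measured log2 fold changes x_g, the activity score of one model
is the mean signed effect over the significant panel genes:

    A = (1 / n_sig) * sum over significant g of s_g * x_g

Non-significant genes contribute nothing (absence of evidence, not evidence
of absence); genes that were not found or not expressed are excluded from
all denominators but reported in coverage.  Concordance fractions f_up and
f_down (fractions of significant genes with s_g * x_g > 0 and < 0) guard the
discrete call against panels that split — the situation where half of the
targets argue activation and half argue the opposite, which is reported as
``inconclusive`` rather than forced to a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .de import CellValue, DETable, query_gene
from .registry import MarkerGene, Panel

__all__ = [
    "ActivityScore",
    "CallParams",
    "PathwayCall",
    "ExpressionMatrix",
    "build_matrix",
    "score_panel",
    "call_pathway",
    "summarize_calls",
]

CALL_STATES = ("activated", "reduced", "no_change", "inconclusive")


@dataclass(frozen=True)
class ActivityScore:
    """Signed mean panel score plus evidence tallies for one (pathway, model)."""

    pathway: str
    model_id: str
    score: float
    n_panel: int
    n_measured: int
    n_significant: int
    f_up: float
    f_down: float

    def __post_init__(self) -> None:
        if not (self.n_significant <= self.n_measured <= self.n_panel):
            raise ValueError(
                f"{self.pathway}/{self.model_id}: evidence counts out of order "
                f"({self.n_significant} <= {self.n_measured} <= {self.n_panel})"
            )


@dataclass(frozen=True)
class CallParams:
    """Decision thresholds for discrete activation calls.

    tau
        Minimum |score| (log2 units) to call a direction.
    min_genes
        Minimum number of significant panel genes for any directional call.
    concord_frac
        Minimum fraction of significant genes agreeing with the direction.
    conflict_frac
        If both f_up and f_down reach this, the panel is split and the call
        is ``inconclusive``.
    """

    tau: float = 0.5
    min_genes: int = 3
    concord_frac: float = 0.6
    conflict_frac: float = 0.4

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        for name in ("concord_frac", "conflict_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class PathwayCall:
    """Discrete activation state with confidence for one (pathway, model)."""

    pathway: str
    model_id: str
    state: str
    confidence: str  # high | low
    evidence: ActivityScore

    def __post_init__(self) -> None:
        if self.state not in CALL_STATES:
            raise ValueError(f"bad call state {self.state!r}")
        if self.confidence not in ("high", "low"):
            raise ValueError(f"bad confidence {self.confidence!r}")


@dataclass
class ExpressionMatrix:
    """Complete panel-gene x model matrix of :class:`CellValue` cells.

    Rows keep registry order and panel grouping; columns keep the metadata
    order the tables were supplied in.
    """

    rows: list[tuple[str, str]]  # (panel label, gene symbol)
    cols: list[str]  # model ids
    cells: dict[tuple[str, str], CellValue]  # (symbol, model_id) -> cell
    scoring_scope: dict[tuple[str, str], bool] = field(default_factory=dict)

    def cell(self, symbol: str, model_id: str) -> CellValue:
        return self.cells[(symbol, model_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame: one row per (panel, gene, model) cell."""
        recs = []
        for panel_label, symbol in self.rows:
            for model_id in self.cols:
                c = self.cells[(symbol, model_id)]
                recs.append(
                    {
                        "panel": panel_label,
                        "gene": symbol,
                        "model": model_id,
                        "status": c.status,
                        "log2fc": c.value,
                        "in_scope": self.scoring_scope.get((symbol, model_id), True),
                    }
                )
        return pd.DataFrame(recs)


def _in_tissue_scope(gene: MarkerGene, tissue: str) -> bool:
    return gene.tissue_scope == "any" or gene.tissue_scope == tissue


def build_matrix(
    panels: Sequence[Panel],
    tables: Sequence[DETable],
    tissue_filter: bool = True,
) -> ExpressionMatrix:
    """Assemble the display/scoring matrix for a set of panels and models.

    Every (gene, model) pair receives exactly one cell.  With
    ``tissue_filter`` on, genes whose ``tissue_scope`` does not match a
    model's tissue stay visible but are flagged out of that column's scoring
    scope (fate determinants of the other disc type are not evidence).
    """
    model_ids = [t.meta.model_id for t in tables]
    if len(set(model_ids)) != len(model_ids):
        raise ValueError("model_ids must be unique across tables")

    rows: list[tuple[str, str]] = []
    seen_row: set[tuple[str, str]] = set()
    cells: dict[tuple[str, str], CellValue] = {}
    scope: dict[tuple[str, str], bool] = {}

    for panel in panels:
        scoped_any = {t.meta.model_id: 0 for t in tables}
        for gene in panel.genes:
            key = (panel.label, gene.symbol)
            if key not in seen_row:
                rows.append(key)
                seen_row.add(key)
            for table in tables:
                mid = table.meta.model_id
                cells[(gene.symbol, mid)] = query_gene(table, gene.symbol)
                in_scope = (not tissue_filter) or _in_tissue_scope(
                    gene, table.meta.tissue
                )
                # a gene shared across panels stays in scope if any panel
                # membership keeps it there
                scope[(gene.symbol, mid)] = scope.get((gene.symbol, mid), False) or in_scope
                scoped_any[mid] += in_scope
        for mid, n in scoped_any.items():
            if tissue_filter and n == 0:
                raise ValueError(
                    f"panel {panel.label} is empty after tissue filtering "
                    f"for model {mid}"
                )
    return ExpressionMatrix(rows=rows, cols=model_ids, cells=cells, scoring_scope=scope)


def score_panel(
    panel: Panel,
    table: DETable,
    *,
    include_roles: Sequence[str] = ("target",),
    include_multi_pathway: bool = True,
    tissue_filter: bool = True,
) -> ActivityScore:
    """Compute the signed mean activity score of one panel in one model.

    Only genes with a role in ``include_roles`` (default: validated targets)
    enter the score; tissue-scoped genes outside the model's tissue are
    dropped; ``include_multi_pathway=False`` recomputes the score without
    shared (cyan) readouts as a sensitivity analysis.  A panel with no
    significant gene scores exactly 0.
    """
    genes = [
        g
        for g in panel.genes
        if g.role in include_roles
        and (include_multi_pathway or not g.multi_pathway)
        and ((not tissue_filter) or _in_tissue_scope(g, table.meta.tissue))
    ]
    if not genes:
        raise ValueError(
            f"panel {panel.label} has no scoreable genes after filtering"
        )

    n_measured = 0
    n_significant = 0
    total = 0.0
    n_up = 0
    n_down = 0
    for g in genes:
        cell = query_gene(table, g.symbol)
        if cell.status in ("significant", "non_significant"):
            n_measured += 1
        if cell.status == "significant":
            n_significant += 1
            contrib = g.sign * cell.value
            total += contrib
            if contrib > 0:
                n_up += 1
            elif contrib < 0:
                n_down += 1

    score = total / n_significant if n_significant else 0.0
    f_up = n_up / n_significant if n_significant else 0.0
    f_down = n_down / n_significant if n_significant else 0.0
    return ActivityScore(
        pathway=panel.pathway,
        model_id=table.meta.model_id,
        score=score,
        n_panel=len(genes),
        n_measured=n_measured,
        n_significant=n_significant,
        f_up=f_up,
        f_down=f_down,
    )


def call_pathway(
    score: ActivityScore,
    params: CallParams = CallParams(),
    n_supporting_models: int = 1,
) -> PathwayCall:
    """Turn an activity score into a discrete activation call.

    Decision order: insufficient evidence -> ``no_change``; a split panel
    (both concordance fractions past ``conflict_frac``) -> ``inconclusive``;
    then a directional call requires both the score magnitude (>= tau) and
    gene-level concordance (>= concord_frac).  Confidence is ``low`` when
    the conclusion rests on a single dataset or on fewer than ``min_genes``
    significant genes.
    """
    if n_supporting_models < 1:
        raise ValueError("n_supporting_models must be >= 1")
    if score.n_significant < params.min_genes:
        state = "no_change"
    elif score.f_up >= params.conflict_frac and score.f_down >= params.conflict_frac:
        state = "inconclusive"
    elif score.score >= params.tau and score.f_up >= params.concord_frac:
        state = "activated"
    elif score.score <= -params.tau and score.f_down >= params.concord_frac:
        state = "reduced"
    else:
        state = "no_change"
    low = n_supporting_models == 1 or score.n_significant < params.min_genes
    return PathwayCall(
        pathway=score.pathway,
        model_id=score.model_id,
        state=state,
        confidence="low" if low else "high",
        evidence=score,
    )


def summarize_calls(calls: Iterable[PathwayCall]) -> pd.DataFrame:
    """Dense pathway x model call matrix, cells "state/confidence"."""
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to summarize")
    seen: set[tuple[str, str]] = set()
    pathways: list[str] = []
    models: list[str] = []
    for c in calls:
        key = (c.pathway, c.model_id)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
        if c.pathway not in pathways:
            pathways.append(c.pathway)
        if c.model_id not in models:
            models.append(c.model_id)
    mat = pd.DataFrame(index=pathways, columns=models, dtype=object)
    for c in calls:
        mat.loc[c.pathway, c.model_id] = f"{c.state}/{c.confidence}"
    mat.index.name = "pathway"
    return mat
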