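"""Reading, harmonizing and querying differential-expression result tables.

A DE table is the published per-model summary of a tumor-vs-reference
comparison: gene symbol, log2 fold change, and a significance value (raw
p-value and/or adjusted p-value).  Symbols are harmonized against the panel
registry's alias table on read.  Querying a gene yields one of four statuses
that the downstream matrix and scoring layers share:

``significant``
    measured, with its significance value strictly below the dataset's
    threshold; carries a log2FC.
``non_significant``
    measured but above threshold; log2FC retained for display only.
``not_found``
    absent from the table (annotation-release differences; never imputed).
``not_expressed``
    present in the data but with zero reads ("n.e."); no log2FC exists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .registry import PanelRegistry, resolve_symbol

__all__ = [
    "DERecord",
    "ModelMetadata",
    "DETable",
    "CellValue",
    "DEFormatError",
    "read_de_table",
    "write_de_table",
    "query_gene",
]

logger = logging.getLogger(__name__)

TISSUES = ("eye", "wing", "leg", "antenna")
TUMOR_CLASSES = ("neoplastic", "hyperplastic", "PRC1")
REFERENCE_TYPES = ("wildtype_control", "internal_neighbors")
STATUSES = ("significant", "non_significant", "not_found", "not_expressed")

#: Tokens in a log2FC / flag column that mark a zero-read gene.
DEFAULT_NE_TOKENS = ("n.e.", "n.e", "ne", "NE", "not_expressed")


class DEFormatError(ValueError):
    """Raised for malformed DE input files (missing columns, bad values)."""


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result in one model."""

    symbol: str
    log2fc: Optional[float] = None
    pvalue: Optional[float] = None
    padj: Optional[float] = None
    status: str = "measured"  # measured | not_expressed

    def __post_init__(self) -> None:
        if self.status not in ("measured", "not_expressed"):
            raise ValueError(f"bad DERecord status {self.status!r}")
        if self.status == "not_expressed" and self.log2fc is not None:
            raise ValueError(
                f"{self.symbol}: not_expressed records carry no log2fc"
            )
        if self.status == "measured":
            if self.log2fc is None or not math.isfinite(self.log2fc):
                raise ValueError(f"{self.symbol}: measured record needs finite log2fc")
            if self.pvalue is None and self.padj is None:
                raise ValueError(
                    f"{self.symbol}: measured record needs pvalue or padj"
                )
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.symbol}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ModelMetadata:
    """Provenance and significance policy for one tumor model dataset.

    ``alpha`` and ``significance_field`` encode the dataset's published
    cut-off: the default policy is raw p < 0.05 with no fold-change
    threshold; datasets published with a stricter adjusted-p cut-off (the
    FACS-sorted internal-neighbor design) use padj with their own alpha.
    """

    model_id: str
    genotype: str
    tissue: str
    tumor_class: str
    timepoint: Optional[str] = None
    reference_type: str = "wildtype_control"
    alpha: float = 0.05
    significance_field: str = "pvalue"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"{self.model_id}: unknown tissue {self.tissue!r}")
        if self.tumor_class not in TUMOR_CLASSES:
            raise ValueError(
                f"{self.model_id}: unknown tumor_class {self.tumor_class!r}"
            )
        if self.reference_type not in REFERENCE_TYPES:
            raise ValueError(
                f"{self.model_id}: unknown reference_type {self.reference_type!r}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"{self.model_id}: alpha must be in (0, 1)")
        if self.significance_field not in ("pvalue", "padj"):
            raise ValueError(
                f"{self.model_id}: significance_field must be pvalue or padj"
            )


@dataclass
class DETable:
    """One model's harmonized DE results keyed by canonical symbol."""

    meta: ModelMetadata
    records: dict[str, DERecord] = field(default_factory=dict)
    unresolved: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CellValue:
    """One (gene, model) cell: a status plus a log2FC when one exists."""

    status: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad cell status {self.status!r}")
        has_value = self.value is not None
        needs_value = self.status in ("significant", "non_significant")
        if has_value != needs_value:
            raise ValueError(
                f"status {self.status!r} and value {self.value!r} inconsistent"
            )


# ---------------------------------------------------------------------------
# reading

def _significance_value(rec: DERecord, meta: ModelMetadata) -> Optional[float]:
    primary = getattr(rec, meta.significance_field)
    if primary is not None:
        return primary
    # fall back to whichever significance column the row does carry
    return rec.padj if meta.significance_field == "pvalue" else rec.pvalue


def _better(a: DERecord, b: DERecord, meta: ModelMetadata) -> DERecord:
    """Collapse duplicate rows for one gene: smallest significance wins."""
    if a.status == "not_expressed":
        return b if b.status == "measured" else a
    if b.status == "not_expressed":
        return a
    sa = _significance_value(a, meta)
    sb = _significance_value(b, meta)
    if sa is None:
        return b
    if sb is None:
        return a
    return a if sa <= sb else b


def read_de_table(
    path: Union[str, Path],
    column_map: Mapping[str, str],
    meta: ModelMetadata,
    registry: PanelRegistry,
    *,
    sep: Optional[str] = None,
    ne_tokens: Sequence[str] = DEFAULT_NE_TOKENS,
) -> DETable:
    """Read a delimited DE table and harmonize its gene symbols.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Maps roles to column names; requires ``gene`` and ``log2fc``, and at
        least one of ``pvalue`` / ``padj``.  Optional ``ne_flag`` names a
        column whose truthy/token values mark zero-read genes.
    meta
        Dataset metadata (carries the significance policy).
    registry
        Panel registry used for symbol resolution; unresolvable symbols are
        kept under their raw spelling and reported in ``DETable.unresolved``.
    sep
        Field separator; inferred from the file extension when omitted
        (``.csv`` -> comma, otherwise tab).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    if "gene" not in column_map or "log2fc" not in column_map:
        raise DEFormatError("column_map must name 'gene' and 'log2fc' columns")
    if "pvalue" not in column_map and "padj" not in column_map:
        raise DEFormatError("column_map must name a 'pvalue' or 'padj' column")

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for role, col in column_map.items():
        if col not in df.columns:
            raise DEFormatError(f"mapped column {col!r} (role {role}) not in header")

    ne_set = {t.casefold() for t in ne_tokens}
    records: dict[str, DERecord] = {}
    unresolved: list[str] = []
    n_dup = 0

    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        raw_symbol = str(row[column_map["gene"]]).strip()
        if not raw_symbol:
            continue
        canonical = resolve_symbol(raw_symbol, registry)
        if canonical is None:
            canonical = raw_symbol
            unresolved.append(raw_symbol)

        lfc_raw = str(row[column_map["log2fc"]]).strip()
        ne_flag = lfc_raw.casefold() in ne_set
        if "ne_flag" in column_map:
            flag_raw = str(row[column_map["ne_flag"]]).strip().casefold()
            ne_flag = ne_flag or flag_raw in ne_set or flag_raw in ("1", "true", "yes")

        if ne_flag:
            rec = DERecord(symbol=canonical, status="not_expressed")
        else:
            try:
                log2fc = float(lfc_raw)
            except ValueError:
                raise DEFormatError(
                    f"{path.name} line {i}: non-numeric log2fc {lfc_raw!r} "
                    f"for gene {raw_symbol!r}"
                ) from None
            rec = DERecord(
                symbol=canonical,
                log2fc=log2fc,
                pvalue=_parse_optional_float(row, column_map, "pvalue", path, i),
                padj=_parse_optional_float(row, column_map, "padj", path, i),
            )
        if canonical in records:
            n_dup += 1
            rec = _better(records[canonical], rec, meta)
        records[canonical] = rec

    logger.info(
        "%s: read %d rows -> %d genes (%d duplicates collapsed, %d unresolved symbols)",
        path.name, len(df), len(records), n_dup, len(unresolved),
    )
    return DETable(meta=meta, records=records, unresolved=tuple(unresolved))


def _parse_optional_float(
    row: Mapping[str, str],
    column_map: Mapping[str, str],
    role: str,
    path: Path,
    line: int,
) -> Optional[float]:
    if role not in column_map:
        return None
    raw = str(row[column_map[role]]).strip()
    if raw in ("", "NA", "na", "NaN", "nan", "."):
        return None
    try:
        return float(raw)
    except ValueError:
        raise DEFormatError(
            f"{path.name} line {line}: non-numeric {role} {raw!r}"
        ) from None


def write_de_table(table: DETable, path: Union[str, Path]) -> None:
    """Write the canonical-symbol normalized form as TSV."""
    rows = [
        {
            "gene": rec.symbol,
            "log2fc": "" if rec.log2fc is None else repr(rec.log2fc),
            "pvalue": "" if rec.pvalue is None else repr(rec.pvalue),
            "padj": "" if rec.padj is None else repr(rec.padj),
            "status": rec.status,
        }
        for rec in table.records.values()
    ]
    pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "padj", "status"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# querying

def query_gene(table: DETable, symbol: str) -> CellValue:
    """Look up one gene's cell status in a model's DE table.

    Significance is strict: a gene is ``significant`` iff its dataset's
    significance value is strictly below the dataset's alpha; a value equal
    to alpha is non-significant.
    """
    rec = table.records.get(symbol)
    if rec is None:
        return CellValue(status="not_found")
    if rec.status == "not_expressed":
        return CellValue(status="not_expressed")
    sig = _significance_value(rec, table.meta)
    if sig is not None and sig < table.meta.alpha:
        return CellValue(status="significant", value=rec.log2fc)
    return CellValue(status="non_significant", value=rec.log2fc)
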