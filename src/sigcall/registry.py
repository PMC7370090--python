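"""Curated, sign-annotated marker-gene panels and gene-alias tables.

Each signaling pathway is represented by a panel of validated transcriptional
readout genes.  A gene's ``sign`` records how the pathway drives it: +1 for a
target induced by pathway activity, -1 for a target the pathway represses (or
a negative marker whose induction indicates low activity, e.g. *brk* for Dpp).
Pathway components themselves (nuclear factors such as Mad, yki, Stat92E) are
kept for display but excluded from activity scoring by default, because their
transcript levels are not activity readouts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import yaml

__all__ = [
    "MarkerGene",
    "Panel",
    "PanelRegistry",
    "ValidationIssue",
    "ValidationReport",
    "RegistryError",
    "SCOREABLE_PATHWAYS",
    "ROLES",
    "TISSUE_SCOPES",
    "load_registry",
    "write_registry",
    "resolve_symbol",
    "validate_registry",
]

#: Pathways that appear in the cross-model summary and must carry a
#: non-empty scoreable panel.
SCOREABLE_PATHWAYS = (
    "EGFR_Ras",
    "Dpp",
    "Hh",
    "Wg",
    "Hippo_Yki",
    "JNK",
    "JAK_STAT",
    "Notch",
)

#: All pathway / panel labels the registry may use.
PATHWAYS = SCOREABLE_PATHWAYS + ("fate", "TF_set", "apoptosis_cell_cycle")

ROLES = ("target", "nuclear_factor", "ligand", "fate_determinant", "other")
TISSUE_SCOPES = ("any", "eye", "wing")

#: Roles whose genes contribute to the activity score by default.
SCORED_ROLES = ("target",)


class RegistryError(ValueError):
    """Raised when a registry file is malformed or violates an invariant."""


@dataclass(frozen=True)
class MarkerGene:
    """One sign-annotated pathway readout gene."""

    symbol: str
    sign: int
    aliases: tuple[str, ...] = ()
    multi_pathway: bool = False
    role: str = "target"
    tissue_scope: str = "any"

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise RegistryError("marker gene symbol must be non-empty")
        if self.sign not in (1, -1):
            raise RegistryError(
                f"gene {self.symbol!r}: sign must be +1 or -1, got {self.sign!r}"
            )
        if self.role not in ROLES:
            raise RegistryError(f"gene {self.symbol!r}: unknown role {self.role!r}")
        if self.tissue_scope not in TISSUE_SCOPES:
            raise RegistryError(
                f"gene {self.symbol!r}: unknown tissue_scope {self.tissue_scope!r}"
            )

    @property
    def scored(self) -> bool:
        """Whether this gene contributes to the activity score by default."""
        return self.role in SCORED_ROLES


@dataclass(frozen=True)
class Panel:
    """An ordered marker panel for one pathway (optionally a sub-panel)."""

    pathway: str
    genes: tuple[MarkerGene, ...]
    sub_panel: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise RegistryError(f"unknown pathway {self.pathway!r}")
        seen: set[str] = set()
        for g in self.genes:
            if g.symbol in seen:
                raise RegistryError(
                    f"panel {self.label}: duplicate symbol {g.symbol!r}"
                )
            seen.add(g.symbol)

    @property
    def label(self) -> str:
        return f"{self.pathway}/{self.sub_panel}" if self.sub_panel else self.pathway

    @property
    def scoreable_genes(self) -> tuple[MarkerGene, ...]:
        return tuple(g for g in self.genes if g.scored)


@dataclass(frozen=True)
class PanelRegistry:
    """The full panel collection plus the alias -> canonical symbol table."""

    panels: tuple[Panel, ...]
    alias_map: dict[str, str] = field(default_factory=dict)
    version: str = "0"

    def __post_init__(self) -> None:
        canon = self.canonical_symbols()
        for alias, target in self.alias_map.items():
            if target not in canon:
                raise RegistryError(
                    f"alias {alias!r} maps to unknown canonical symbol {target!r}"
                )

    def canonical_symbols(self) -> set[str]:
        return {g.symbol for p in self.panels for g in p.genes}

    def iter_panels(self, pathway: Optional[str] = None) -> Iterator[Panel]:
        for p in self.panels:
            if pathway is None or p.pathway == pathway:
                yield p

    def pathway_panels(self, pathway: str) -> tuple[Panel, ...]:
        return tuple(self.iter_panels(pathway))

    def merged_panel(self, pathway: str) -> Panel:
        """All sub-panels of a pathway collapsed into one panel.

        A symbol appearing in several sub-panels is kept once (first
        occurrence wins), so the merged panel satisfies the per-panel
        uniqueness invariant.
        """
        genes: list[MarkerGene] = []
        seen: set[str] = set()
        for p in self.iter_panels(pathway):
            for g in p.genes:
                if g.symbol not in seen:
                    genes.append(g)
                    seen.add(g.symbol)
        if not genes:
            raise RegistryError(f"no panel registered for pathway {pathway!r}")
        return Panel(pathway=pathway, genes=tuple(genes))


# ---------------------------------------------------------------------------
# symbol resolution

def resolve_symbol(query: str, registry: PanelRegistry) -> Optional[str]:
    """Map a (possibly aliased) gene symbol to its canonical registry symbol.

    Matching is case-insensitive after whitespace trimming; canonical symbols
    take precedence over aliases.  Returns ``None`` when the symbol is not
    known to the registry — an unresolved symbol is a value, not an error.
    """
    q = query.strip().casefold()
    if not q:
        raise ValueError("query symbol must be non-empty")
    canon = getattr(registry, "_canon_index", None)
    if canon is None:
        canon = {s.casefold(): s for s in sorted(registry.canonical_symbols())}
        alias = {}
        for a, target in registry.alias_map.items():
            alias.setdefault(a.strip().casefold(), target)
        object.__setattr__(registry, "_canon_index", canon)
        object.__setattr__(registry, "_alias_index", alias)
    if q in canon:
        return canon[q]
    return registry._alias_index.get(q)  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# loading / writing

def _parse_gene(raw: dict, panel_label: str) -> MarkerGene:
    if not isinstance(raw, dict) or "symbol" not in raw:
        raise RegistryError(f"panel {panel_label}: gene entry missing 'symbol'")
    try:
        return MarkerGene(
            symbol=str(raw["symbol"]),
            sign=int(raw.get("sign", 1)),
            aliases=tuple(str(a) for a in raw.get("aliases", ())),
            multi_pathway=bool(raw.get("multi_pathway", False)),
            role=str(raw.get("role", "target")),
            tissue_scope=str(raw.get("tissue_scope", "any")),
        )
    except RegistryError as e:
        raise RegistryError(f"panel {panel_label}: {e}") from None


def _registry_from_mapping(doc: dict) -> PanelRegistry:
    if not isinstance(doc, dict) or "panels" not in doc:
        raise RegistryError("registry file must contain a top-level 'panels' list")
    panels: list[Panel] = []
    for p in doc["panels"]:
        if "pathway" not in p:
            raise RegistryError("panel entry missing 'pathway'")
        label = f"{p['pathway']}/{p.get('sub_panel')}" if p.get("sub_panel") else p["pathway"]
        genes = tuple(_parse_gene(g, label) for g in p.get("genes", ()))
        panels.append(
            Panel(
                pathway=str(p["pathway"]),
                sub_panel=p.get("sub_panel"),
                genes=genes,
                notes=str(p.get("notes", "")),
            )
        )
    alias_map: dict[str, str] = {}
    for alias, target in dict(doc.get("alias_map", {})).items():
        alias_map[str(alias)] = str(target)
    # aliases declared on the genes themselves feed the same table
    for panel in panels:
        for g in panel.genes:
            for a in g.aliases:
                prev = alias_map.get(a)
                if prev is not None and prev != g.symbol:
                    raise RegistryError(
                        f"alias {a!r} maps to both {prev!r} and {g.symbol!r}"
                    )
                alias_map[a] = g.symbol
    return PanelRegistry(
        panels=tuple(panels),
        alias_map=alias_map,
        version=str(doc.get("version", "0")),
    )


def load_registry(path: Union[str, Path, None] = None) -> PanelRegistry:
    """Load and validate a panel registry.

    With no path the curated default registry shipped with the package is
    loaded.  Any invariant violation raises :class:`RegistryError` naming the
    first offending panel or gene.
    """
    if path is None:
        ref = importlib.resources.files("sigcall.data") / "default_registry.yaml"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise RegistryError(f"registry file is not valid YAML: {e}") from e
    registry = _registry_from_mapping(doc)
    report = validate_registry(registry)
    if not report.ok:
        raise RegistryError(report.failures[0].message)
    return registry


def write_registry(registry: PanelRegistry, path: Union[str, Path]) -> None:
    """Serialize a registry back to YAML (round-trips with load_registry)."""
    doc = {
        "version": registry.version,
        "panels": [
            {
                "pathway": p.pathway,
                **({"sub_panel": p.sub_panel} if p.sub_panel else {}),
                **({"notes": p.notes} if p.notes else {}),
                "genes": [
                    {
                        "symbol": g.symbol,
                        "sign": g.sign,
                        **({"aliases": list(g.aliases)} if g.aliases else {}),
                        **({"multi_pathway": True} if g.multi_pathway else {}),
                        **({"role": g.role} if g.role != "target" else {}),
                        **({"tissue_scope": g.tissue_scope} if g.tissue_scope != "any" else {}),
                    }
                    for g in p.genes
                ],
            }
            for p in registry.panels
        ],
        "alias_map": {
            a: t
            for a, t in sorted(registry.alias_map.items())
            if t != _gene_declared_alias_target(registry, a)
        },
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def _gene_declared_alias_target(registry: PanelRegistry, alias: str) -> Optional[str]:
    for p in registry.panels:
        for g in p.genes:
            if alias in g.aliases:
                return g.symbol
    return None


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class ValidationIssue:
    invariant: str
    message: str


@dataclass
class ValidationReport:
    """Per-panel tallies plus pass/fail per registry invariant."""

    panel_counts: dict[str, dict[str, int]]
    failures: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.failures

    def summary(self) -> str:
        lines = []
        for label, c in self.panel_counts.items():
            lines.append(
                f"{label}: {c['n_genes']} genes "
                f"({c['n_positive']}+ / {c['n_negative']}-, "
                f"{c['n_multi_pathway']} multi-pathway, {c['n_scored']} scored)"
            )
        if self.ok:
            lines.append("all invariants pass")
        else:
            for f in self.failures:
                lines.append(f"FAIL [{f.invariant}] {f.message}")
        return "\n".join(lines)


def validate_registry(registry: PanelRegistry) -> ValidationReport:
    """Check registry invariants; failures are reported, never raised."""
    failures: list[ValidationIssue] = []
    counts: dict[str, dict[str, int]] = {}

    for panel in registry.panels:
        counts[panel.label] = {
            "n_genes": len(panel.genes),
            "n_positive": sum(1 for g in panel.genes if g.sign == 1),
            "n_negative": sum(1 for g in panel.genes if g.sign == -1),
            "n_multi_pathway": sum(1 for g in panel.genes if g.multi_pathway),
            "n_scored": len(panel.scoreable_genes),
        }

    have = {p.pathway for p in registry.panels}
    for pw in SCOREABLE_PATHWAYS:
        if pw not in have:
            failures.append(
                ValidationIssue(
                    "summary_pathway_panel",
                    f"summary pathway without panel: {pw}",
                )
            )
        else:
            n_scored = sum(
                len(p.scoreable_genes) for p in registry.iter_panels(pw)
            )
            if n_scored == 0:
                failures.append(
                    ValidationIssue(
                        "summary_pathway_panel",
                        f"pathway {pw} has no scoreable genes",
                    )
                )

    def _subpanel(pathway: str, sub: str) -> Optional[Panel]:
        for p in registry.iter_panels(pathway):
            if p.sub_panel == sub:
                return p
        return None

    bhlh = _subpanel("Notch", "canonical_bHLH")
    if bhlh is not None and len(bhlh.genes) != 13:
        failures.append(
            ValidationIssue(
                "notch_bhlh_size",
                f"Notch canonical_bHLH sub-panel has {len(bhlh.genes)} genes, expected 13",
            )
        )
    noncanon = _subpanel("Notch", "non_canonical")
    if noncanon is not None and len(noncanon.genes) != 9:
        failures.append(
            ValidationIssue(
                "notch_noncanonical_size",
                f"Notch non_canonical sub-panel has {len(noncanon.genes)} genes, expected 9",
            )
        )

    # alias map functional and consistent with canonical symbols
    canon = registry.canonical_symbols()
    lower_canon = {s.casefold(): s for s in canon}
    for alias, target in registry.alias_map.items():
        key = alias.strip().casefold()
        if key in lower_canon and lower_canon[key] != target:
            failures.append(
                ValidationIssue(
                    "alias_shadows_canonical",
                    f"alias {alias!r} shadows canonical symbol {lower_canon[key]!r}",
                )
            )
    return ValidationReport(panel_counts=counts, failures=failures)
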