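"""Seeded synthetic DE tables with known per-pathway activation structure.

The generator emulates the *summary* statistics a published differential-
expression table reports — log2 fold changes, significance flags and
p-values — not the underlying read counts.  Pathway activation manifests
exactly as the scoring model assumes real activation does: a coordinated
signed shift of the pathway's target panel.  For a gene g with panel sign
s_g in a model whose pathway state has direction d (+1 activated, -1
reduced, 0 neutral, per-gene random +/-1 when conflicting):

    x_g = d * s_g * mu + Normal(0, sigma)

A truly affected gene (d != 0) is flagged significant with probability
``power``; a null gene with probability ``alpha`` (the false-positive rate).
Flagged genes receive a p-value uniform on [0, dataset alpha), unflagged
ones uniform on [dataset alpha, 1], so the strict p < alpha gate downstream
recovers the flags exactly.  Genes can drop out of the table entirely
(``dropout`` -> not_found) or appear with zero reads (``ne_rate`` ->
not_expressed), and ``n_background`` null non-panel genes pad each table.

Genes shared between pathways respond to the strongest of their pathways'
states (any non-neutral state beats neutral; ties resolve in registry
pathway order); an additive response mode is available as a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .activity import CallParams, PathwayCall, call_pathway, score_panel
from .de import DERecord, DETable, ModelMetadata, write_de_table
from .registry import SCOREABLE_PATHWAYS, PanelRegistry

__all__ = [
    "SimulationTruth",
    "SimulatedExperiment",
    "RecoveryReport",
    "simulate_experiment",
    "call_experiment",
    "evaluate_recovery",
]

TRUTH_STATES = ("activated", "reduced", "neutral", "conflicting")

#: Expected call for each true state.
EXPECTED_CALL = {
    "activated": "activated",
    "reduced": "reduced",
    "neutral": "no_change",
    "conflicting": "inconclusive",
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth activation states and noise model for one experiment.

    Defaults reflect a clearly-activated pathway in a well-powered bulk
    dataset: a 4-fold mean shift (mu = 2 log2 units), moderate per-gene
    scatter, 90% detection power, 5% false-positive rate, and a 10% chance
    a panel gene is missing from a given annotation release.
    """

    states: Mapping[tuple[str, str], str]  # (model_id, pathway) -> state
    mu: float = 2.0
    sigma: float = 0.5
    power: float = 0.9
    alpha: float = 0.05
    dropout: float = 0.1
    ne_rate: float = 0.0
    n_background: int = 200
    seed: int = 0
    additive_crosstalk: bool = False

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for name in ("power", "alpha", "dropout", "ne_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        for (model_id, pathway), state in self.states.items():
            if state not in TRUTH_STATES:
                raise ValueError(
                    f"unknown truth state {state!r} for ({model_id}, {pathway})"
                )


@dataclass
class SimulatedExperiment:
    truth: SimulationTruth
    models: list[ModelMetadata]
    tables: list[DETable]

    def write_tables(self, out_dir: Union[str, Path]) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for table in self.tables:
            p = out_dir / f"{table.meta.model_id}.de.tsv"
            write_de_table(table, p)
            paths.append(p)
        return paths


def _gene_memberships(
    registry: PanelRegistry,
) -> list[tuple[str, list[tuple[str, int]]]]:
    """Ordered unique symbols with their (pathway, sign) memberships.

    Only summary pathways contribute simulated effects; display-only panels
    (fate, TF set, apoptosis) share symbols with pathway panels and inherit
    whatever those produce.
    """
    order: list[str] = []
    members: dict[str, list[tuple[str, int]]] = {}
    for pathway in SCOREABLE_PATHWAYS:
        for panel in registry.iter_panels(pathway):
            for g in panel.genes:
                if g.symbol not in members:
                    order.append(g.symbol)
                    members[g.symbol] = []
                if g.scored:
                    members[g.symbol].append((pathway, g.sign))
    # symbols that appear only in display panels are simulated as nulls
    for panel in registry.panels:
        if panel.pathway in SCOREABLE_PATHWAYS:
            continue
        for g in panel.genes:
            if g.symbol not in members:
                order.append(g.symbol)
                members[g.symbol] = []
    return [(s, members[s]) for s in order]


def _state_direction(state: str, rng: np.random.Generator) -> int:
    if state == "activated":
        return 1
    if state == "reduced":
        return -1
    if state == "conflicting":
        return 1 if rng.random() < 0.5 else -1
    return 0


def simulate_experiment(
    truth: SimulationTruth,
    registry: PanelRegistry,
    models: Sequence[ModelMetadata],
) -> SimulatedExperiment:
    """Generate one DE table per model, bit-reproducible from (truth, seed)."""
    model_ids = {m.model_id for m in models}
    known_pathways = {p.pathway for p in registry.panels}
    for model_id, pathway in truth.states:
        if model_id not in model_ids:
            raise ValueError(f"truth refers to unknown model {model_id!r}")
        if pathway not in known_pathways:
            raise ValueError(f"truth refers to unknown pathway {pathway!r}")

    memberships = _gene_memberships(registry)
    tables: list[DETable] = []
    for m_idx, meta in enumerate(models):
        rng = np.random.default_rng([truth.seed, m_idx])
        records: dict[str, DERecord] = {}
        for symbol, pathways in memberships:
            # target effect: strongest (first non-neutral) membership, or the
            # sum of all memberships' effects in additive-crosstalk mode
            effects = []
            for pathway, sign in pathways:
                state = truth.states.get((meta.model_id, pathway), "neutral")
                d = _state_direction(state, rng)
                effects.append(d * sign)
            if truth.additive_crosstalk:
                signed_shift = sum(effects)
            else:
                signed_shift = next((e for e in effects if e != 0), 0)
            affected = signed_shift != 0

            x = signed_shift * truth.mu + rng.normal(0.0, truth.sigma)
            flagged = rng.random() < (truth.power if affected else truth.alpha)
            if rng.random() < truth.dropout:
                continue
            if rng.random() < truth.ne_rate:
                records[symbol] = DERecord(symbol=symbol, status="not_expressed")
                continue
            records[symbol] = _make_record(symbol, x, flagged, meta, rng)

        for i in range(truth.n_background):
            symbol = f"BG{i + 1:05d}"
            x = rng.normal(0.0, truth.sigma)
            flagged = rng.random() < truth.alpha
            records[symbol] = _make_record(symbol, x, flagged, meta, rng)
        tables.append(DETable(meta=meta, records=records))
    return SimulatedExperiment(truth=truth, models=list(models), tables=tables)


def _make_record(
    symbol: str,
    x: float,
    flagged: bool,
    meta: ModelMetadata,
    rng: np.random.Generator,
) -> DERecord:
    if flagged:
        p = rng.uniform(0.0, meta.alpha)
    else:
        p = rng.uniform(meta.alpha, 1.0)
    kwargs = {meta.significance_field: float(p)}
    return DERecord(symbol=symbol, log2fc=float(x), **kwargs)


def call_experiment(
    experiment: SimulatedExperiment,
    registry: PanelRegistry,
    params: CallParams = CallParams(),
    pathways: Sequence[str] = SCOREABLE_PATHWAYS,
) -> list[PathwayCall]:
    """Score and call every (pathway, model) pair of an experiment."""
    n_models = len(experiment.tables)
    calls = []
    for pathway in pathways:
        panel = registry.merged_panel(pathway)
        for table in experiment.tables:
            score = score_panel(panel, table)
            calls.append(call_pathway(score, params, n_supporting_models=n_models))
    return calls


@dataclass
class RecoveryReport:
    """Truth-state x called-state confusion matrix with accuracies."""

    confusion: pd.DataFrame
    accuracy: float
    per_pathway_accuracy: dict[str, float]
    n_pairs: int

    def __str__(self) -> str:
        lines = [f"recovery over {self.n_pairs} (pathway, model) pairs:"]
        lines.append(self.confusion.to_string())
        lines.append(f"overall accuracy: {self.accuracy:.3f}")
        for pw, acc in sorted(self.per_pathway_accuracy.items()):
            lines.append(f"  {pw}: {acc:.3f}")
        return "\n".join(lines)


def evaluate_recovery(
    experiment: SimulatedExperiment,
    calls: Sequence[PathwayCall],
) -> RecoveryReport:
    """Compare calls against the simulation ground truth.

    A ``conflicting`` truth counts as recovered when called
    ``inconclusive``; a ``neutral`` truth when called ``no_change``.
    Pathways without an explicit truth entry are implicitly neutral.
    """
    call_map = {(c.pathway, c.model_id): c for c in calls}
    from .activity import CALL_STATES  # local to avoid cycle at import time

    confusion = pd.DataFrame(
        0, index=list(TRUTH_STATES), columns=list(CALL_STATES), dtype=int
    )
    confusion.index.name = "truth"
    n_correct = 0
    pw_total: dict[str, int] = {}
    pw_correct: dict[str, int] = {}

    pairs = []
    for table in experiment.tables:
        for c in calls:
            if c.model_id == table.meta.model_id:
                pairs.append((c.model_id, c.pathway))
    missing = [
        key for key in experiment.truth.states if key not in
        {(m, p) for (m, p) in pairs}
    ]
    if missing:
        raise ValueError(f"calls do not cover truth pairs: {missing}")

    for model_id, pathway in pairs:
        truth_state = experiment.truth.states.get((model_id, pathway), "neutral")
        called = call_map[(pathway, model_id)].state
        confusion.loc[truth_state, called] += 1
        ok = called == EXPECTED_CALL[truth_state]
        n_correct += ok
        pw_total[pathway] = pw_total.get(pathway, 0) + 1
        pw_correct[pathway] = pw_correct.get(pathway, 0) + ok

    n_pairs = len(pairs)
    return RecoveryReport(
        confusion=confusion,
        accuracy=n_correct / n_pairs if n_pairs else float("nan"),
        per_pathway_accuracy={
            pw: pw_correct[pw] / pw_total[pw] for pw in pw_total
        },
        n_pairs=n_pairs,
    )
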