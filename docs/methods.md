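# Methods

## Model

`sigcall` treats each tumor model as a published differential-expression
summary: for each gene, a log2 fold change $x_g$ (tumor vs reference) and a
significance value (raw or adjusted p). Pathway activity is inferred from a
curated panel of transcriptional readout genes, each carrying a sign $s_g$:
+1 when the pathway induces the gene, −1 when the pathway represses it or
when the gene is a negative marker whose induction indicates low activity.
Two deliberate sign choices in the shipped registry deserve note. In the
Dpp panel, *brk* is −1 (Dpp shuts it down, so *brk* induction means low Dpp
activity) and *sog* is −1 (a secreted BMP antagonist whose upregulation
tracks, and plausibly causes, low Dpp activity). In the JAK/STAT panel,
*Socs36E* and *Ptp61F* are pathway *inhibitors* but transcriptionally
*induced* targets, so they score +1: their upregulation is evidence of high
pathway activity. *Nox*, *Keap1* and *pnr* are negatively regulated by
JAK/STAT and score −1.

The activity score for a panel in one model is the signed mean over the
significant panel genes,

$$A = \frac{1}{n_\text{sig}} \sum_{g\,\in\,\text{sig}} s_g x_g,$$

with concordance fractions $f_\uparrow$ and $f_\downarrow$ (fractions of
significant genes with $s_g x_g > 0$ and $< 0$). $A$ is in log2 units and
$A = 0$ by definition when no panel gene is significant. Published
per-model heatmap readings give no numeric score — the score and its
thresholds are this package's formalization of that visual reading.

### Evidence semantics

- **Strict significance gate.** A gene is significant iff its dataset's
  significance value is strictly below the dataset's α (default: raw
  p < 0.05, no fold-change threshold). Datasets published under a stricter
  adjusted-p policy (e.g. a FACS-sorted tumor-vs-neighbor design with
  padj < 0.01) carry their own α and significance field in their metadata.
- **Non-significant genes contribute nothing** and are excluded from the
  denominator: a light-grey cell is absence of evidence, not evidence of
  absence.
- **`not_found`** (absent from a dataset, typically annotation-release
  differences) and **`not_expressed`** (in the data with zero reads) genes
  are excluded from all denominators and never imputed; they are reported
  in coverage counts ($n_\text{panel} \ge n_\text{measured} \ge
  n_\text{sig}$).
- **Roles.** Only `target` genes are scored by default. Nuclear factors
  (Mad, Med, pan, sd, yki, Stat92E, kay, Jra, ...) are pathway components,
  not activity readouts, and are display-only; so are ligand rows whose
  transcription is not controlled by their own pathway (*wg*, *Wnt4*,
  *Wnt6*; *dpp* within the Hh panel). Both exclusions are overridable via
  `include_roles`.
- **Multi-pathway readouts** (e.g. *dilp8*, the *upd* ligands, *chinmo*)
  are scored by default; `include_multi_pathway=False` recomputes the
  score without them as a sensitivity analysis.
- **Tissue scope.** Fate-determinant rows are scoped to eye or wing;
  out-of-scope genes stay visible in the matrix but leave the scoring
  scope of that model's column.

### Calling rule

Given thresholds (τ = 0.5 log2 units, `min_genes` = 3, `concord_frac` =
0.6, `conflict_frac` = 0.4, all configurable):

1. $n_\text{sig}$ < `min_genes` → `no_change` (insufficient evidence);
2. $f_\uparrow \ge$ `conflict_frac` **and** $f_\downarrow \ge$
   `conflict_frac` → `inconclusive` (the panel splits — half the targets
   argue activation, half the opposite — so no verdict is forced);
3. $A \ge \tau$ and $f_\uparrow \ge$ `concord_frac` → `activated`;
4. $A \le -\tau$ and $f_\downarrow \ge$ `concord_frac` → `reduced`;
5. otherwise `no_change`.

Confidence is `low` when the conclusion rests on a single dataset
(`n_supporting_models` = 1) or on fewer than `min_genes` significant genes.
`no_change` and `inconclusive` are distinct states merged only at render
time (both yellow in the summary image; the TSV keeps them apart). τ was
set at a 1.4-fold concordant shift — comfortably above per-gene technical
noise yet well below clear activation signatures — and the fraction pair
(0.6/0.4) so that a 50:50 split is inconclusive while a 2:1 majority can
still call a direction.

## The registry

Panels are curated constants (no data-driven panel discovery, no live
FlyBase queries). The Notch panel has three sub-panels: the canonical bHLH
readouts (*dpn* plus the twelve E(spl)-complex transcription units, 13
genes), nine representative non-canonical hyperplasia targets (*Ser*,
*Kank*, *zormin*, *fru*, *CG6191*, *CG3835*, *CG18507*, *pigs*, *jbug*),
and an `other` sub-panel holding *Ldh* (scored) plus display-only Csk/Src
context rows. The alias table is seeded with the synonym pairs the field's
literature itself uses (*os*/*upd1*, *ImpL3*/*Ldh*, *Ilp8*/*dilp8*,
*th*/*Diap1*, *dm*/*Myc*, *coll*/*kn*, *dTCF*/*pan*, ...); resolution is
case-insensitive after trimming, canonical symbols take precedence, and an
unresolved symbol is a value (`None`), never an exception — unresolved rows
are kept under their raw spelling. Registry loading enforces the schema and
the invariants (signs in {−1, +1}, within-panel symbol uniqueness, the
Notch sub-panel sizes, a non-empty scoreable panel per summary pathway, a
functional alias map) and round-trips through `write_registry`.

Duplicate gene rows in an input DE table collapse to the row with the
smallest significance value (the collision is logged); the source studies
do not state a rule, and keeping the strongest evidence is the conservative
reading for a presence/absence gate.

## Synthetic data

The generator emulates DE *summaries*, not read counts: the pipeline's
inputs are published summary tables, so simulating the summary distribution
is sufficient and keeps the model transparent. For a gene with sign $s_g$
in a model whose pathway state has direction $d$ (+1 activated, −1
reduced, 0 neutral; per-gene random ±1 for `conflicting`):

$$x_g = d\, s_g\, \mu + \mathcal{N}(0, \sigma^2).$$

Affected genes are flagged significant with probability `power`, null genes
with probability `alpha`; flagged genes draw p uniform on [0, α) and
unflagged on [α, 1], so the strict gate downstream recovers the flags
exactly. Genes drop out of a table with probability `dropout` (→
`not_found`) or appear with zero reads with probability `ne_rate` (→
`not_expressed`); `n_background` null genes pad each table. Genes shared
between pathways respond to the strongest of their pathways' states (ties
in registry pathway order) — a deliberate simplification of cross-talk; an
additive mode (`additive_crosstalk=True`) sums the memberships' effects
instead. `conflicting` assigns each target an independent random direction,
the minimal model of a genuinely split panel. Everything is reproducible
bit-for-bit from `(truth, seed)` via per-model `numpy` generator streams.

Defaults (μ = 2 log2 units, σ = 0.5, power = 0.9, α = 0.05, dropout = 0.1,
200 background genes) describe a clearly activated pathway in a
well-powered bulk dataset with realistic annotation dropout.

What the simulator does **not** model: count-level noise and its
mean–variance structure, batch effects, correlated genes, non-autonomous
signaling between tumor and neighbor cells, and compositional shifts in
bulk samples. Passing recovery tests therefore show that the extraction →
scoring → calling chain inverts its own generative assumptions, not that
those assumptions hold in any particular real dataset.

## Benchmarks and problem sizes

The parameter-recovery benchmark runs 200 replicates of one model each,
with per-pathway states drawn uniformly from {activated, reduced, neutral}
over the six pathways whose merged panels have ≥5 scoreable genes
(EGFR/Ras, Dpp, Hippo/Yki, JNK, JAK/STAT, Notch; the Hh and Wg panels have
2–3 scored targets, below `min_genes`, so no simulation could ever call
them — they are exercised by the null-rate benchmark instead). The
`conflicting` state is excluded from this accuracy benchmark by design:
with 5–12 significant genes a random per-gene split is lopsided often
enough (binomial tails) that `inconclusive` is not the statistically
identifiable answer, so including it would measure the binomial, not the
pipeline. The conflicting → inconclusive branch is tested separately on
the large Notch panel and as a direct rule check. The null benchmark (150
all-neutral replicates, all eight pathways) bounds the false-activation
rate by α. Both run in seconds on one core.

## Numerical notes

- The score is computed in plain double accumulation; panels are small
  (≤ ~25 genes), so no compensated summation is needed. Equivalence with a
  brute-force loop is asserted to 1e-12.
- `f_up + f_down ≤ 1`, with equality unless some $s_g x_g$ is exactly 0.
- Display clamping (min(max(x, −5), 5)) is idempotent, order-preserving,
  and display-only: every rendered figure has a TSV twin carrying the
  unclamped values, and the TSV — not the image — is the tested surface.
- Exact colors for the heatmap ends and the summary states are conventions
  (dark red/green, yellow for no-change/inconclusive, white background for
  low confidence) and are configurable; nothing downstream depends on them.

## Known limitations

- Panel membership is a curation; different readout choices shift scores.
- The score weights all panel genes equally; no gene-level reliability
  weighting.
- No p-value is attached to the activity score itself (no panel-level
  permutation test), and no cross-model meta-call beyond the per-model
  matrix.
- `inconclusive` detection is conservative and, for genuinely split panels,
  limited by panel size (see above).
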