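"""Signed panel scoring, the expression matrix, and activation calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigcall import (
    ActivityScore,
    CallParams,
    DERecord,
    DETable,
    MarkerGene,
    ModelMetadata,
    Panel,
    build_matrix,
    call_pathway,
    score_panel,
    summarize_calls,
)


def empty_table(model_id="m1", tissue="eye"):
    meta = ModelMetadata(model_id=model_id, genotype="test", tissue=tissue,
                         tumor_class="neoplastic")
    return DETable(meta=meta, records={})


def make_panel(signs, pathway="JNK", **gene_kw):
    genes = tuple(
        MarkerGene(symbol=f"g{i}", sign=s, **gene_kw) for i, s in enumerate(signs)
    )
    return Panel(pathway=pathway, genes=genes)


def fill_table(table, panel, values, pvalues=None):
    pvalues = pvalues or [0.001] * len(values)
    for g, x, p in zip(panel.genes, values, pvalues):
        table.records[g.symbol] = DERecord(symbol=g.symbol, log2fc=x, pvalue=p)
    return table


# ---------------------------------------------------------------------------
# score_panel

class TestScorePanel:
    def test_single_negative_marker_flips_sign(self, table_factory):
        # a repressed BMP-antagonist readout strongly down => high activity
        panel = make_panel([-1], pathway="Dpp")
        table = fill_table(table_factory([]), panel, [-4.16])
        s = score_panel(panel, table)
        assert s.score == pytest.approx(4.16)
        assert (s.n_significant, s.f_up, s.f_down) == (1, 1.0, 0.0)

    def test_hand_computed_mixed_panel(self, table_factory):
        panel = make_panel([1, 1, -1])
        table = fill_table(table_factory([]), panel, [2.0, 1.0, -3.0])
        s = score_panel(panel, table)
        assert s.score == pytest.approx(2.0)
        assert s.f_up == 1.0 and s.f_down == 0.0

    def test_no_significant_genes_scores_zero(self, table_factory):
        panel = make_panel([1, 1])
        table = fill_table(table_factory([]), panel, [2.0, 3.0], pvalues=[0.5, 0.9])
        s = score_panel(panel, table)
        assert s.score == 0.0 and s.n_significant == 0
        assert s.n_measured == 2

    def test_non_target_roles_excluded_by_default(self, table_factory):
        genes = (
            MarkerGene(symbol="t1", sign=1),
            MarkerGene(symbol="nf", sign=1, role="nuclear_factor"),
            MarkerGene(symbol="lig", sign=1, role="ligand"),
        )
        panel = Panel(pathway="Wg", genes=genes)
        table = table_factory([("t1", 1.0, 0.01), ("nf", 9.0, 0.01), ("lig", 9.0, 0.01)])
        s = score_panel(panel, table)
        assert s.n_panel == 1 and s.score == pytest.approx(1.0)

    def test_multi_pathway_exclusion_mode(self, table_factory):
        genes = (
            MarkerGene(symbol="own", sign=1),
            MarkerGene(symbol="shared", sign=1, multi_pathway=True),
        )
        panel = Panel(pathway="JNK", genes=genes)
        table = table_factory([("own", 1.0, 0.01), ("shared", 5.0, 0.01)])
        full = score_panel(panel, table)
        strict = score_panel(panel, table, include_multi_pathway=False)
        assert full.score == pytest.approx(3.0)
        assert strict.score == pytest.approx(1.0)

    def test_tissue_scoped_gene_dropped_for_other_tissue(self, table_factory):
        genes = (
            MarkerGene(symbol="eye_only", sign=1, role="fate_determinant",
                       tissue_scope="eye"),
            MarkerGene(symbol="shared", sign=1, role="fate_determinant"),
        )
        panel = Panel(pathway="fate", genes=genes)
        table = table_factory(
            [("eye_only", 3.0, 0.01), ("shared", 1.0, 0.01)], tissue="wing"
        )
        s = score_panel(panel, table, include_roles=("fate_determinant",))
        assert s.n_panel == 1 and s.score == pytest.approx(1.0)

    def test_empty_after_filtering_raises(self, table_factory):
        panel = make_panel([1], role="nuclear_factor")
        with pytest.raises(ValueError, match="no scoreable genes"):
            score_panel(panel, table_factory([]))

    def test_oracle_equivalence_random_panels(self, table_factory):
        """Score matches an independent brute-force loop on random panels."""
        rng = np.random.default_rng(20260930)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            signs = rng.choice([-1, 1], size=n)
            values = rng.normal(0, 3, size=n)
            sig = rng.random(n) < 0.7
            panel = make_panel(signs)
            table = fill_table(
                table_factory([]), panel, list(values),
                pvalues=[0.01 if s else 0.5 for s in sig],
            )
            s = score_panel(panel, table)

            # brute force: explicit loop over significant genes
            total, count = 0.0, 0
            for i in range(n):
                if sig[i]:
                    total += signs[i] * values[i]
                    count += 1
            expected = total / count if count else 0.0
            assert abs(s.score - expected) < 1e-12
            assert s.n_significant == count


# property suite -------------------------------------------------------------

panel_case = st.lists(
    st.tuples(
        st.sampled_from([-1, 1]),
        st.floats(-8, 8, allow_nan=False),
        st.booleans(),
    ),
    min_size=1,
    max_size=10,
)


@settings(max_examples=200, derandomize=True)
@given(case=panel_case)
def test_score_antisymmetry(case):
    """Flipping every sign negates the score and swaps f_up/f_down."""
    signs = [s for s, _, _ in case]
    values = [v for _, v, _ in case]
    pvals = [0.01 if sig else 0.5 for _, _, sig in case]
    panel = make_panel(signs)
    flipped = make_panel([-s for s in signs])
    t1 = fill_table(empty_table(), panel, values, pvals)
    a = score_panel(panel, t1)
    b = score_panel(flipped, t1)
    assert b.score == pytest.approx(-a.score, abs=1e-12)
    assert b.f_up == pytest.approx(a.f_down)
    assert b.f_down == pytest.approx(a.f_up)
    assert (b.n_panel, b.n_measured, b.n_significant) == (
        a.n_panel, a.n_measured, a.n_significant
    )


@settings(max_examples=200, derandomize=True)
@given(case=panel_case, seed=st.integers(0, 2**16))
def test_score_permutation_invariance(case, seed):
    signs = [s for s, _, _ in case]
    values = [v for _, v, _ in case]
    pvals = [0.01 if sig else 0.5 for _, _, sig in case]
    panel = make_panel(signs)
    table = fill_table(empty_table(), panel, values, pvals)
    a = score_panel(panel, table)

    order = np.random.default_rng(seed).permutation(len(case))
    panel2 = Panel(
        pathway="JNK",
        genes=tuple(
            MarkerGene(symbol=f"g{i}", sign=signs[i]) for i in order
        ),
    )
    b = score_panel(panel2, table)
    assert b.score == pytest.approx(a.score, abs=1e-12)
    assert b.n_significant == a.n_significant


@settings(max_examples=200, derandomize=True)
@given(case=panel_case, bump=st.floats(0.001, 5.0, allow_nan=False))
def test_score_monotone_in_positive_gene(case, bump):
    """Raising a sign-positive significant gene never lowers the score."""
    case = [(1, case[0][1], True)] + case[1:]
    signs = [s for s, _, _ in case]
    values = [v for _, v, _ in case]
    pvals = [0.01 if sig else 0.5 for _, _, sig in case]
    panel = make_panel(signs)
    a = score_panel(panel, fill_table(empty_table(), panel, values, pvals))
    values2 = [values[0] + bump] + values[1:]
    b = score_panel(panel, fill_table(empty_table(), panel, values2, pvals))
    assert b.score >= a.score - 1e-12


@settings(max_examples=150, derandomize=True)
@given(case=panel_case)
def test_concordance_fractions_partition(case):
    signs = [s for s, _, _ in case]
    values = [v for _, v, _ in case]
    pvals = [0.01 if sig else 0.5 for _, _, sig in case]
    panel = make_panel(signs)
    s = score_panel(panel, fill_table(empty_table(), panel, values, pvals))
    assert s.f_up + s.f_down <= 1.0 + 1e-12
    assert s.n_significant <= s.n_measured <= s.n_panel
    if s.n_significant == 0:
        assert s.score == 0.0


# ---------------------------------------------------------------------------
# build_matrix

class TestBuildMatrix:
    def test_completeness(self, table_factory):
        p1 = make_panel([1, 1, -1], pathway="JNK")
        p2 = Panel(pathway="Dpp", genes=(
            MarkerGene(symbol="d0", sign=1), MarkerGene(symbol="d1", sign=-1),
        ))
        t1 = fill_table(table_factory([], model_id="m1"), p1, [1.0, 2.0, -1.0])
        t2 = table_factory([], model_id="m2")
        m = build_matrix([p1, p2], [t1, t2])
        assert len(m.rows) == 5 and m.cols == ["m1", "m2"]
        assert len(m.cells) == 10
        assert all((sym, mid) in m.cells for _, sym in m.rows for mid in m.cols)

    def test_eye_genes_out_of_scope_in_wing_model(self, table_factory):
        genes = (
            MarkerGene(symbol="eye_g", sign=1, role="fate_determinant",
                       tissue_scope="eye"),
            MarkerGene(symbol="any_g", sign=1, role="fate_determinant"),
        )
        panel = Panel(pathway="fate", genes=genes)
        t_eye = table_factory([("eye_g", 1.0, 0.01), ("any_g", 1.0, 0.01)],
                              model_id="eye_m", tissue="eye")
        t_wing = table_factory([("eye_g", 1.0, 0.01), ("any_g", 1.0, 0.01)],
                               model_id="wing_m", tissue="wing")
        m = build_matrix([panel], [t_eye, t_wing])
        assert m.scoring_scope[("eye_g", "eye_m")]
        assert not m.scoring_scope[("eye_g", "wing_m")]
        # the cell is still displayed
        assert m.cell("eye_g", "wing_m").status == "significant"

    def test_gene_missing_in_one_table(self, table_factory):
        panel = make_panel([1])
        t1 = fill_table(table_factory([], model_id="m1"), panel, [1.0])
        t2 = table_factory([], model_id="m2")
        m = build_matrix([panel], [t1, t2])
        statuses = [m.cell("g0", mid).status for mid in m.cols]
        assert statuses.count("not_found") == 1

    def test_duplicate_model_ids_rejected(self, table_factory):
        panel = make_panel([1])
        t = table_factory([])
        with pytest.raises(ValueError, match="unique"):
            build_matrix([panel], [t, t])


# ---------------------------------------------------------------------------
# call_pathway

def mk_score(score, f_up, f_down, n_sig, pathway="Dpp", n_panel=10):
    return ActivityScore(
        pathway=pathway, model_id="m1", score=score, n_panel=n_panel,
        n_measured=max(n_sig, n_panel - 2), n_significant=n_sig,
        f_up=f_up, f_down=f_down,
    )


class TestCallPathway:
    def test_strong_concordant_induction_two_models(self):
        c = call_pathway(mk_score(4.16, 1.0, 0.0, 5), n_supporting_models=2)
        assert (c.state, c.confidence) == ("activated", "high")

    def test_no_evidence_is_no_change_low(self):
        c = call_pathway(mk_score(0.0, 0.0, 0.0, 0), n_supporting_models=3)
        assert (c.state, c.confidence) == ("no_change", "low")

    def test_split_panel_is_inconclusive(self):
        # half the targets argue activation, half the opposite: no verdict
        c = call_pathway(mk_score(0.3, 0.5, 0.5, 8), n_supporting_models=2)
        assert c.state == "inconclusive"

    def test_reduction_branch(self):
        c = call_pathway(mk_score(-2.0, 0.1, 0.9, 6), n_supporting_models=2)
        assert (c.state, c.confidence) == ("reduced", "high")

    def test_single_dataset_gives_low_confidence(self):
        c = call_pathway(mk_score(3.0, 1.0, 0.0, 6), n_supporting_models=1)
        assert (c.state, c.confidence) == ("activated", "low")

    def test_score_below_tau_is_no_change(self):
        c = call_pathway(mk_score(0.3, 1.0, 0.0, 6), n_supporting_models=2)
        assert c.state == "no_change"

    def test_discordant_strong_score_is_not_directional(self):
        # magnitude alone is not enough without gene-level concordance
        c = call_pathway(mk_score(2.0, 0.5, 0.2, 6), n_supporting_models=2)
        assert c.state == "no_change"

    @pytest.mark.parametrize("bad", [
        dict(tau=0.0), dict(tau=-1.0), dict(concord_frac=1.5),
        dict(conflict_frac=-0.1), dict(min_genes=0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            CallParams(**bad)

    def test_call_is_pure_function_of_inputs(self):
        s = mk_score(1.2, 0.8, 0.1, 5)
        p = CallParams()
        assert call_pathway(s, p, 2) == call_pathway(s, p, 2)


class TestSummarizeCalls:
    def _calls(self, pathways, models):
        return [
            call_pathway(mk_score(2.0, 1.0, 0.0, 5, pathway=pw), n_supporting_models=2)
            for pw in pathways
            for _ in models
        ]

    def test_shape(self):
        calls = []
        for pw in ["JNK", "Dpp", "Notch"]:
            for mid in ["m1", "m2"]:
                s = ActivityScore(pathway=pw, model_id=mid, score=2.0, n_panel=8,
                                  n_measured=6, n_significant=5, f_up=1.0, f_down=0.0)
                calls.append(call_pathway(s, n_supporting_models=2))
        mat = summarize_calls(calls)
        assert mat.shape == (3, 2)
        assert set(mat.values.ravel()) == {"activated/high"}

    def test_duplicate_pair_rejected(self):
        s = mk_score(2.0, 1.0, 0.0, 5)
        c = call_pathway(s, n_supporting_models=2)
        with pytest.raises(ValueError, match="duplicate"):
            summarize_calls([c, c])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_calls([])
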