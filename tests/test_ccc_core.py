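"""Mass-action strength model, permutation test and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cccdiff import (
    GeneComplex,
    HillParams,
    LRDatabase,
    LRInteraction,
    aggregate_pathways,
    celltype_contributions,
    complex_expression,
    count_strength_maps,
    infer_communication,
    information_flow,
    interaction_strength,
    permutation_test,
    relative_flow,
    summarize_profiles,
)
from cccdiff.ccc_core import CommunicationTensor, ParameterError, PathwayScores

from conftest import make_dataset


class TestSummarizeProfiles:
    def test_low_fraction_gene_zeroed(self):
        # expressed in 3 of 20 cells (15%) -> summary forced to 0
        values = np.zeros(20)
        values[:3] = 5.0
        ds = make_dataset({"T": {"g1": 0.0}, "U": {"g1": 1.0}}, n_cells=20)
        ds.matrix[0, :20] = values  # overwrite type T's g1 column block
        prof = summarize_profiles(ds, threshold=0.2)
        assert prof.expr_fraction.at["T", "g1"] == pytest.approx(0.15)
        assert prof.mean_expr.at["T", "g1"] == 0.0

    def test_constant_input_identical_under_both_summaries(self):
        ds = make_dataset({"T": {"g1": 4.0}, "U": {"g1": 4.0}}, n_cells=8)
        for summary in ("trimean", "mean"):
            prof = summarize_profiles(ds, summary=summary)
            assert prof.mean_expr.at["T", "g1"] == pytest.approx(4.0)

    def test_trimean_drops_extreme_quartiles(self):
        ds = make_dataset({"T": {"g1": 0.0}, "U": {"g1": 10.0}}, n_cells=8)
        ds.matrix[0, :8] = [0, 0, 0, 0, 10, 10, 10, 10]
        prof = summarize_profiles(ds, threshold=0.0)
        # mean of the middle half {0, 0, 10, 10}
        assert prof.mean_expr.at["T", "g1"] == pytest.approx(5.0)

    def test_trimean_matches_scipy(self):
        from scipy.stats import trim_mean

        rng = np.random.default_rng(7)
        for n in (4, 5, 9, 16, 37):
            x = rng.gamma(2, 1, n)
            ds = make_dataset({"T": {"g1": 1.0}}, n_cells=n)
            ds.matrix[0] = x
            prof = summarize_profiles(ds, threshold=0.0)
            assert prof.mean_expr.at["T", "g1"] == pytest.approx(
                trim_mean(x, 0.25), rel=1e-12
            )

    def test_invalid_threshold_rejected(self):
        ds = make_dataset({"T": {"g1": 1.0}, "U": {"g1": 1.0}})
        with pytest.raises(ParameterError):
            summarize_profiles(ds, threshold=1.5)


class TestComplexExpression:
    @pytest.fixture
    def profile(self):
        ds = make_dataset(
            {"T": {"g1": 2.0, "g2": 8.0, "g3": 0.0, "g4": 5.0},
             "U": {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 1.0}}
        )
        return summarize_profiles(ds, threshold=0.0)

    def test_geometric_mean(self, profile):
        cplx = GeneComplex("X", ("g1", "g2"))
        assert complex_expression(profile, cplx, "T") == pytest.approx(4.0)

    def test_single_subunit_identity(self, profile):
        assert complex_expression(profile, GeneComplex("X", ("g4",)), "T") == 5.0

    def test_zero_subunit_nulls_complex(self, profile):
        cplx = GeneComplex("X", ("g3", "g4"))
        assert complex_expression(profile, cplx, "T") == 0.0

    def test_missing_gene_treated_as_zero(self, profile):
        cplx = GeneComplex("X", ("g1", "nope"))
        assert complex_expression(profile, cplx, "T") == 0.0


class TestInteractionStrength:
    def test_null_ligand_gives_zero(self):
        assert interaction_strength(0.0, 3.0) == 0.0

    def test_half_saturation_point(self):
        # L*R = kh = 0.5 -> exactly one half
        assert interaction_strength(1.0, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_unit_expression_closed_form(self):
        assert interaction_strength(1.0, 1.0) == pytest.approx(2 / 3, abs=1e-12)

    def test_agonist_raises_antagonist_lowers(self):
        base = interaction_strength(1.0, 1.0)
        up = interaction_strength(1.0, 1.0, {"agonist": 1.0})
        down = interaction_strength(1.0, 1.0, {"antagonist": 1.0})
        assert up > base > down

    def test_costimulatory_raises_coinhibitory_lowers(self):
        base = interaction_strength(1.0, 1.0)
        up = interaction_strength(1.0, 1.0, {"co_stimulatory": 1.0})
        down = interaction_strength(1.0, 1.0, {"co_inhibitory": 1.0})
        assert up > base > down

    def test_cofactors_ignored_when_disabled(self):
        params = HillParams(use_cofactors=False)
        with_cof = interaction_strength(1.0, 1.0, {"agonist": 9.0}, params)
        assert with_cof == pytest.approx(2 / 3)

    def test_negative_input_rejected(self):
        with pytest.raises(ParameterError):
            interaction_strength(-1.0, 1.0)

    @given(
        L=st.floats(0, 10), R=st.floats(0, 10),
        dL=st.floats(0, 5), ag=st.floats(0, 5), an=st.floats(0, 5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_ligand_bounded(self, L, R, dL, ag, an):
        terms = {"agonist": ag, "antagonist": an}
        s1 = interaction_strength(L, R, terms)
        s2 = interaction_strength(L + dL, R, terms)
        assert s2 >= s1 - 1e-15
        assert 0 <= s1 < 2
        assert interaction_strength(L, R) < 1  # no cofactors: below 1


def two_type_toy():
    """2 cell types x 4 genes with constant expression; strengths have a
    closed form computable by hand."""
    values = {
        "A": {"LIG": 2.0, "RECA": 0.5, "RECB": 0.0, "AGO": 1.0},
        "B": {"LIG": 0.5, "RECA": 2.0, "RECB": 8.0, "AGO": 0.0},
    }
    ds = make_dataset(values, n_cells=10)
    db = LRDatabase(
        interactions=[
            LRInteraction(
                id="I1",
                ligand=GeneComplex("LIG", ("LIG",)),
                receptor=GeneComplex("RECA", ("RECA",)),
                pathway="P1",
            ),
            LRInteraction(
                id="I2",
                ligand=GeneComplex("LIG2", ("LIG",)),
                receptor=GeneComplex("RECA_RECB", ("RECA", "RECB")),
                pathway="P2",
                agonists=("AGO",),
            ),
        ]
    )
    return ds, db, values


def hill(L, R, kh=0.5):
    lr = L * R
    return lr / (kh + lr)


class TestTensorOracle:
    def test_strengths_match_hand_computation(self):
        ds, db, v = two_type_toy()
        tensor = infer_communication(ds, db, HillParams(n_perm=5), seed=0)
        types = tensor.cell_types
        kh = 0.5
        for si, s in enumerate(types):
            for ri, r in enumerate(types):
                # I1: plain ligand-receptor
                expected = hill(v[s]["LIG"], v[r]["RECA"])
                got = tensor.strength[si, ri, tensor.interactions.index("I1")]
                assert got == pytest.approx(expected, abs=1e-12)
                # I2: receptor complex (geometric mean, null if any 0) with
                # sender-side agonist
                rec = (
                    0.0
                    if v[r]["RECA"] == 0 or v[r]["RECB"] == 0
                    else np.sqrt(v[r]["RECA"] * v[r]["RECB"])
                )
                ag = v[s]["AGO"]
                expected2 = hill(v[s]["LIG"], rec) * (1 + ag / (kh + ag))
                got2 = tensor.strength[si, ri, tensor.interactions.index("I2")]
                assert got2 == pytest.approx(expected2, abs=1e-12)

    def test_determinism_same_seed(self):
        ds, db, _ = two_type_toy()
        t1 = infer_communication(ds, db, HillParams(n_perm=20), seed=42)
        t2 = infer_communication(ds, db, HillParams(n_perm=20), seed=42)
        np.testing.assert_array_equal(t1.pval, t2.pval)
        np.testing.assert_array_equal(t1.strength, t2.strength)

    def test_zero_strength_has_p_one(self):
        ds, db, _ = two_type_toy()
        tensor = infer_communication(ds, db, HillParams(n_perm=20), seed=1)
        zero = tensor.strength == 0
        assert np.all(tensor.pval[zero] == 1.0)


class TestPermutationTest:
    def test_planted_signal_significant(self, planted_small):
        ds, db, truth = planted_small
        route = truth.iloc[0]
        interaction = db.pathways[route["pathway"]][0]
        p = permutation_test(
            ds, db, (route["sender"], route["receiver"], interaction),
            HillParams(n_perm=100), seed=3,
        )
        assert p <= 0.02

    def test_all_filtered_dataset_gives_all_zero(self):
        # no gene reaches the 20% fraction anywhere -> empty tensor
        ds = make_dataset({"A": {"g1": 0.0}, "B": {"g1": 0.0}}, n_cells=10)
        db = LRDatabase(
            interactions=[
                LRInteraction(
                    id="I1",
                    ligand=GeneComplex("g1", ("g1",)),
                    receptor=GeneComplex("g1b", ("g1b",)),
                    pathway="P",
                )
            ]
        )
        tensor = infer_communication(ds, db, HillParams(n_perm=10), seed=0)
        assert np.all(tensor.strength == 0)
        assert np.all(tensor.pval == 1.0)


def toy_scores():
    score = np.zeros((2, 2, 2))
    score[0, 1, 0] = 0.4
    score[1, 0, 1] = 0.1
    score[0, 0, 1] = 0.4
    return PathwayScores(score=score, cell_types=["A", "B"], pathways=["P1", "P2"])


class TestAggregation:
    def test_only_significant_strengths_summed(self):
        strength = np.zeros((2, 2, 2))
        strength[0, 1, 0] = 0.2  # p = 0.2 -> not significant
        strength[0, 1, 1] = 0.3  # p = 0.01 -> significant
        pval = np.ones((2, 2, 2))
        pval[0, 1, 0] = 0.2
        pval[0, 1, 1] = 0.01
        tensor = CommunicationTensor(
            strength=strength, pval=pval, cell_types=["A", "B"],
            interactions=["I1", "I2"], alpha=0.05,
        )
        db = LRDatabase(
            interactions=[
                LRInteraction(id="I1", ligand=GeneComplex("a", ("a",)),
                              receptor=GeneComplex("b", ("b",)), pathway="P"),
                LRInteraction(id="I2", ligand=GeneComplex("c", ("c",)),
                              receptor=GeneComplex("d", ("d",)), pathway="P"),
            ]
        )
        ps = aggregate_pathways(tensor, db)
        assert ps.score[0, 1, 0] == pytest.approx(0.3)

    def test_count_and_strength_maps(self):
        strength = np.zeros((2, 2, 3))
        strength[0, 1] = [0.1, 0.2, 0.3]
        pval = np.full((2, 2, 3), 1.0)
        pval[0, 1] = 0.01
        tensor = CommunicationTensor(
            strength=strength, pval=pval, cell_types=["A", "B"],
            interactions=["I1", "I2", "I3"], alpha=0.05,
        )
        counts, totals = count_strength_maps(tensor)
        assert counts.at["A", "B"] == 3
        assert totals.at["A", "B"] == pytest.approx(0.6)
        assert counts.to_numpy().sum() == 3

    def test_information_flow_sums_cell_pairs(self):
        flow = information_flow(toy_scores())
        assert flow["P1"] == pytest.approx(0.4)
        assert flow["P2"] == pytest.approx(0.5)

    def test_relative_flow_normalizes_and_labels(self):
        ps_a = toy_scores()
        ps_b = PathwayScores(
            score=np.zeros((2, 2, 2)), cell_types=["A", "B"], pathways=["P1", "P2"]
        )
        ps_b.score[0, 1, 0] = 0.6
        rel = relative_flow(ps_a, ps_b)
        assert rel.loc["P1", "relative_A"] == pytest.approx(0.4)
        assert rel.loc["P1", "relative_B"] == pytest.approx(0.6)
        assert rel.loc["P2", "label"] == "specific_to_A"

    def test_contributions_directions_and_conservation(self):
        ps = toy_scores()
        out = celltype_contributions(ps, "outgoing")
        inc = celltype_contributions(ps, "incoming")
        assert out.at["A", "P1"] == pytest.approx(0.4)
        assert inc.at["B", "P1"] == pytest.approx(0.4)
        flow = information_flow(ps)
        for pw in ps.pathways:
            assert out[pw].sum() == pytest.approx(flow[pw])
            assert inc[pw].sum() == pytest.approx(flow[pw])
        rel = celltype_contributions(ps, "outgoing", relative=True)
        assert rel["P1"].max() == pytest.approx(1.0)

    def test_flow_conserves_total_significant_strength(self, planted_small):
        ds, db, _ = planted_small
        tensor = infer_communication(ds, db, HillParams(n_perm=30), seed=5)
        ps = aggregate_pathways(tensor, db)
        total = np.where(tensor.significant, tensor.strength, 0.0).sum()
        assert information_flow(ps).sum() == pytest.approx(total, abs=1e-12)


class TestMonotonicity:
    def test_raising_ligand_never_lowers_strength(self):
        import copy

        ds, db, _ = two_type_toy()
        base = infer_communication(ds, db, HillParams(n_perm=2), seed=0)
        lig_row = ds.gene_index["LIG"]
        rng = np.random.default_rng(0)
        for _ in range(5):
            ds2 = copy.deepcopy(ds)
            ds2.matrix[lig_row] += rng.uniform(0, 2)
            t2 = infer_communication(ds2, db, HillParams(n_perm=2), seed=0)
            assert np.all(t2.strength >= base.strength - 1e-12)
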