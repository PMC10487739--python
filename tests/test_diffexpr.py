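import numpy as np
import pytest
from scipy import stats

from helpers import make_normalized
from dsp_attenuation.diffexpr import (
    BUOE_CONTRAST,
    Contrast,
    FLIGHT_CONTRAST,
    call_degs,
    de_analysis,
    log2_fold_change,
    permutation_qvalues,
    t_test,
    welch_t,
)
from dsp_attenuation.errors import ContrastError
from dsp_attenuation.io import AOIAnnotation
from dsp_attenuation.normalization import q3_normalize
from dsp_attenuation.synthetic import SimulationConfig, simulate_dataset


def annotations_for(groups: list[tuple[str, str]], region: str = "CA"):
    """One AOI per listed (condition, treatment), replicates auto-numbered."""
    counts: dict[tuple[str, str], int] = {}
    out = []
    for cond, trt in groups:
        counts[(cond, trt)] = counts.get((cond, trt), 0) + 1
        rep = counts[(cond, trt)]
        out.append(
            AOIAnnotation(
                aoi_id=f"{region}_{cond}-{trt}_{rep}",
                region=region,
                condition=cond,
                treatment=trt,
                replicate=rep,
                mouse_id=f"{cond}-{trt}-m{rep}",
            )
        )
    return out


SIX = annotations_for([("FLT", "SAL")] * 3 + [("GC", "SAL")] * 3)
FLIGHT = FLIGHT_CONTRAST("CA")


class TestLog2FoldChange:
    def test_identical_group_means_give_zero(self):
        norm = make_normalized(np.tile([[2.0]], (4, 6)))
        np.testing.assert_allclose(log2_fold_change(norm, SIX, FLIGHT), 0.0)

    def test_closed_form_difference_of_means(self):
        norm = make_normalized([[3.0, 3.0, 3.0, 1.0, 1.0, 1.0]])
        assert log2_fold_change(norm, SIX, FLIGHT)[0] == pytest.approx(2.0)

    def test_empty_group_is_contrast_error(self):
        norm = make_normalized(np.zeros((2, 6)))
        with pytest.raises(ContrastError):
            log2_fold_change(norm, SIX, BUOE_CONTRAST("CA"))

    def test_recovers_planted_effect_on_simulated_data(self):
        cfg = SimulationConfig(
            n_genes=3000,
            regions=("CA",),
            n_replicates=6,
            n_flight_degs_per_region=150,
            flight_effect_size=2.0,
            attenuation_alpha=0.0,
            seed=21,
        )
        matrix, annotations, truth = simulate_dataset(cfg)
        norm = q3_normalize(matrix)
        lfc = log2_fold_change(norm, annotations, FLIGHT)
        idx = {g: i for i, g in enumerate(matrix.genes)}
        signed = [
            np.sign(delta) * lfc[idx[g]] for g, delta in truth.flight_effects["CA"].items()
        ]
        # log2(x+1) compresses effects slightly below the planted 2.0
        assert np.mean(signed) == pytest.approx(2.0, abs=0.25)


class TestWelchT:
    def test_no_difference_no_variance_gives_t0_p1(self):
        t, p = welch_t(np.array([[2.0, 2.0]]), np.array([[2.0, 2.0]]))
        assert t[0] == 0.0
        assert p[0] == 1.0

    def test_fixed_numbers_match_reference_value(self):
        t, p = welch_t(np.array([[5.0, 6.0, 7.0]]), np.array([[1.0, 2.0, 3.0]]))
        assert t[0] == pytest.approx(4.898979485566356)
        assert p[0] == pytest.approx(0.008049893100837719, rel=1e-9)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(50, 4)), rng.normal(1.0, 2.0, size=(50, 5))
        t, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)

    def test_constant_unequal_groups_hit_variance_floor(self):
        t, p = welch_t(np.array([[2.0, 2.0]]), np.array([[1.0, 1.0]]))
        assert t[0] > 1e5
        assert p[0] < 1e-5

    def test_group_of_one_rejected(self):
        with pytest.raises(ContrastError):
            welch_t(np.array([[1.0]]), np.array([[1.0, 2.0]]))

    def test_swapping_groups_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        t1, p1 = welch_t(a, b)
        t2, p2 = welch_t(b, a)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(
        n_genes=800,
        regions=("CA",),
        n_replicates=3,
        n_flight_degs_per_region=60,
        flight_effect_size=2.5,
        seed=13,
    )
    matrix, annotations, truth = simulate_dataset(cfg)
    return q3_normalize(matrix), annotations, truth


class TestPermutationQvalues:

    def test_three_vs_three_triggers_enumeration(self, sim):
        norm, annotations, _ = sim
        with pytest.warns(UserWarning, match="20 distinct label assignments"):
            q = permutation_qvalues(norm, annotations, FLIGHT, n_perm=1000, seed=0)
        assert q.shape == (800,)

    def test_q_in_unit_interval_and_monotone_in_p_rank(self, sim):
        norm, annotations, _ = sim
        _, p = t_test(norm, annotations, FLIGHT)
        with pytest.warns(UserWarning):
            q = permutation_qvalues(norm, annotations, FLIGHT, n_perm=1000, seed=0)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_swapping_contrast_groups_leaves_q_unchanged(self, sim):
        norm, annotations, _ = sim
        swapped = Contrast("CA", reference_group=("FLT", "SAL"), test_group=("GC", "SAL"))
        with pytest.warns(UserWarning):
            q1 = permutation_qvalues(norm, annotations, FLIGHT, n_perm=1000, seed=0)
            q2 = permutation_qvalues(norm, annotations, swapped, n_perm=1000, seed=0)
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_null_data_calibration(self):
        cfg = SimulationConfig(
            n_genes=2000,
            regions=("CA",),
            n_replicates=4,
            n_flight_degs_per_region=0,
            seed=17,
        )
        matrix, annotations, _ = simulate_dataset(cfg)
        norm = q3_normalize(matrix)
        with pytest.warns(UserWarning):  # C(8,4)=70 assignments enumerated
            q = permutation_qvalues(norm, annotations, FLIGHT, n_perm=1000, seed=3)
        assert (q < 0.05).mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 2000)


class TestCallDegs:
    def test_threshold_boundaries_are_strict(self):
        genes = ["a", "b", "c"]
        lfc = np.array([1.0, 0.585, 1.0])
        q = np.array([0.05, 0.01, 0.01])
        table = call_degs(genes, lfc, np.zeros(3), np.zeros(3), q)
        assert list(table["is_deg"]) == [False, False, True]
        assert list(table["direction"]) == ["none", "none", "up"]

    def test_direction_follows_sign(self):
        table = call_degs(
            ["a", "b"], np.array([2.0, -2.0]), np.zeros(2), np.zeros(2), np.array([0.01, 0.01])
        )
        assert list(table["direction"]) == ["up", "down"]

    def test_deg_set_invariant_to_gene_order(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        lfc, q = rng.normal(0, 1, 50), rng.uniform(0, 0.2, 50)
        table = call_degs(genes, lfc, np.zeros(50), np.zeros(50), q)
        perm = rng.permutation(50)
        shuffled = call_degs(
            [genes[i] for i in perm], lfc[perm], np.zeros(50), np.zeros(50), q[perm]
        )
        degs = set(table.loc[table["is_deg"], "gene"])
        assert degs == set(shuffled.loc[shuffled["is_deg"], "gene"])


def test_de_analysis_finds_planted_degs_and_signs():
    cfg = SimulationConfig(
        n_genes=1500,
        regions=("CA",),
        n_replicates=6,
        n_flight_degs_per_region=100,
        flight_effect_size=2.0,
        seed=23,
    )
    matrix, annotations, truth = simulate_dataset(cfg)
    norm = q3_normalize(matrix)
    with pytest.warns(UserWarning):  # 924 assignments enumerated
        table = de_analysis(norm, annotations, FLIGHT, n_perm=1000, seed=0)
    called = set(table.loc[table["is_deg"], "gene"])
    planted = truth.flight_deg_set("CA")
    assert len(called & planted) / len(planted) > 0.5
    # called directions agree with planted signs
    for row in table[table["is_deg"]].itertuples():
        if row.gene in planted:
            expected = "up" if truth.flight_effects["CA"][row.gene] > 0 else "down"
            assert row.direction == expected
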