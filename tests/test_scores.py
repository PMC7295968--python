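"""The twelve signature-summary scores, significance weighting and the
percent-activity rescaling."""

import math

import numpy as np
import pytest

from sigpotency import (
    ALL_METHODS,
    CompoundSpec,
    IntegrityError,
    ReferenceContext,
    Role,
    Scale,
    SignatureScorer,
    SimulationConfig,
    build_reference_context,
    compute_score,
    percent_activity,
    score_treatments,
    significance_weight,
    simulate_plate,
)
from sigpotency.scores import AC_REFERENCED, _score

from conftest import make_plate


def manual_ctx(ac, nc_rows=None, n_genes=None):
    """ReferenceContext with explicit AC vector, NC rows and sample covariance
    (identity when NC rows are degenerate)."""
    ac = None if ac is None else np.asarray(ac, dtype=float)
    n = n_genes if n_genes is not None else len(ac)
    nc = np.zeros((4, n)) if nc_rows is None else np.asarray(nc_rows, dtype=float)
    cov = np.eye(n)
    if nc_rows is not None and nc.shape[0] > n:
        cov = np.cov(nc, rowvar=False, ddof=1)
    return ReferenceContext(
        genes=tuple(f"G{i}" for i in range(n)),
        ac_vector=ac,
        nc_vectors=nc,
        nc_center=np.median(nc, axis=0),
        nc_cov=cov,
        nc_cov_inv=np.linalg.inv(cov),
    )


class TestHandComputedScores:
    """profile [3,4], AC [1,0], NC centre [0,0]."""

    CTX = None

    @classmethod
    def setup_class(cls):
        cls.CTX = manual_ctx([1.0, 0.0])

    @pytest.mark.parametrize(
        "method,expected",
        [
            ("cos_AC", 0.6),
            ("scalar_projection_AC", 3.0),
            ("dot_p_AC", 3.0),
            ("vec_norm", 5.0),
            ("euc_NC", 5.0),
            ("euc_AC", math.sqrt(20.0)),
            ("num_readouts_changed", 1.0),
        ],
    )
    def test_formula_values(self, method, expected):
        assert compute_score([3.0, 4.0], self.CTX, method) == pytest.approx(expected)

    def test_self_similarity(self):
        ac = np.array([2.0, -1.0, 3.0])
        ctx = manual_ctx(ac)
        assert compute_score(ac, ctx, "cos_AC") == pytest.approx(1.0)
        assert compute_score(ac, ctx, "euc_AC") == pytest.approx(0.0)
        assert compute_score(ac, ctx, "scalar_projection_AC") == pytest.approx(
            np.linalg.norm(ac)
        )
        assert compute_score(-ac, ctx, "cos_AC") == pytest.approx(-1.0)

    def test_mahalanobis_equals_euclidean_under_identity(self):
        rng = np.random.default_rng(2)
        ctx = manual_ctx(rng.normal(size=5))
        for _ in range(20):
            p = rng.normal(size=5)
            assert compute_score(p, ctx, "maha_NC") == pytest.approx(
                compute_score(p, ctx, "euc_NC"), rel=1e-12
            )
            assert compute_score(p, ctx, "maha_AC") == pytest.approx(
                compute_score(p, ctx, "euc_AC"), rel=1e-12
            )

    def test_dot_is_projection_times_ac_norm(self):
        rng = np.random.default_rng(3)
        ac = rng.normal(size=6)
        ctx = manual_ctx(ac)
        for _ in range(25):
            p = rng.normal(size=6)
            assert compute_score(p, ctx, "dot_p_AC") == pytest.approx(
                compute_score(p, ctx, "scalar_projection_AC") * np.linalg.norm(ac),
                rel=1e-12,
            )


class TestSignificanceWeight:
    def test_three_robust_sd_gives_one(self):
        assert significance_weight([3.0] * 7) == pytest.approx(1.0)
        assert significance_weight([3.0, -3.0, 3.0, -3.0]) == pytest.approx(1.0)

    def test_half_signal_gives_half(self):
        assert significance_weight([1.5] * 5) == pytest.approx(0.5)

    def test_capped_at_one(self):
        assert significance_weight([300.0] * 3) == 1.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            significance_weight([])

    def test_weight_enters_cosine(self):
        ac = np.array([1.0, 1.0])
        ctx = manual_ctx(ac)
        p = np.array([1.5, 1.5])
        assert compute_score(p, ctx, "cos_weight_AC") == pytest.approx(
            compute_score(p, ctx, "cos_AC") * 0.5
        )


class TestBruteForceEquivalence:
    def test_all_methods_match_straight_line_oracle(self, bruteforce):
        rng = np.random.default_rng(17)
        for trial in range(40):
            n_genes = int(rng.integers(2, 11))
            n_nc = n_genes + 3  # keep the sample covariance well defined
            nc = rng.normal(size=(n_nc, n_genes))
            ac = rng.normal(size=n_genes) * 3
            profile = rng.normal(size=n_genes) * 2
            cov = np.cov(nc, rowvar=False, ddof=1)
            cov_inv = np.linalg.inv(cov)
            ctx = ReferenceContext(
                genes=tuple(f"G{i}" for i in range(n_genes)),
                ac_vector=ac,
                nc_vectors=nc,
                nc_center=np.median(nc, axis=0),
                nc_cov=cov,
                nc_cov_inv=cov_inv,
            )
            for method in ALL_METHODS:
                expected = bruteforce(profile, ac, nc.tolist(), cov_inv.tolist(), method)
                assert compute_score(profile, ctx, method) == pytest.approx(
                    expected, rel=1e-10, abs=1e-12
                ), method


class TestInvariances:
    def test_scale_invariance_and_linearity(self):
        rng = np.random.default_rng(9)
        ac = rng.normal(size=5)
        ctx = manual_ctx(ac)
        p = rng.normal(size=5)
        for alpha in (0.5, 2.0, 17.0):
            for m in ("cos_AC", "cor_p_AC", "cor_s_AC"):
                assert compute_score(alpha * p, ctx, m) == pytest.approx(
                    compute_score(p, ctx, m), rel=1e-10
                )
            for m in ("vec_norm", "dot_p_AC", "scalar_projection_AC"):
                assert compute_score(alpha * p, ctx, m) == pytest.approx(
                    alpha * compute_score(p, ctx, m), rel=1e-10
                )

    def test_bounds(self):
        rng = np.random.default_rng(11)
        ac = rng.normal(size=6)
        ctx = manual_ctx(ac)
        for _ in range(30):
            p = rng.normal(size=6) * rng.uniform(0.1, 30)
            for m in ("cos_AC", "cor_p_AC", "cor_s_AC", "cos_weight_AC"):
                assert -1 - 1e-12 <= compute_score(p, ctx, m) <= 1 + 1e-12
            assert 0 <= significance_weight(p) <= 1
            assert 0 <= compute_score(p, ctx, "num_readouts_changed") <= 6

    def test_degenerate_profile_scores_zero_for_direction_methods(self):
        ctx = manual_ctx([1.0, 2.0])
        for m in ("cos_AC", "cor_p_AC", "cor_s_AC", "cos_weight_AC",
                  "scalar_projection_AC"):
            # scalar projection of a zero profile is genuinely 0
            score, degen = _score(np.zeros(2), ctx, m)
            assert score == 0.0
            if m != "scalar_projection_AC":
                assert degen


class TestPercentActivity:
    def _ctx(self):
        ctx = manual_ctx([4.0, 0.0])
        ctx.nc_score_center = {"scalar_projection_AC": 0.0}
        ctx.ac_score_center = {"scalar_projection_AC": 4.0}
        return ctx

    def test_nc_and_ac_anchors(self):
        ctx = self._ctx()
        assert percent_activity(0.0, ctx, "scalar_projection_AC") == 0.0
        assert percent_activity(4.0, ctx, "scalar_projection_AC") == 100.0
        assert percent_activity(2.0, ctx, "scalar_projection_AC") == 50.0

    def test_ac_similarity_anchors(self):
        ctx = manual_ctx([3.0, 4.0])
        # profile == AC -> euc_AC score 0 -> 100 %; NC centre -> 0 %
        assert percent_activity(0.0, ctx, "euc_AC") == pytest.approx(100.0)
        d = np.linalg.norm(ctx.ac_vector - ctx.nc_center)
        assert percent_activity(d, ctx, "euc_AC") == pytest.approx(0.0)

    def test_uninformative_method_rejected(self):
        ctx = self._ctx()
        ctx.ac_score_center["scalar_projection_AC"] = 0.0
        with pytest.raises(IntegrityError, match="uninformative"):
            percent_activity(1.0, ctx, "scalar_projection_AC")


@pytest.fixture(scope="module")
def ac_like_plate():
    # compound wells replicate the AC signature at every concentration
    cfg = SimulationConfig(
        compounds=(CompoundSpec("mimic", true_ec50_uM=1e-12),),
        noise_sd=0.05,
        n_nc_wells=12,
        n_ac_wells=4,
        n_tech_replicates=3,
        seed=21,
    )
    return simulate_plate(cfg)


class TestScoreTreatments:
    def test_ac_mimic_scores_100_percent(self, ac_like_plate):
        series = score_treatments(ac_like_plate)
        for s in series:
            if s.method in AC_REFERENCED:
                assert np.all(np.abs(s.percent_activity - 100.0) < 12.0), s.method

    def test_nc_wells_centre_at_zero_percent(self, ac_like_plate):
        scorer = SignatureScorer().fit(ac_like_plate)
        nc = ac_like_plate.subset_wells(ac_like_plate.wells_with_role(Role.NC))
        table = scorer.transform(nc)
        med = table.groupby("method")["percent_activity"].median()
        assert np.all(np.abs(med) < 25.0)

    def test_without_ac_wells_magnitude_methods_still_computed(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(10, 3))
        roles = [Role.NC] * 6 + [Role.COMPOUND] * 4
        concs = [np.nan] * 6 + [0.1, 1.0, 10.0, 100.0]
        pset = make_plate(vals, roles, concentrations=concs, scale=Scale.RSCORE)
        series = score_treatments(pset, methods=("vec_norm", "euc_NC", "cos_AC"))
        methods = {s.method for s in series}
        assert methods == {"vec_norm", "euc_NC"}

    def test_only_ac_methods_without_ac_is_error(self):
        pset = make_plate(
            np.ones((4, 2)),
            [Role.NC] * 3 + [Role.COMPOUND],
            scale=Scale.RSCORE,
        )
        with pytest.raises(IntegrityError):
            score_treatments(pset, methods=("cos_AC",))

    def test_technical_replicates_aggregated_by_median(self, ac_like_plate):
        series = score_treatments(ac_like_plate, methods=("vec_norm",))
        s = series[0]
        detail = s.well_scores
        expected = detail.groupby("concentration_uM")["raw_score"].median().sort_index()
        assert np.allclose(s.raw_score, expected.values)
        assert len(s.concentrations_uM) == 8  # one point per concentration


class TestReferenceContextConstruction:
    def test_ac_vector_is_per_gene_median(self):
        vals = np.array(
            [[0.0, 0.0], [0.1, -0.1], [-0.1, 0.1],
             [5.0, 1.0], [7.0, 3.0], [6.0, 2.0]]
        )
        roles = [Role.NC] * 3 + [Role.AC] * 3
        pset = make_plate(vals, roles, scale=Scale.RSCORE)
        ctx = build_reference_context(pset, methods=("vec_norm",))
        assert np.allclose(ctx.ac_vector, [6.0, 2.0])

    def test_covariance_shrunk_when_genes_exceed_wells(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(7, 10))  # 5 NC wells, 10 genes
        roles = [Role.NC] * 5 + [Role.AC] * 2
        pset = make_plate(vals, roles, scale=Scale.RSCORE)
        with pytest.warns(UserWarning, match="shrunk"):
            ctx = build_reference_context(pset, methods=("maha_NC",))
        assert ctx.cov_shrunk
        # usable: finite Mahalanobis distances
        assert np.isfinite(compute_score(rng.normal(size=10), ctx, "maha_NC"))
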