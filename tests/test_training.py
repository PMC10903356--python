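import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tici
from tici.exceptions import ValidationError

from conftest import make_monotone_fixture


def brute_force_spearman(x, y):
    """Independent oracle: explicit average ranks, then the Pearson formula."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den if den else 0.0


class TestSpearman:
    def test_perfect_correlation_is_one(self):
        x = list(range(1, 11))
        assert tici.spearman_rho(x, x) == pytest.approx(1.0)

    def test_perfect_inverse_is_minus_one(self):
        x = list(range(1, 11))
        assert tici.spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_vectors_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(3, 20))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n).astype(float)
            assert tici.spearman_rho(x, y) == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12)

    def test_matches_scipy_on_untied_data(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(9)
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            assert tici.spearman_rho(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12)

    def test_zero_variance_returns_neutral_zero(self):
        assert tici.spearman_rho([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tici.spearman_rho([1, 2], [1, 2, 3])

    @given(st.lists(st.integers(0, 6), min_size=2, max_size=25),
           st.data())
    def test_bounded_and_symmetric(self, x, data):
        y = data.draw(st.lists(st.integers(0, 6), min_size=len(x),
                               max_size=len(x)))
        rho = tici.spearman_rho(x, y)
        assert -1.0 <= rho <= 1.0
        assert rho == pytest.approx(tici.spearman_rho(y, x), abs=1e-12)


class TestIndicatorFromRho:
    @pytest.mark.parametrize("rho,expected", [
        (0.0, 5.0), (1.0, 10.0), (-1.0, 0.0), (0.4, 7.0)])
    def test_transform(self, rho, expected):
        assert tici.indicator_from_rho(rho) == pytest.approx(expected)

    @pytest.mark.parametrize("rho", [-1.01, 1.01, 2.0])
    def test_out_of_range_rejected(self, rho):
        with pytest.raises(ValueError):
            tici.indicator_from_rho(rho)


class TestSampleRawScore:
    def test_mean_of_present_values(self):
        values = np.array([2.0, 4.0, 9.0, 8.0])
        present = np.array([True, True, True, False])
        assert tici.sample_raw_score(present, values) == pytest.approx(5.0)

    def test_single_present_asv(self):
        assert tici.sample_raw_score([False, True],
                                     [1.0, 7.65]) == pytest.approx(7.65)

    def test_all_present_equals_full_mean(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 10, 50)
        got = tici.sample_raw_score(np.ones(50, bool), values)
        assert got == pytest.approx(values.mean())

    def test_no_indicator_present_is_undefined(self):
        assert np.isnan(tici.sample_raw_score([False, False], [1.0, 2.0]))


class TestInits:
    def test_random_init_deterministic_per_seed(self):
        sites = [f"S{i}" for i in range(12)]
        a = tici.random_init(sites, 7)
        b = tici.random_init(sites, 7)
        np.testing.assert_array_equal(a.ranks, b.ranks)
        c = tici.random_init(sites, 8)
        assert not np.array_equal(a.ranks, c.ranks)

    def test_random_init_ranks_are_permutation(self):
        r = tici.random_init([f"S{i}" for i in range(9)], 0)
        assert sorted(r.ranks.tolist()) == list(range(1, 10))

    def test_guided_init_ascending(self):
        r = tici.guided_init(["a", "b", "c"], {"a": 10, "b": 20, "c": 30})
        np.testing.assert_array_equal(r.ranks, [1, 2, 3])

    def test_guided_init_ties_get_average_ranks(self):
        r = tici.guided_init(["a", "b", "c"], {"a": 5, "b": 5, "c": 9})
        np.testing.assert_array_equal(r.ranks, [1.5, 1.5, 3])

    def test_guided_init_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        sites = [f"S{i}" for i in range(15)]
        scores = dict(zip(sites, rng.normal(size=15)))
        r = tici.guided_init(sites, scores)
        order = sorted(sites, key=scores.get)
        expected = {s: i + 1 for i, s in enumerate(order)}
        assert r.as_dict() == expected


class TestChessmanTrain:
    def _train_fixture(self, init_seed=0, reverse=False):
        table, design, sites = make_monotone_fixture()
        pm = tici.presence_matrix(table)
        asvs = pm.asvs
        if reverse:
            n = len(sites)
            init = tici.SiteRanking(sites=sites,
                                    ranks=np.arange(n, 0, -1.0),
                                    basis="guided_init")
        elif init_seed is None:
            init = tici.SiteRanking(sites=sites,
                                    ranks=np.arange(1.0, len(sites) + 1),
                                    basis="guided_init")
        else:
            init = tici.random_init(sites, init_seed)
        return tici.chessman_train(pm, design, asvs, init), sites, design, pm

    def test_constant_prevalence_gives_all_fives_one_iteration(self):
        import pandas as pd
        rows = [(f"S{i}_r{r}", "a1", "CI", 9)
                for i in range(4) for r in range(3)]
        table = tici.ASVTable.from_records(
            pd.DataFrame(rows, columns=["sample_id", "asv_id", "assay",
                                        "count"]))
        design = tici.SiteDesign(
            samples={f"S{i}_r{r}": (f"S{i}", "field_sample")
                     for i in range(4) for r in range(3)})
        pm = tici.presence_matrix(table)
        init = tici.random_init([f"S{i}" for i in range(4)], 0)
        model, trace = tici.chessman_train(pm, design, pm.asvs, init)
        assert trace.converged_by == "fixed_point"
        assert model.training_meta.iterations == 1
        assert all(e.indicator_value == 5.0 for e in model.entries.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_noiseless_gradient_recovers_ranking_or_reverse(self, seed):
        (model, trace), sites, design, _ = self._train_fixture(seed)
        scores = trace.final_site_scores
        rho = tici.spearman_rho([scores[s] for s in sites],
                                list(range(len(sites))))
        assert abs(rho) == pytest.approx(1.0)
        assert trace.converged_by in ("fixed_point", "cycle")

    def test_same_seed_gives_bit_identical_model(self):
        (m1, _), _, _, _ = self._train_fixture(5)
        (m2, _), _, _, _ = self._train_fixture(5)
        assert m1.entries == m2.entries
        assert m1.training_meta == m2.training_meta

    def test_reversed_init_yields_mirrored_model(self):
        (m_fwd, _), _, _, _ = self._train_fixture(None)
        (m_rev, _), _, _, _ = self._train_fixture(None, reverse=True)
        vf = m_fwd.values_series()
        vr = m_rev.values_series().reindex(vf.index)
        np.testing.assert_allclose(vr.to_numpy(), 10.0 - vf.to_numpy(),
                                   atol=1e-12)

    def test_reinit_at_converged_ranking_stops_after_one_iteration(self):
        (model, trace), sites, design, pm = self._train_fixture(1)
        from scipy.stats import rankdata
        scores = trace.final_site_scores
        ranking = tici.SiteRanking(
            sites=sites,
            ranks=rankdata([scores[s] for s in sites]),
            basis="tici_update")
        model2, trace2 = tici.chessman_train(pm, design, pm.asvs, ranking)
        assert trace2.converged_by == "fixed_point"
        assert model2.training_meta.iterations == 1
        assert model2.values_series().equals(model.values_series())

    def test_constant_asv_scores_neutral_five(self):
        (model, _), _, _, _ = self._train_fixture(0)
        assert model.entries["ubiq"].indicator_value == 5.0

    def test_values_always_in_scale(self, small_model):
        oriented, unoriented, _ = small_model
        for m in (oriented, unoriented):
            v = m.values_series().to_numpy()
            assert v.min() >= 0.0 and v.max() <= 10.0

    def test_too_few_sites_rejected(self):
        import pandas as pd
        rows = [(f"S{i}_r0", "a1", "CI", 9) for i in range(2)]
        table = tici.ASVTable.from_records(
            pd.DataFrame(rows, columns=["sample_id", "asv_id", "assay",
                                        "count"]))
        design = tici.SiteDesign(
            samples={f"S{i}_r0": (f"S{i}", "field_sample") for i in range(2)})
        pm = tici.presence_matrix(table)
        init = tici.random_init(["S0", "S1"], 0)
        with pytest.raises(ValidationError, match="3 sites"):
            tici.chessman_train(pm, design, pm.asvs, init)


class TestOrientModel:
    def _model(self, values):
        return tici.IndicatorModel(
            entries={f"a{i}": tici.IndicatorEntry(v)
                     for i, v in enumerate(values)})

    def test_positive_correlation_unchanged(self):
        m = self._model([2.0, 8.0])
        scores = {"s1": 1.0, "s2": 2.0, "s3": 3.0}
        out = tici.orient_model(m, scores, {"s1": 10, "s2": 20, "s3": 30})
        assert out.entries == m.entries
        assert out.orientation == "as_trained"

    def test_negative_correlation_inverts(self):
        m = self._model([2.0, 8.0])
        scores = {"s1": 3.0, "s2": 2.0, "s3": 1.0}
        out = tici.orient_model(m, scores, {"s1": 10, "s2": 20, "s3": 30})
        assert out.orientation == "inverted"
        assert [e.indicator_value for e in out.entries.values()] == [8.0, 2.0]

    def test_double_orientation_is_identity(self, small_survey, small_model):
        table, design, _ = small_survey
        oriented, _, trace = small_model
        ref = design.reference_scores()
        report = tici.score_survey(table, design, oriented)
        site_scores = dict(zip(report.per_site["site_id"],
                               report.per_site["tici_mean"]))
        again = tici.orient_model(oriented, site_scores, ref)
        assert again.orientation == oriented.orientation
        assert again.entries == oriented.entries

    def test_inversion_negates_site_score_correlation(self, small_survey,
                                                      small_model):
        table, design, _ = small_survey
        oriented, _, _ = small_model
        ref = design.reference_scores()
        sites = sorted(ref)

        def site_rho(model):
            rep = tici.score_survey(table, design, model)
            tmean = dict(zip(rep.per_site["site_id"],
                             rep.per_site["tici_mean"]))
            return tici.spearman_rho([tmean[s] for s in sites],
                                     [ref[s] for s in sites])

        assert site_rho(oriented.inverted()) == pytest.approx(
            -site_rho(oriented), abs=1e-12)

    def test_too_few_overlapping_sites_rejected(self):
        m = self._model([5.0])
        with pytest.raises(ValidationError, match="3"):
            tici.orient_model(m, {"s1": 1.0, "s2": 2.0},
                              {"s1": 1.0, "s2": 2.0})


class TestReproducibility:
    def test_random_seeds_converge_to_same_oriented_model(self, small_survey):
        """Training is insensitive to the random initial ranking: after
        orientation, runs from different seeds agree (R^2 >= 0.99)."""
        table, design, _ = small_survey
        pm = tici.presence_matrix(table)
        indicators = tici.select_indicators(pm, design, 200)
        ref = design.reference_scores()
        models = []
        for seed in range(5):
            init = tici.random_init(sorted(design.site_ids), seed)
            m, trace = tici.chessman_train(pm, design, indicators, init)
            models.append(tici.orient_model(m, trace.final_site_scores, ref))
        r2 = [tici.compare_models(models[0], m)[0] for m in models[1:]]
        assert sum(r >= 0.99 for r in r2) >= 3
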