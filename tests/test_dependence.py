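import warnings

import numpy as np
import pandas as pd
import pytest

from holopipe.dependence import DependenceParams, select_dependent, spearman_profile
from holopipe.simulate import ExpressionSimConfig, gen_counts
from tests.conftest import make_matrix


def rank_oracle_rho(x, y):
    """Spearman rho from first principles: average ranks by pairwise
    comparison counting, then the Pearson formula on those ranks."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(v.size)
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def profile_matrix(rows, sheet):
    return make_matrix(np.asarray(rows, dtype=np.int64), sheet)


class TestSpearman:
    def test_driver_vs_itself_is_one(self, two_group_sheet):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 500, size=(5, 6))
        cm = profile_matrix(counts, two_group_sheet)
        rho = spearman_profile(cm, cm.transcript_ids[0])
        assert rho[cm.transcript_ids[0]] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, two_group_sheet):
        driver = np.array([10, 20, 40, 80, 160, 320])
        # a strictly increasing transform of the driver has identical ranks;
        # constant majority genes pin the size factors at 1
        gene = np.array([1, 3, 9, 27, 81, 243])
        counts = np.vstack([driver, gene, np.full(6, 50), np.full(6, 80), np.full(6, 120)])
        cm = profile_matrix(counts, two_group_sheet)
        rho = spearman_profile(cm, cm.transcript_ids[0])
        assert rho.iloc[1] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, two_group_sheet):
        driver = np.array([10, 20, 40, 80, 160, 320])
        counts = np.vstack([driver, driver[::-1], np.full(6, 50), np.full(6, 80), np.full(6, 120)])
        cm = profile_matrix(counts, two_group_sheet)
        rho = spearman_profile(cm, cm.transcript_ids[0])
        assert rho.iloc[1] == pytest.approx(-1.0)

    def test_constant_gene_reported_nan(self, two_group_sheet):
        driver = np.array([10, 20, 40, 80, 160, 320])
        # two constant majority genes pin the size factors at 1, so the
        # constant gene stays constant after normalization
        counts = np.vstack([driver, np.full(6, 7), np.full(6, 50)])
        cm = profile_matrix(counts, two_group_sheet)
        rho = spearman_profile(cm, cm.transcript_ids[0])
        assert np.isnan(rho.iloc[1])

    def test_matches_rank_oracle_small_n(self, two_group_sheet):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 30, size=(4, 6))  # small values force ties
            counts[:, 0] += 1
            cm = profile_matrix(counts, two_group_sheet)
            from holopipe.de import median_of_ratios_size_factors

            try:
                factors = median_of_ratios_size_factors(cm.counts)
            except ValueError:
                continue
            y = cm.counts / factors[None, :]
            rho = spearman_profile(cm, cm.transcript_ids[0])
            for i in range(1, 4):
                expected = rank_oracle_rho(y[0], y[i])
                if np.isnan(rho.iloc[i]):
                    assert np.isnan(expected) or np.unique(y[i]).size < 2
                else:
                    assert rho.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_errors(self, two_group_sheet):
        cm = profile_matrix(np.ones((2, 6)), two_group_sheet)
        with pytest.raises(ValueError):
            spearman_profile(cm, cm.transcript_ids[0], scope=["s0", "s1"])


class TestSelection:
    def _de(self, rows):
        return pd.DataFrame(rows)

    def test_rho_at_threshold_selected(self):
        rho = pd.Series({"driver": 1.0, "g": 0.8})
        de = self._de(
            [
                {"transcript_id": "driver", "log2fc": 2.0, "p_adj": 0.001},
                {"transcript_id": "g", "log2fc": 0.0, "p_adj": 0.9},
            ]
        )
        out = select_dependent(rho, de, DependenceParams("driver")).set_index("transcript_id")
        assert out.loc["g", "selected"] and out.loc["g", "selection_route"] == "by_rho"

    def test_de_route(self):
        rho = pd.Series({"driver": 1.0, "g": 0.3})
        de = self._de(
            [
                {"transcript_id": "driver", "log2fc": 2.0, "p_adj": 0.001},
                {"transcript_id": "g", "log2fc": 1.2, "p_adj": 0.05},
            ]
        )
        out = select_dependent(rho, de, DependenceParams("driver")).set_index("transcript_id")
        assert out.loc["g", "selected"] and out.loc["g", "selection_route"] == "by_de"

    def test_upregulated_in_knockdown_needs_absolute_flag(self):
        rho = pd.Series({"driver": 1.0, "g": 0.0})
        de = self._de(
            [
                {"transcript_id": "driver", "log2fc": 2.0, "p_adj": 0.001},
                {"transcript_id": "g", "log2fc": -1.2, "p_adj": 0.05},
            ]
        )
        directional = select_dependent(rho, de, DependenceParams("driver")).set_index("transcript_id")
        assert not directional.loc["g", "selected"]
        agnostic = select_dependent(
            rho, de, DependenceParams("driver", absolute_lfc=True)
        ).set_index("transcript_id")
        assert agnostic.loc["g", "selected"]

    def test_selection_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        rho = pd.Series(rng.uniform(-1, 1, 50), index=genes)
        de = self._de(
            [
                {"transcript_id": g, "log2fc": rng.normal(0, 1.5), "p_adj": rng.random()}
                for g in genes
            ]
            + [{"transcript_id": "driver", "log2fc": 2.0, "p_adj": 0.001}]
        )
        strict = select_dependent(rho, de, DependenceParams("driver", rho_min=0.9, alpha=0.05))
        loose = select_dependent(rho, de, DependenceParams("driver", rho_min=0.7, alpha=0.2))
        strict_sel = set(strict.loc[strict["selected"], "transcript_id"])
        loose_sel = set(loose.loc[loose["selected"], "transcript_id"])
        assert strict_sel <= loose_sel

    def test_nan_rho_never_selected_by_rho(self):
        rho = pd.Series({"driver": 1.0, "g": np.nan})
        de = self._de(
            [
                {"transcript_id": "driver", "log2fc": 2.0, "p_adj": 0.001},
                {"transcript_id": "g", "log2fc": 0.0, "p_adj": 1.0},
            ]
        )
        out = select_dependent(rho, de, DependenceParams("driver")).set_index("transcript_id")
        assert not out.loc["g", "selected"]

    def test_driver_absent_from_de_warns_and_disables_route(self):
        rho = pd.Series({"driver": 1.0, "g": 0.3})
        de = self._de([{"transcript_id": "g", "log2fc": 2.0, "p_adj": 0.001}])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = select_dependent(rho, de, DependenceParams("driver")).set_index("transcript_id")
        assert any("driver" in str(w.message) for w in rec)
        assert not out.loc["g", "selected"]


class TestNullCalibration:
    def test_null_simulation_selects_almost_nothing(self):
        # no coupling, no knockdown wave effects: only the driver itself
        # varies, so neither route should fire for null genes beyond the
        # nominal rates
        cfg = ExpressionSimConfig(
            n_genes=500, n_early=0, n_late=0, n_overlap=0, n_dependent=0,
            timepoints=("0hpa", "3hpa"), seed=13,
        )
        cm, truth = gen_counts(cfg)
        from holopipe import de as de_mod

        rho = spearman_profile(cm, "driver")
        a = cm.sheet.samples_where(timepoint="3hpa", condition="control")
        b = cm.sheet.samples_where(timepoint="3hpa", condition="runt_rnai")
        de_res = de_mod.run_de(cm, a, b)
        out = select_dependent(rho, de_res, DependenceParams("driver"))
        selected = out[out["selected"] & (out["transcript_id"] != "driver")]
        assert len(selected) / 500 <= 0.02
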