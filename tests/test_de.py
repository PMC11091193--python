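import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from holopipe.de import (
    DEGFilter,
    call_degs,
    compare_waves,
    estimate_dispersions,
    median_of_ratios_size_factors,
    nb_wald_test,
    run_de,
    species_read_fractions,
    split_by_species,
)
from tests.conftest import make_matrix


def calls_frame(mapping, flags=None):
    flags = flags or {}
    return pd.DataFrame(
        {
            "transcript_id": list(mapping),
            "label": list(mapping.values()),
            "chloroplast_flag": [flags.get(t, False) for t in mapping],
        }
    )


class TestSplit:
    def test_ambiguous_excluded_from_both(self, two_group_sheet):
        labels = {}
        for i in range(5):
            labels[f"g{i:04d}"] = "host"
        for i in range(5, 8):
            labels[f"g{i:04d}"] = "symbiont"
        labels["g0008"] = "ambiguous"  # chloroplast-flagged, already ambiguous
        labels["g0009"] = "ambiguous"
        cm = make_matrix(np.ones((10, 6), dtype=np.int64), two_group_sheet)
        calls = calls_frame(labels, flags={"g0008": True})
        host, symb = split_by_species(cm, calls)
        assert host.shape == (5, 6)
        assert symb.shape == (3, 6)

    def test_all_host_errors(self, two_group_sheet):
        cm = make_matrix(np.ones((3, 6), dtype=np.int64), two_group_sheet)
        calls = calls_frame({f"g{i:04d}": "host" for i in range(3)})
        with pytest.raises(ValueError):
            split_by_species(cm, calls)

    def test_flag_never_lives_on_symbiont(self, two_group_sheet):
        labels = {"g0000": "host", "g0001": "symbiont", "g0002": "symbiont"}
        cm = make_matrix(np.ones((3, 6), dtype=np.int64), two_group_sheet)
        calls = calls_frame(labels)
        _, symb_drop = split_by_species(cm, calls, drop_chloroplast=True)
        _, symb_keep = split_by_species(cm, calls, drop_chloroplast=False)
        assert symb_drop.shape == symb_keep.shape == (2, 6)


class TestReadFractions:
    def test_all_host(self, two_group_sheet):
        cm = make_matrix(np.full((4, 6), 5, dtype=np.int64), two_group_sheet)
        calls = calls_frame({f"g{i:04d}": "host" for i in range(4)})
        frac = species_read_fractions(cm, calls)
        assert np.allclose(frac["frac_host"], 1.0)
        assert np.allclose(frac["frac_symbiont"], 0.0)

    def test_even_split(self, two_group_sheet):
        cm = make_matrix(np.full((4, 6), 5, dtype=np.int64), two_group_sheet)
        labels = {"g0000": "host", "g0001": "host", "g0002": "symbiont", "g0003": "symbiont"}
        frac = species_read_fractions(cm, calls_frame(labels))
        assert np.allclose(frac["frac_host"], 0.5)
        assert np.allclose(frac["frac_ambiguous"], 0.0)

    def test_matches_independent_summation(self, two_group_sheet):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, size=(30, 6))
        counts[:, 0] += 1  # avoid a zero-total sample
        labels = rng.choice(["host", "symbiont", "ambiguous"], size=30)
        cm = make_matrix(counts, two_group_sheet)
        calls = calls_frame(dict(zip(cm.transcript_ids, labels)))
        frac = species_read_fractions(cm, calls)
        totals = frac[["frac_host", "frac_symbiont", "frac_ambiguous"]].sum(axis=1)
        assert np.allclose(totals, 1.0)
        j = 2
        expected = counts[labels == "host", j].sum() / counts[:, j].sum()
        assert frac["frac_host"].iloc[j] == pytest.approx(expected)

    def test_zero_total_sample_errors(self, two_group_sheet):
        counts = np.ones((3, 6), dtype=np.int64)
        counts[:, 4] = 0
        cm = make_matrix(counts, two_group_sheet)
        with pytest.raises(ValueError, match="s4"):
            species_read_fractions(cm, calls_frame({t: "host" for t in cm.transcript_ids}))


class TestSizeFactors:
    def test_identical_samples(self):
        counts = np.tile(np.array([[10], [20], [30]]), (1, 2))
        assert np.allclose(median_of_ratios_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        a = np.array([10, 20, 50, 100])
        counts = np.column_stack([a, 2 * a])
        f = median_of_ratios_size_factors(counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(100, 5))
        f1 = median_of_ratios_size_factors(counts)
        f2 = median_of_ratios_size_factors(7 * counts)
        assert np.allclose(f1, f2)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 500, size=(50, 7))
        f = median_of_ratios_size_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_no_reference_gene_errors(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError):
            median_of_ratios_size_factors(counts)


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Direct textbook step-up: q_(i) = min over j>=i of m p_(j) / j."""
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


class TestBenjaminiHochberg:
    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 200)))
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, bh_step_up(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        p = rng.random(500)
        q = multipletests(p, method="fdr_bh")[1]
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDispersions:
    def _matrix(self, counts, sheet):
        return make_matrix(counts, sheet)

    def test_poisson_data_low_dispersion(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(100.0, size=(400, 20))
        sheet = _sheet_n(10)
        cm = make_matrix(counts, sheet)
        disp = estimate_dispersions(cm, np.ones(20))
        assert np.median(disp) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(7)
        size = 1 / 0.2
        counts = rng.negative_binomial(size, size / (size + 100.0), size=(400, 20))
        cm = make_matrix(counts, _sheet_n(10))
        disp = estimate_dispersions(cm, np.ones(20))
        assert 0.1 <= np.median(disp) <= 0.3

    def test_constant_gene_hits_lower_bound(self):
        counts = np.full((20, 6), 50, dtype=np.int64)
        counts[0] = 50  # constant gene among Poisson-varying ones
        rng = np.random.default_rng(8)
        counts[1:] = rng.poisson(50.0, size=(19, 6))
        cm = make_matrix(counts, _sheet_n(3))
        disp = estimate_dispersions(cm, np.ones(6), shrink_weight=1.0)
        assert disp[0] <= 1e-3

    def test_single_sample_errors(self):
        rows = pd.DataFrame(
            [{"sample_id": "s0", "timepoint": "0hpa", "condition": "control", "replicate": 1}]
        )
        from holopipe.io import SampleSheet

        cm = make_matrix(np.ones((3, 1), dtype=np.int64), SampleSheet(rows))
        with pytest.raises(ValueError):
            estimate_dispersions(cm, np.ones(1))


def _sheet_n(n_per_group):
    from holopipe.io import SampleSheet

    rows = [
        {
            "sample_id": f"s{j}",
            "timepoint": "0hpa",
            "condition": "control" if j < n_per_group else "runt_rnai",
            "replicate": j % n_per_group + 1,
        }
        for j in range(2 * n_per_group)
    ]
    return SampleSheet(pd.DataFrame(rows))


class TestWaldTest:
    def test_equal_groups_near_zero(self):
        counts = np.tile(np.array([[100], [500], [50]]), (1, 6)).astype(np.int64)
        cm = make_matrix(counts, _sheet_n(3))
        res = nb_wald_test(cm, np.ones(6), np.full(3, 0.1), ([f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)]))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["wald"].abs() < 0.1).all()
        assert (res["p"] > 0.9).all()

    def test_all_zero_gene_excluded_from_family(self):
        counts = np.ones((5, 6), dtype=np.int64) * 50
        counts[2] = 0
        cm = make_matrix(counts, _sheet_n(3))
        res = nb_wald_test(cm, np.ones(6), np.full(5, 0.1), ([f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)]))
        assert np.isnan(res["p"].iloc[2]) and np.isnan(res["p_adj"].iloc[2])
        assert res["p"].drop(index=2).notna().all()

    def test_wald_equals_lfc_over_se(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 300, size=(40, 6)).astype(np.int64)
        cm = make_matrix(counts, _sheet_n(3))
        res = nb_wald_test(cm, np.ones(6), np.full(40, 0.1), ([f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)]))
        ok = res["se"] > 0
        assert np.allclose(res.loc[ok, "wald"], res.loc[ok, "log2fc"] / res.loc[ok, "se"])

    def test_overlapping_groups_rejected(self):
        cm = make_matrix(np.ones((2, 6), dtype=np.int64), _sheet_n(3))
        with pytest.raises(ValueError):
            nb_wald_test(cm, np.ones(6), np.ones(2), (["s0", "s1"], ["s1", "s2"]))


class TestDEGCalls:
    def test_thresholds_inclusive(self):
        res = pd.DataFrame(
            {
                "transcript_id": ["at", "below"],
                "log2fc": [0.8, 0.79],
                "p_adj": [0.05, 0.001],
            }
        )
        up, down = call_degs(res, DEGFilter())
        assert up == {"at"} and down == set()

    def test_direction_restriction(self):
        res = pd.DataFrame(
            {
                "transcript_id": ["u", "d"],
                "log2fc": [1.0, -1.0],
                "p_adj": [0.01, 0.01],
            }
        )
        up, down = call_degs(res, DEGFilter(direction="up"))
        assert up == {"u"} and down == set()


class TestCompareWaves:
    def test_small_example(self):
        only1, only2, shared = compare_waves({"A", "B", "C"}, {"C", "D"})
        assert only1 == {"A", "B"} and only2 == {"D"} and shared == {"C"}

    def test_disjoint(self):
        _, _, shared = compare_waves({"A"}, {"B"})
        assert shared == set()

    @settings(max_examples=30, derandomize=True)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_partition_of_union(self, s1, s2):
        only1, only2, shared = compare_waves(s1, s2)
        assert len(only1) + len(only2) + len(shared) == len(s1 | s2)
        assert only1 | only2 | shared == s1 | s2
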