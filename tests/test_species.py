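import numpy as np
import pandas as pd
import pytest

from holopipe.io import TranscriptSet
from holopipe.simulate import HolobiontSimConfig, gen_enrichment_profiles, gen_transcriptomes
from holopipe.species import (
    GateSpec,
    classify,
    compute_enrichment_profiles,
    fit_auto_gates,
    flag_chloroplast,
    gc_separation_report,
)


def profile_row(tid="t", length=1000, rh=0, rs=0, gc=0.5):
    return {
        "transcript_id": tid,
        "length": length,
        "reads_host_enr": rh,
        "reads_symb_enr": rs,
        "depth_host_enr": rh / length,
        "depth_symb_enr": rs / length,
        "breadth_host_enr": np.nan,
        "breadth_symb_enr": np.nan,
        "gc": gc,
    }


class TestEnrichmentProfiles:
    def test_depth_formula(self):
        ts = TranscriptSet([("t1", "A" * 1000)])
        table = compute_enrichment_profiles(ts, {"t1": 100}, {"t1": 10})
        assert table["depth_host_enr"].iloc[0] == pytest.approx(0.1)
        assert table["depth_symb_enr"].iloc[0] == pytest.approx(0.01)

    def test_breadth_passthrough(self):
        ts = TranscriptSet([("t1", "ACGT")])
        table = compute_enrichment_profiles(
            ts, {"t1": 4}, {"t1": 1}, {"t1": 1.0}, {"t1": 0.25}
        )
        assert table["breadth_host_enr"].iloc[0] == 1.0

    def test_gc_ignores_n(self):
        ts = TranscriptSet([("a", "ATGC"), ("b", "ATGN")])
        table = compute_enrichment_profiles(
            ts, {"a": 1, "b": 1}, {"a": 1, "b": 1}
        ).set_index("transcript_id")
        assert table.loc["a", "gc"] == pytest.approx(0.5)
        assert table.loc["b", "gc"] == pytest.approx(1 / 3)

    def test_unknown_transcript_in_counts_errors(self):
        ts = TranscriptSet([("t1", "ACGT")])
        with pytest.raises(ValueError):
            compute_enrichment_profiles(ts, {"t1": 1, "ghost": 2}, {"t1": 1, "ghost": 2})

    def test_missing_counts_errors(self):
        ts = TranscriptSet([("t1", "ACGT")])
        with pytest.raises(ValueError, match="t1"):
            compute_enrichment_profiles(ts, {}, {})


class TestGatesAndClassify:
    def test_clear_host_call(self):
        table = pd.DataFrame(
            [profile_row("h", rh=500, rs=1), profile_row("s", rh=1, rs=500)]
        )
        gates = fit_auto_gates(table)
        calls = classify(table, gates).set_index("transcript_id")
        assert calls.loc["h", "label"] == "host"
        assert calls.loc["s", "label"] == "symbiont"

    def test_equal_depths_ambiguous(self):
        table = pd.DataFrame(
            [profile_row("x", rh=100, rs=100), profile_row("y", rh=300, rs=1)]
        )
        gates = fit_auto_gates(table)
        calls = classify(table, gates).set_index("transcript_id")
        assert calls.loc["x", "label"] == "ambiguous"

    def test_partition_property(self):
        cfg = HolobiontSimConfig(n_host=100, n_symbiont=80, n_shared=10, seed=2)
        ts, truth = gen_transcriptomes(cfg)
        table = gen_enrichment_profiles(ts, truth, cfg)
        calls = classify(table, fit_auto_gates(table))
        counts = calls["label"].value_counts()
        assert counts.sum() == len(table)

    def test_shrinking_regions_only_moves_to_ambiguous(self):
        cfg = HolobiontSimConfig(n_host=150, n_symbiont=100, n_shared=5, seed=3)
        ts, truth = gen_transcriptomes(cfg)
        table = gen_enrichment_profiles(ts, truth, cfg)
        loose = classify(table, fit_auto_gates(table, min_log10_ratio=0.5))
        tight = classify(table, fit_auto_gates(table, min_log10_ratio=1.5))
        merged = loose.merge(tight, on="transcript_id", suffixes=("_loose", "_tight"))
        changed = merged[merged["label_loose"] != merged["label_tight"]]
        assert (changed["label_tight"] == "ambiguous").all()

    def test_scaling_reads_preserves_labels(self):
        cfg = HolobiontSimConfig(n_host=100, n_symbiont=100, n_shared=0, seed=4)
        ts, truth = gen_transcriptomes(cfg)
        table = gen_enrichment_profiles(ts, truth, cfg)
        scaled = table.copy()
        for col in ("reads_host_enr", "reads_symb_enr"):
            scaled[col] = scaled[col] * 7
        for col, reads in (("depth_host_enr", "reads_host_enr"), ("depth_symb_enr", "reads_symb_enr")):
            scaled[col] = scaled[reads] / scaled["length"]
        c1 = classify(table, fit_auto_gates(table))
        c2 = classify(scaled, fit_auto_gates(scaled))
        assert (c1["label"].to_numpy() == c2["label"].to_numpy()).all()

    def test_manual_gates_round_trip(self):
        spec = GateSpec(mode="manual", host_box=(-1.0, 2.0, -5.0, -2.0),
                        symbiont_box=(-5.0, -2.0, -1.0, 2.0))
        back = GateSpec.from_dict(spec.to_dict())
        assert back == spec

    def test_all_zero_depths_error(self):
        table = pd.DataFrame([profile_row("a"), profile_row("b")])
        with pytest.raises(ValueError):
            fit_auto_gates(table)


class TestChloroplastFlag:
    def _setup(self):
        rows = [profile_row(f"bg{i}", rh=10, rs=10) for i in range(18)]
        rows.append(profile_row("amb_hi", rh=900, rs=900))
        rows.append(profile_row("host_hi", rh=900, rs=900))
        table = pd.DataFrame(rows)
        calls = pd.DataFrame(
            {
                "transcript_id": table["transcript_id"],
                "label": ["ambiguous"] * 19 + ["host"],
                "chloroplast_flag": False,
            }
        )
        return table, calls

    def test_rule_conjunction(self):
        table, calls = self._setup()
        out = flag_chloroplast(calls, table, {"amb_hi": {"GO:0009507"}}).set_index("transcript_id")
        assert out.loc["amb_hi", "chloroplast_flag"]

    def test_no_annotation_not_flagged(self):
        table, calls = self._setup()
        out = flag_chloroplast(calls, table, {}).set_index("transcript_id")
        assert not out["chloroplast_flag"].any()

    def test_host_label_never_flagged(self):
        table, calls = self._setup()
        out = flag_chloroplast(calls, table, {"host_hi": {"GO:0009535"}}).set_index("transcript_id")
        assert not out.loc["host_hi", "chloroplast_flag"]

    def test_low_depth_ambiguous_not_flagged(self):
        table, calls = self._setup()
        out = flag_chloroplast(calls, table, {"bg0": {"GO:0009507"}}).set_index("transcript_id")
        assert not out.loc["bg0", "chloroplast_flag"]


class TestGCReport:
    def test_planted_gc_means_recovered(self):
        cfg = HolobiontSimConfig(n_host=200, n_symbiont=200, n_shared=0,
                                 gc_host_mean=0.40, gc_symbiont_mean=0.58, seed=6)
        ts, truth = gen_transcriptomes(cfg)
        table = gen_enrichment_profiles(ts, truth, cfg)
        calls = classify(table, fit_auto_gates(table))
        rep = gc_separation_report(table, calls)
        assert abs(rep["groups"]["host"]["gc_mean"] - 0.40) < 0.03
        assert abs(rep["groups"]["symbiont"]["gc_mean"] - 0.58) < 0.03
        assert rep["separation"]["p"] < 1e-6

    def test_identical_gc_no_separation(self):
        rows = [profile_row(f"h{i}", rh=500, rs=1, gc=0.5) for i in range(20)]
        rows += [profile_row(f"s{i}", rh=1, rs=500, gc=0.5) for i in range(20)]
        table = pd.DataFrame(rows)
        calls = classify(table, fit_auto_gates(table))
        rep = gc_separation_report(table, calls)
        assert rep["separation"]["p"] > 0.9
        assert abs(rep["separation"]["auc"] - 0.5) < 0.05

    def test_single_group_report(self):
        rows = [profile_row(f"h{i}", rh=500, rs=1, gc=0.4) for i in range(5)]
        table = pd.DataFrame(rows)
        calls = classify(table, fit_auto_gates(table))
        rep = gc_separation_report(table, calls)
        assert "separation" not in rep
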