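import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from consistentprot import differential as dm
from consistentprot import io_formats as io
from consistentprot import preprocess_qc as pre
from consistentprot import synthdata as sd
from oracles import classify_by_rule_text

UNDEF = None
GRID = [0.3, 0.5, 0.51, 0.9, 1.0, 1.1, 1.2, 1.3, UNDEF]


def _design(rows):
    return io.SampleDesign(pd.DataFrame(
        rows, columns=["sample_label", "donor", "condition", "tech_rep"]
    ))


def _ratio_row(pid, donor, kd, nt):
    return {
        "protein_group_id": pid, "donor": donor, "kd_value": kd, "nt_value": nt,
        "detected_kd": kd > 0, "detected_nt": nt > 0,
        "ratio": kd / nt if kd > 0 and nt > 0 else np.nan,
    }


class TestAggregateTechnical:
    def _setup(self, runs):
        idx = pd.Index(["P1"], name="protein_group_id")
        ann = pd.DataFrame({"gene_name": [""], "is_reverse": [False],
                            "is_contaminant": [False], "is_keratin": [False],
                            "n_theoretical_peptides": [1]}, index=idx)
        labels = [f"S{i}" for i in range(len(runs))]
        inten = pd.DataFrame([runs], index=idx, columns=labels, dtype=float)
        design = _design([(lab, "A", "KD", i + 1) for i, lab in enumerate(labels)])
        return io.ProteinQuantTable(ann, inten), design

    def test_mean_over_detected_runs(self):
        t, d = self._setup([100.0, 110.0, 0.0, 90.0])
        agg = dm.aggregate_technical(t, d)
        assert agg.loc[0, "value"] == 100.0
        assert agg.loc[0, "n_detected"] == 3

    def test_all_undetected_gives_zero(self):
        t, d = self._setup([0.0, 0.0, 0.0, 0.0])
        agg = dm.aggregate_technical(t, d)
        assert agg.loc[0, "value"] == 0.0
        assert agg.loc[0, "n_detected"] == 0

    def test_single_run_identity(self):
        t, d = self._setup([42.0])
        assert dm.aggregate_technical(t, d).loc[0, "value"] == 42.0


class TestDonorRatios:
    def test_ratio_conventions(self):
        agg = pd.DataFrame(
            [("P1", "A", "KD", 50.0, 2), ("P1", "A", "NT", 100.0, 2),
             ("P2", "A", "KD", 0.0, 0), ("P2", "A", "NT", 100.0, 2),
             ("P3", "A", "KD", 120.0, 2), ("P3", "A", "NT", 100.0, 2)],
            columns=["protein_group_id", "donor", "condition", "value", "n_detected"],
        )
        r = dm.donor_ratios(agg).set_index("protein_group_id")
        assert r.loc["P1", "ratio"] == 0.5
        assert np.isnan(r.loc["P2", "ratio"]) and not r.loc["P2", "detected_kd"]
        assert r.loc["P3", "ratio"] == pytest.approx(1.2)

    def test_donor_missing_condition_excluded_with_warning(self):
        agg = pd.DataFrame(
            [("P1", "A", "KD", 50.0, 2), ("P1", "A", "NT", 100.0, 2),
             ("P1", "B", "KD", 10.0, 2)],
            columns=["protein_group_id", "donor", "condition", "value", "n_detected"],
        )
        with pytest.warns(UserWarning, match="B"):
            r = dm.donor_ratios(agg)
        assert list(r["donor"].unique()) == ["A"]


class TestEligibility:
    @pytest.mark.parametrize("n_detected,expected", [(4, True), (3, True), (2, False)])
    def test_detected_in_enough_donors(self, n_detected, expected):
        rows = []
        for i, donor in enumerate("ABCD"):
            detected = i < n_detected
            rows.append(_ratio_row("P1", donor, 1.0 if detected else 0.0,
                                   2.0 if detected else 0.0))
        eligible = dm.eligibility_filter(pd.DataFrame(rows))
        assert ("P1" in eligible) is expected

    def test_detection_in_one_condition_counts(self):
        rows = [_ratio_row("P1", d, 0.0, 5.0) for d in "ABC"]
        rows.append(_ratio_row("P1", "D", 0.0, 0.0))
        assert "P1" in dm.eligibility_filter(pd.DataFrame(rows))


class TestClassifyConsistency:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ([0.4, 0.45, 0.5, 0.9], "DOWN"),   # all reduced, three <= 0.5
            ([0.4, 0.4, 0.4, 1.1], "NS"),      # not reduced in all four
            ([1.3, 1.25, 1.2, 1.05], "UP"),    # all increased, three >= 1.2
            ([0.3, 0.3, None, None], "DOWN"),  # two undetectable allowed
            ([0.3, None, None, None], "NS"),   # three undetectable: too many
            ([0.5, 0.5, 0.5, 0.5], "DOWN"),
            ([1.2, 1.2, 1.1, 1.2], "UP"),
            ([1.2, 1.2, 1.2, 0.9], "NS"),      # not increased in all four
            ([0.4, 0.4, 0.9, 0.9], "NS"),      # only two qualifying events
        ],
    )
    def test_rule_examples(self, ratios, expected):
        assert dm.classify_consistency(ratios) == expected

    def test_nt_undetected_neither_qualifies_nor_disqualifies(self):
        # donor D has the protein only in KD: no usable ratio
        call = dm.classify_consistency(
            [0.4, 0.4, 0.5, None],
            kd_detected=[True, True, True, True],
            nt_detected=[True, True, True, False],
        )
        assert call == "DOWN"
        call = dm.classify_consistency(
            [1.3, 1.3, 1.2, None],
            kd_detected=[True, True, True, True],
            nt_detected=[True, True, True, False],
        )
        assert call == "UP"

    def test_kd_lost_donor_disqualifies_up(self):
        call = dm.classify_consistency(
            [1.3, 1.3, 1.2, None],
            kd_detected=[True, True, True, False],
            nt_detected=[True, True, True, True],
        )
        assert call == "NS"

    def test_matches_rule_text_oracle_on_grid_sample(self):
        # exhaustive over a coarse sub-grid; the full grid runs in the
        # acceptance suite
        for combo in itertools.product([0.3, 0.9, 1.1, 1.3, UNDEF], repeat=4):
            donors = [(100.0 * r, 100.0) if r is not None else (0.0, 100.0)
                      for r in combo]
            assert dm.classify_consistency(combo) == classify_by_rule_text(donors), combo

    @given(st.lists(st.one_of(st.none(),
                              st.floats(0.01, 10.0, allow_nan=False)),
                    min_size=4, max_size=4))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_never_both_up_and_down_and_thresholds_monotone(self, ratios):
        call = dm.classify_consistency(ratios)
        assert call in ("DOWN", "UP", "NS")
        # stricter magnitude thresholds can only lose calls
        strict = dm.ClassifierThresholds(down_ratio=0.4, up_ratio=1.5)
        strict_call = dm.classify_consistency(ratios, strict)
        if strict_call == "DOWN":
            assert call == "DOWN"
        if strict_call == "UP":
            assert call == "UP"

    def test_classify_all_agrees_with_scalar_path(self, small_config, small_dataset):
        table, design, _ = small_dataset
        norm, _ = pre.preprocess(table)
        ratios = dm.donor_ratios(dm.aggregate_technical(norm, design))
        calls = dm.classify_all(ratios)
        for pid, grp in ratios.groupby("protein_group_id"):
            if calls.loc[pid, "call"] == "INELIGIBLE":
                continue
            scalar = dm.classify_consistency(
                grp["ratio"].tolist(),
                kd_detected=grp["detected_kd"].tolist(),
                nt_detected=grp["detected_nt"].tolist(),
            )
            assert calls.loc[pid, "call"] == scalar, pid


class TestPairedT:
    def test_closed_form_value(self):
        # log10 differences [1, 2, 3]: t = 2 / (1/sqrt(3))
        res = dm.paired_t_log10([10.0, 100.0, 1000.0], [1.0, 1.0, 1.0])
        assert res.t == pytest.approx(2 * math.sqrt(3), rel=1e-9)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_zero_variance_flagged(self):
        res = dm.paired_t_log10([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert res.zero_variance and math.isnan(res.p)
        res = dm.paired_t_log10([10.0, 20.0], [1.0, 2.0])  # diffs [1, 1]
        assert res.zero_variance

    def test_too_few_usable_pairs(self):
        res = dm.paired_t_log10([10.0, 0.0, 5.0], [1.0, 2.0, 0.0])
        assert res.n_pairs == 1 and math.isnan(res.p) and not res.zero_variance


class TestVolcano:
    def test_mean_log2_ratio(self):
        rows = [_ratio_row("P1", d, 50.0, 100.0) for d in "ABCD"]
        v = dm.volcano_table(pd.DataFrame(rows))
        assert v.loc[0, "mean_log2_ratio"] == pytest.approx(-1.0)

    def test_symmetry(self):
        rows = [_ratio_row("P1", "A", 200.0, 100.0), _ratio_row("P1", "B", 50.0, 100.0),
                _ratio_row("P1", "C", 100.0, 100.0), _ratio_row("P1", "D", 100.0, 100.0)]
        v = dm.volcano_table(pd.DataFrame(rows))
        assert v.loc[0, "mean_log2_ratio"] == pytest.approx(0.0)

    def test_planted_effect_recovered_at_low_noise(self):
        cfg = sd.SynthConfig(seed=21, n_proteins=2000, tech_sd=0.05, donor_sd=0.2,
                             detect_limit=-1e9, n_decoys=0,
                             n_keratin_contaminants=0, n_endogenous_keratins=0)
        table, design, truth = sd.generate_dataset(cfg)
        norm = pre.normalize_total(table)
        ratios = dm.donor_ratios(dm.aggregate_technical(norm, design))
        v = dm.volcano_table(ratios).set_index("protein_group_id")
        down = truth[truth == sd.DOWN_TRUE].index
        close = (v.loc[down, "mean_log2_ratio"] + 2.0).abs() < 0.1
        assert close.mean() >= 0.95


class TestScaleInvariance:
    def test_global_intensity_scaling_changes_nothing(self, small_config, small_dataset):
        table, design, _ = small_dataset
        blank = sd.generate_blank_run(small_config, table)
        scaled = table.copy()
        scaled.intensity *= 37.5
        if scaled.ibaq is not None:
            scaled.ibaq *= 37.5

        def run(t, b):
            norm, _ = pre.preprocess(t, b[b > 0])
            ratios = dm.donor_ratios(dm.aggregate_technical(norm, design))
            return dm.differential_calls(ratios)

        c1 = run(table, blank)
        c2 = run(scaled, blank * 37.5)
        assert (c1["call"] == c2["call"]).all()
        np.testing.assert_allclose(
            c1["mean_log2_ratio"], c2["mean_log2_ratio"], rtol=1e-9, equal_nan=True
        )
        np.testing.assert_allclose(c1["p"], c2["p"], rtol=1e-9, equal_nan=True)
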