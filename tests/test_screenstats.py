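"""Normalization, replicate aggregation, hit calling and dose-response."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spheroquant import synthdata
from spheroquant.exceptions import ContractError, NormalizationError
from spheroquant.screenstats import (
    aggregate_replicates,
    call_hits,
    dose_response_analysis,
    normalize_to_controls,
    toxicity_flag,
)


def make_table(rows):
    defaults = {
        "compound": "C1",
        "concentration_um": 10.0,
        "replicate": 1,
        "plate": "P1",
        "well": "A1",
        "migration_area_um2": 100.0,
        "dead_fraction": 0.05,
        "role": "compound",
        "excluded": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def plate_with_controls(plate, control_areas, compound_rows):
    rows = [
        {
            "plate": plate,
            "well": f"Z{i}",
            "compound": "DMSO",
            "concentration_um": 0.0,
            "migration_area_um2": a,
            "role": "control",
        }
        for i, a in enumerate(control_areas)
    ]
    return make_table(rows + [{**r, "plate": plate} for r in compound_rows])


class TestNormalization:
    def test_fold_is_area_over_control_mean(self):
        table = plate_with_controls(
            "P1", [100, 100, 100], [{"migration_area_um2": 170.0}]
        )
        norm = normalize_to_controls(table)
        assert norm.loc[norm.role == "compound", "fold"].item() == pytest.approx(1.7)

    def test_control_mean_fold_exactly_one_per_plate(self, rng):
        table = plate_with_controls("P1", rng.uniform(50, 150, 8), [])
        norm = normalize_to_controls(table)
        assert norm["fold"].mean() == pytest.approx(1.0)

    def test_platewise_normalization(self):
        t1 = plate_with_controls("P1", [100, 100], [{"migration_area_um2": 150.0}])
        t2 = plate_with_controls("P2", [200, 200], [{"migration_area_um2": 150.0}])
        norm = normalize_to_controls(pd.concat([t1, t2], ignore_index=True))
        folds = norm.loc[norm.role == "compound", "fold"].to_numpy()
        assert folds[0] == pytest.approx(1.5)
        assert folds[1] == pytest.approx(0.75)

    def test_plate_without_controls_is_error(self):
        table = make_table([{"migration_area_um2": 100.0}])
        with pytest.raises(NormalizationError):
            normalize_to_controls(table)

    def test_excluded_controls_do_not_count(self):
        table = plate_with_controls("P1", [100, 100, 100], [])
        table["excluded"] = True
        with pytest.raises(NormalizationError):
            normalize_to_controls(table)


class TestAggregateReplicates:
    def test_mean(self):
        mean, sd, n = aggregate_replicates([1.0, 1.2, 1.4])
        assert mean == pytest.approx(1.2)
        assert n == 3

    def test_single_value_sd_zero(self):
        assert aggregate_replicates([2.0]) == (2.0, 0.0, 1)

    def test_matches_textbook_formulas(self, rng):
        x = rng.normal(1, 0.3, size=17)
        mean, sd, n = aggregate_replicates(x)
        assert mean == pytest.approx(x.sum() / 17)
        assert sd == pytest.approx(
            np.sqrt(((x - x.mean()) ** 2).sum() / 16)
        )

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            aggregate_replicates([])


class TestToxicityFlag:
    @pytest.mark.parametrize("dead,thr,expected", [(0.9, 0.5, True), (0.0, 0.5, False)])
    def test_flag(self, dead, thr, expected):
        assert toxicity_flag(dead, thr) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            toxicity_flag(1.2, 0.5)

    def test_flag_count_monotone_in_threshold(self, rng):
        dead = rng.uniform(0, 1, 200)
        counts = [
            sum(toxicity_flag(d, t) for d in dead) for t in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)


def screen_with(folds_by_compound, control_sd=0.1, dead_by_compound=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for plate in ("P1", "P2", "P3"):
        for i in range(8):
            rows.append(
                {
                    "plate": plate,
                    "well": f"Z{i}",
                    "compound": "DMSO",
                    "concentration_um": 0.0,
                    "migration_area_um2": 100 * rng.normal(1, control_sd),
                    "role": "control",
                }
            )
    for compound, fold in folds_by_compound.items():
        dead = (dead_by_compound or {}).get(compound, 0.05)
        for rep, plate in enumerate(("P1", "P2", "P3"), start=1):
            rows.append(
                {
                    "plate": plate,
                    "well": compound,
                    "compound": compound,
                    "replicate": rep,
                    "migration_area_um2": 100 * fold * rng.normal(1, control_sd),
                    "dead_fraction": dead,
                }
            )
    return make_table(rows)


class TestCallHits:
    def test_cutoffs_and_classes(self):
        table = screen_with(
            {"HI": 1.7, "NONE": 1.0, "LOW": 0.30, "TOX": 0.30},
            control_sd=0.05,
            dead_by_compound={"TOX": 0.9, "LOW": 0.05},
            seed=3,
        )
        calls = call_hits(normalize_to_controls(table), k_sd=4.0)
        by = calls.set_index("compound")["call"]
        assert by["HI"] == "high"
        assert by["NONE"] == "none"
        assert by["LOW"] == "low"
        assert by["TOX"] == "toxic"

    def test_class_respects_cutoff_invariant(self):
        table = screen_with({f"C{i}": f for i, f in enumerate([0.2, 0.9, 1.1, 2.5])})
        calls = call_hits(normalize_to_controls(table))
        for _, row in calls.iterrows():
            if row["call"] == "high":
                assert row["fold"] >= row["high_cutoff"]
            if row["call"] == "low":
                assert row["fold"] <= row["low_cutoff"]

    def test_all_replicates_excluded_is_excluded_class(self):
        table = screen_with({"GONE": 1.0})
        table.loc[table.compound == "GONE", "excluded"] = True
        calls = call_hits(normalize_to_controls(table))
        assert calls.set_index("compound").loc["GONE", "call"] == "excluded"

    def test_invalid_k_sd(self):
        table = screen_with({"C1": 1.0})
        with pytest.raises(ContractError):
            call_hits(normalize_to_controls(table), k_sd=0.0)

    def test_invariant_to_plate_relabeling_and_row_order(self):
        table = screen_with({"A": 2.2, "B": 0.4, "C": 1.0}, seed=9)
        norm = normalize_to_controls(table)
        base = call_hits(norm).set_index("compound")["call"]
        renamed = table.copy()
        renamed["plate"] = renamed["plate"].map({"P1": "X", "P2": "Y", "P3": "Z"})
        shuffled = renamed.sample(frac=1, random_state=1).reset_index(drop=True)
        again = call_hits(normalize_to_controls(shuffled)).set_index("compound")["call"]
        assert base.to_dict() == again.to_dict()

    def test_excluding_compound_well_does_not_move_other_calls(self):
        table = screen_with({"A": 2.2, "B": 1.0}, seed=5)
        base = call_hits(normalize_to_controls(table)).set_index("compound")["call"]
        table2 = table.copy()
        idx = table2[(table2.compound == "B") & (table2.replicate == 1)].index
        table2.loc[idx, "excluded"] = True
        after = call_hits(normalize_to_controls(table2)).set_index("compound")["call"]
        assert after["A"] == base["A"]


class TestPlantedScreenRecovery:
    def test_planted_labels_recovered_across_seeds(self):
        for seed in (1, 2, 3):
            spec = synthdata.validation_screen_spec(seed)
            table, truth = synthdata.generate_screen_table(spec)
            calls = call_hits(normalize_to_controls(table), k_sd=4.0)
            merged = calls.merge(truth, on="compound")
            assert (
                (merged.label == "high") == (merged.call == "high")
            ).all(), f"seed {seed}: high calls diverge from planted truth"
            assert (
                (merged.label == "low") == (merged.call == "low")
            ).all(), f"seed {seed}: low calls diverge from planted truth"

    def test_null_screen_false_positives_pooled(self):
        hits = 0
        for seed in range(10):
            spec = synthdata.ScreenSpec(seed=seed)
            table, _ = synthdata.generate_screen_table(spec)
            calls = call_hits(normalize_to_controls(table), k_sd=4.0)
            hits += (calls["call"] != "none").sum()
        assert hits <= 1

    def test_planted_counts_exact(self):
        spec = synthdata.validation_screen_spec(0)
        _, truth = synthdata.generate_screen_table(spec)
        assert (truth.label == "high").sum() == 24
        assert (truth.label == "low").sum() == 36


class TestDoseResponse:
    def dose_table(self, fold_by_conc, control_sd=0.05, n_rep=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for conc, fold in fold_by_conc.items():
            plate = f"P{conc}"
            for i in range(6):
                rows.append(
                    {
                        "plate": plate,
                        "well": f"Z{i}",
                        "compound": "DMSO",
                        "concentration_um": 0.0,
                        "migration_area_um2": 100 * rng.normal(1, control_sd),
                        "role": "control",
                    }
                )
            for rep in range(n_rep):
                rows.append(
                    {
                        "plate": plate,
                        "well": f"C{rep}",
                        "compound": "CMP",
                        "concentration_um": conc,
                        "replicate": rep + 1,
                        "migration_area_um2": 100 * fold * rng.normal(1, control_sd),
                    }
                )
        return make_table(rows)

    def test_flat_compound_nothing_significant(self):
        table = self.dose_table({0.1: 1.0, 1.0: 1.0, 10.0: 1.0}, seed=2)
        (res,) = dose_response_analysis(normalize_to_controls(table))
        assert not res.per_concentration["significant"].any()

    def test_effect_only_at_top_concentration(self):
        table = self.dose_table({0.1: 1.0, 1.0: 1.0, 10.0: 2.5}, seed=3)
        (res,) = dose_response_analysis(normalize_to_controls(table))
        per = res.per_concentration.set_index("concentration_um")
        assert bool(per.loc[10.0, "significant"])
        assert not per.loc[[0.1, 1.0], "significant"].any()
        assert res.peak_concentration == 10.0

    def test_monotone_effect_matches_welch_oracle(self):
        table = self.dose_table({0.1: 1.5, 1.0: 2.0, 10.0: 2.8}, seed=4)
        norm = normalize_to_controls(table)
        (res,) = dose_response_analysis(norm)
        assert res.per_concentration["significant"].all()
        assert res.peak_concentration == 10.0
        # closed-form Welch oracle at one concentration
        sub = norm[(norm.role == "compound") & (norm.concentration_um == 1.0)]
        ctrl = norm[(norm.role == "control") & (norm.plate == "P1.0")]
        x, y = sub["fold"].to_numpy(), ctrl["fold"].to_numpy()
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        got = res.per_concentration.set_index("concentration_um").loc[1.0, "p_value"]
        assert got == pytest.approx(p, rel=1e-9)

    def test_single_concentration_rejected(self):
        table = self.dose_table({10.0: 2.0})
        with pytest.raises(ContractError):
            dose_response_analysis(normalize_to_controls(table))

    def test_peak_tie_resolves_to_highest_concentration(self):
        table = self.dose_table({1.0: 2.0, 10.0: 2.0}, control_sd=0.0)
        (res,) = dose_response_analysis(normalize_to_controls(table))
        assert res.peak_concentration == 10.0
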