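import math

import numpy as np
import pandas as pd
import pytest

from conftest import build_table
from oracles import brute_exclude, brute_fold_changes
from secretomics.differential import (
    ConfigurationError,
    DiffConfig,
    FoldChangeClassifier,
    classify_fold_change,
    compute_fold_changes,
    exclude_nonspecific,
    rank_and_select,
)

FULL = {"pos", "conc"}


def control_only_table(control_values):
    """One control array plus the two metrs arrays the stage demands."""
    probes = list(control_values)
    values = {
        "M_base": {p: 1.0 for p in probes},
        "M_stim": {p: 1.0 for p in probes},
        "C1": dict(control_values),
    }
    meta = [
        ("M_base", "metrs", "baseline", 1, 1.0),
        ("M_stim", "metrs", "stimulated", 1, 1.0),
        ("C1", "control", "baseline", 1, 1.0),
    ]
    return build_table(values, meta, applied=FULL)


def random_diff_table(rng, n_probes, n_control=1, missing_rate=0.1):
    probes = [f"TGT{j:03d}" for j in range(n_probes)]
    arrays = [("M_base", "metrs", "baseline"), ("M_stim", "metrs", "stimulated")] + [
        (f"C{i}", "control", "baseline") for i in range(n_control)
    ]
    values = {
        a: {p: float(rng.uniform(0, 1e4)) for p in probes} for a, _, _ in arrays
    }
    missing = []
    for a, _, _ in arrays:
        for p in probes:
            if rng.random() < missing_rate:
                missing.append((p, a))
    meta = [(a, g, c, 1, 1.0) for a, g, c in arrays]
    return build_table(values, meta, applied=FULL, missing=missing)


def as_nested_dict(table):
    return {
        a: {
            p: (None if np.isnan(v) else float(v))
            for p, v in table.values[a].items()
        }
        for a in table.arrays
    }


class TestExclusion:
    def test_forced_example(self):
        table = control_only_table(
            {"A": 10.0, "B": 9.0, "C": 1.0, "D": 2.0, "E": 3.0, "F": 4.0}
        )
        result = exclude_nonspecific(table)
        excluded = {p for p, (e, _) in result.items() if e}
        assert excluded == {"A", "B"}
        assert result["A"][1] == ("C1",)

    def test_ties_at_cutoff_are_inclusive(self):
        table = control_only_table(
            {"A": 10.0, "B": 10.0, "C": 10.0, "D": 1.0, "E": 2.0, "F": 3.0}
        )
        result = exclude_nonspecific(table)
        excluded = {p for p, (e, _) in result.items() if e}
        assert excluded == {"A", "B", "C"}

    def test_no_control_array_is_configuration_error(self):
        table = build_table(
            {"M_base": {"A": 1.0}, "M_stim": {"A": 2.0}},
            [
                ("M_base", "metrs", "baseline", 1, 1.0),
                ("M_stim", "metrs", "stimulated", 1, 1.0),
            ],
            applied=FULL,
        )
        with pytest.raises(ConfigurationError, match="control"):
            exclude_nonspecific(table)

    @pytest.mark.parametrize("mode", ["per_control_array_rank", "pooled_tertile"])
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        n_probes = int(rng.integers(10, 61))
        n_control = int(rng.integers(1, 3))
        table = random_diff_table(rng, n_probes, n_control)
        cfg = DiffConfig(exclusion_mode=mode)
        result = exclude_nonspecific(table, cfg=cfg)
        got = {p for p, (e, _) in result.items() if e}
        controls = [m.array_id for m in table.meta if m.genotype == "control"]
        expected = brute_exclude(as_nested_dict(table), controls, 1 / 3, mode)
        assert got == expected


class TestFoldChanges:
    def test_simple_ratio(self):
        table = build_table(
            {"M_base": {"A": 100.0}, "M_stim": {"A": 300.0}, "C1": {"A": 1.0}},
            [
                ("M_base", "metrs", "baseline", 1, 1.0),
                ("M_stim", "metrs", "stimulated", 1, 1.0),
                ("C1", "control", "baseline", 1, 1.0),
            ],
            applied=FULL,
        )
        fc = compute_fold_changes(table)
        assert fc.loc["A", "fold_change"] == 3.0

    def test_zero_baseline_is_incalculable(self):
        table = build_table(
            {"M_base": {"A": 0.0}, "M_stim": {"A": 300.0}},
            [
                ("M_base", "metrs", "baseline", 1, 1.0),
                ("M_stim", "metrs", "stimulated", 1, 1.0),
            ],
            applied=FULL,
        )
        fc = compute_fold_changes(table)
        assert np.isnan(fc.loc["A", "fold_change"])

    def test_missing_condition_is_configuration_error(self):
        table = build_table(
            {"M_base": {"A": 1.0}, "C1": {"A": 1.0}},
            [
                ("M_base", "metrs", "baseline", 1, 1.0),
                ("C1", "control", "baseline", 1, 1.0),
            ],
            applied=FULL,
        )
        with pytest.raises(ConfigurationError, match="stimulated"):
            compute_fold_changes(table)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_with_replicates(self, seed):
        rng = np.random.default_rng(500 + seed)
        probes = [f"TGT{j:02d}" for j in range(15)]
        arrays = [
            ("B1", "metrs", "baseline"),
            ("B2", "metrs", "baseline"),
            ("S1", "metrs", "stimulated"),
            ("S2", "metrs", "stimulated"),
        ]
        values = {
            a: {p: float(rng.uniform(0, 100)) for p in probes} for a, _, _ in arrays
        }
        missing = [
            (p, a)
            for a, _, _ in arrays
            for p in probes
            if rng.random() < 0.15
        ]
        table = build_table(
            values,
            [(a, g, c, 1, 1.0) for a, g, c in arrays],
            applied=FULL,
            missing=missing,
        )
        fc = compute_fold_changes(table)
        oracle = brute_fold_changes(as_nested_dict(table), ["B1", "B2"], ["S1", "S2"])
        for p, (base, stim, ratio) in oracle.items():
            if ratio is None:
                assert np.isnan(fc.loc[p, "fold_change"])
            else:
                assert fc.loc[p, "fold_change"] == pytest.approx(ratio, rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "fc,excluded,expected",
        [
            (2.0, False, "up"),
            (0.5, False, "down"),
            (1.5, False, "ns"),
            (0.65, False, "ns"),
            (1.0, False, "ns"),
            (1.5000001, False, "up"),
            (0.6499999, False, "down"),
            (2.0, True, "excluded"),
            (float("nan"), False, "excluded"),
            (None, False, "excluded"),
        ],
    )
    def test_threshold_semantics(self, fc, excluded, expected):
        assert classify_fold_change(fc, excluded) == expected


def calls_frame(fc_by_probe, call_by_probe):
    return pd.DataFrame(
        {
            "signal_baseline": 1.0,
            "signal_stimulated": [fc_by_probe[p] for p in fc_by_probe],
            "fold_change": [fc_by_probe[p] for p in fc_by_probe],
            "call": [call_by_probe[p] for p in fc_by_probe],
        },
        index=pd.Index(list(fc_by_probe), name="probe_id"),
    )


class TestRanking:
    def test_up_report_truncated_to_top_k(self):
        fcs = {f"P{i:02d}": 1.6 + i * 0.1 for i in range(12)}
        calls = calls_frame(fcs, {p: "up" for p in fcs})
        up, down = rank_and_select(calls)
        assert len(up) == 10
        assert up.index[0] == "P11"  # largest fold change first
        assert list(up["rank"]) == list(range(1, 11))
        assert len(down) == 0

    def test_down_report_never_truncated(self):
        fcs = {f"P{i}": 0.1 + i * 0.05 for i in range(3)}
        calls = calls_frame(fcs, {p: "down" for p in fcs})
        up, down = rank_and_select(calls)
        assert len(down) == 3
        assert down.index[0] == "P0"  # strongest downregulation first

    def test_boundary_tie_breaks_lexicographically(self):
        fcs = {f"P{i:02d}": 5.0 - i * 0.1 for i in range(9)}
        fcs["AAA"] = 2.0
        fcs["ZZZ"] = 2.0
        calls = calls_frame(fcs, {p: "up" for p in fcs})
        up, _ = rank_and_select(calls)
        assert len(up) == 10
        assert "AAA" in up.index and "ZZZ" not in up.index


class TestEndToEndProperties:
    def _study_table(self, rng, up=("TGT000",), down=("TGT001",)):
        table = random_diff_table(rng, 30, n_control=1, missing_rate=0.0)
        values = table.values.copy()
        for p in up:
            values.loc[p, "M_stim"] = values.loc[p, "M_base"] * 4
        for p in down:
            values.loc[p, "M_stim"] = values.loc[p, "M_base"] * 0.2
        return build_table(
            {a: values[a].to_dict() for a in values.columns},
            [(m.array_id, m.genotype, m.condition, m.replicate, m.protein_conc)
             for m in table.meta],
            applied=FULL,
        )

    def test_probe_permutation_invariance(self):
        rng = np.random.default_rng(42)
        table = self._study_table(rng)
        clf = FoldChangeClassifier().fit(table)
        perm = table.values.sample(frac=1, random_state=0)
        shuffled = build_table(
            {a: perm[a].to_dict() for a in perm.columns},
            [(m.array_id, m.genotype, m.condition, m.replicate, m.protein_conc)
             for m in table.meta],
            applied=FULL,
        )
        clf2 = FoldChangeClassifier().fit(shuffled)
        assert clf.results_["call"].sort_index().equals(
            clf2.results_["call"].sort_index()
        )

    def test_raising_stimulated_signal_never_moves_call_downward(self):
        order = {"down": 0, "ns": 1, "up": 2}
        rng = np.random.default_rng(43)
        table = self._study_table(rng)
        clf = FoldChangeClassifier().fit(table)
        bumped_values = table.values.copy()
        bumped_values["M_stim"] *= 2.0
        bumped = build_table(
            {a: bumped_values[a].to_dict() for a in bumped_values.columns},
            [(m.array_id, m.genotype, m.condition, m.replicate, m.protein_conc)
             for m in table.meta],
            applied=FULL,
        )
        clf2 = FoldChangeClassifier().fit(bumped)
        for p in table.probes:
            before, after = clf.results_.loc[p, "call"], clf2.results_.loc[p, "call"]
            if before in order and after in order:
                assert order[after] >= order[before]

    def test_global_scaling_changes_nothing(self):
        rng = np.random.default_rng(44)
        table = self._study_table(rng)
        clf = FoldChangeClassifier().fit(table)
        scaled = build_table(
            {a: (table.values[a] * 17.0).to_dict() for a in table.arrays},
            [(m.array_id, m.genotype, m.condition, m.replicate, m.protein_conc)
             for m in table.meta],
            applied=FULL,
        )
        clf2 = FoldChangeClassifier().fit(scaled)
        assert clf.results_["call"].equals(clf2.results_["call"])
        assert list(clf.up_report_.index) == list(clf2.up_report_.index)
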