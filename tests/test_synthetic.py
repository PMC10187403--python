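import math

import numpy as np
import pytest

from secretomics.differential import FoldChangeClassifier
from secretomics.normalize import normalize_table
from secretomics.preprocess import collapse_duplicates
from secretomics.synthetic import (
    SimConfig,
    simulate_dataset,
    simulate_fasta,
    study_config,
    target_ids,
    write_arrays,
)


def noise_free_config(**overrides):
    base = dict(
        n_targets=15,
        baseline_log_sd=1.0,
        spot_cv=0.0,
        bg_mean=0.0,
        bg_sd=0.0,
        array_scale_sd=0.0,
        conc_range=(1.0, 1.0),
        planted_up={"TGT0001": 3.0, "TGT0002": 1.8},
        planted_down={"TGT0003": 0.3},
        n_nonspecific=5,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


def run_analysis(dataset):
    table = collapse_duplicates(dataset.spots, dataset.design)
    table, _ = normalize_table(table)
    return FoldChangeClassifier().fit(table)


class TestSimulate:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimConfig(
            n_targets=40,
            planted_up={"TGT0001": 3.0},
            planted_down={"TGT0002": 0.3},
            n_nonspecific=5,
            seed=3,
        )
        d1 = tmp_path / "run1"
        d2 = tmp_path / "run2"
        write_arrays(simulate_dataset(cfg), d1)
        write_arrays(simulate_dataset(cfg), d2)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimConfig(n_targets=20, seed=1))
        b = simulate_dataset(SimConfig(n_targets=20, seed=2))
        assert not np.allclose(
            a.truth.probes["baseline_abundance"], b.truth.probes["baseline_abundance"]
        )

    def test_unknown_planted_probe_rejected(self):
        with pytest.raises(ValueError, match="not in the target set"):
            simulate_dataset(SimConfig(n_targets=5, planted_up={"TGT9999": 2.0}))

    def test_spot_counts_match_layout(self):
        cfg = SimConfig(n_targets=20, duplicates=3, n_pos=6, n_neg=4, seed=0)
        ds = simulate_dataset(cfg)
        per_array = 20 * 3 + 6 + 4
        assert len(ds.spots) == per_array * 4
        assert len(ds.design) == 4

    def test_noise_free_fold_changes_equal_planted(self):
        ds = simulate_dataset(noise_free_config())
        clf = run_analysis(ds)
        truth = ds.truth.probes
        for p in truth.index:
            got = clf.results_.loc[p, "fold_change"]
            assert got == pytest.approx(truth.loc[p, "fold_change"], rel=1e-9)

    def test_noise_free_exclusions_are_exactly_the_planted_nonspecific(self):
        # with 15 targets the top tertile of a control array is 5 probes,
        # so 5 planted binders fill it exactly
        ds = simulate_dataset(noise_free_config())
        clf = run_analysis(ds)
        ns = set(ds.truth.probes.index[ds.truth.probes["nonspecific"]])
        assert len(ns) == 5
        excluded = set(
            clf.results_.index[
                clf.results_["exclusion_reason"] == "nonspecific_top_tertile"
            ]
        )
        assert excluded == ns

    def test_nonspecific_levels_exceed_every_residual(self):
        ds = simulate_dataset(study_config(seed=5))
        control_arrays = ds.truth.arrays.index[
            ds.truth.arrays["genotype"] == "control"
        ]
        table = collapse_duplicates(ds.spots, ds.design)
        ns = ds.truth.probes["nonspecific"]
        for a in control_arrays:
            col = table.values[a]
            assert col[ns].min() > col[~ns].median()


class TestWriteArrays:
    def test_gpr_file_count(self, tmp_path):
        ds = simulate_dataset(SimConfig(n_targets=10, seed=1))
        paths = write_arrays(ds, tmp_path, dialect="gpr")
        assert len(paths) == 6  # 4 arrays + design + truth
        assert sorted(p.suffix for p in paths) == [
            ".csv",
            ".gpr",
            ".gpr",
            ".gpr",
            ".gpr",
            ".tsv",
        ]

    def test_round_trip_through_gpr_reader(self, tmp_path):
        from secretomics.io import read_gpr

        ds = simulate_dataset(SimConfig(n_targets=8, seed=2))
        paths = write_arrays(ds, tmp_path, dialect="gpr")
        reread = []
        for p in paths:
            if p.suffix == ".gpr":
                reread.extend(read_gpr(p, array_id=p.stem))
        by_key = {(s.array_id, s.block, s.row, s.col): s for s in ds.spots}
        assert len(reread) == len(ds.spots)
        for s in reread:
            assert s == by_key[(s.array_id, s.block, s.row, s.col)]

    def test_long_table_dialect_round_trips(self, tmp_path):
        from secretomics.io import read_long_table

        ds = simulate_dataset(SimConfig(n_targets=8, seed=2))
        paths = write_arrays(ds, tmp_path, dialect="long_table")
        (arrays_path,) = [p for p in paths if p.name == "arrays.csv"]
        assert read_long_table(arrays_path) == ds.spots


class TestSimulateFasta:
    def test_zero_met_rate_means_untaggable(self):
        for pid, seq in simulate_fasta(30, (10, 20), met_rate=0.0, seed=1):
            assert seq[0] == "M" and "M" not in seq[1:]

    def test_met_rate_one_is_all_met(self):
        for pid, seq in simulate_fasta(10, (5, 9), met_rate=1.0, seed=1):
            assert seq == "M" * len(seq)

    def test_taggable_fraction_matches_closed_form(self):
        n, length, rate = 2000, 400, 0.02
        records = simulate_fasta(n, (length, length), met_rate=rate, seed=12)
        observed = np.mean([("M" in seq[1:]) for _, seq in records])
        expected = 1.0 - (1.0 - rate) ** (length - 1)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_fasta(0, (10, 20), 0.1, 1)
        with pytest.raises(ValueError):
            simulate_fasta(5, (10, 20), 1.5, 1)


def test_target_ids_are_targets_not_controls():
    from secretomics.io import infer_role

    assert all(infer_role(p) == "target" for p in target_ids(600))
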