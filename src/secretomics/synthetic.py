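"""Synthetic antibody-array datasets with known ground truth.

Emulates the study design the analysis assumes: an L507-style array
(~507 duplicate-spotted target antibodies plus positive/negative control
spots) hybridized across a 2x2 design — genotype {metrs, control} x
condition {baseline, stimulated} — with planted fold changes, planted
non-specific binders, multiplicative log-normal spot noise, per-array scale
drift, and per-sample loading (concentration) differences.

Generative model, per probe i with baseline abundance A_i ~ LogNormal:

* MetRS arrays carry A_i (baseline) or A_i x fc_i (stimulated).
* Control-genotype arrays carry a low residual level L_i (material from
  non-expressing cells is not biotinylated), except the planted
  non-specific binders, whose control level is placed strictly above the
  largest residual draw — guaranteeing top-tertile membership when spot
  noise is off.
* Each spot's foreground is true signal x loading concentration (targets
  only) x array scale x LogNormal(0, spot_cv) plus a background draw; the
  recorded background median is an independent background draw.
* Positive-control spots emit a fixed bright level x array scale (printed
  controls do not depend on the loaded sample), negative controls emit
  background only.

All randomness flows from one seed; per-array sub-streams keep individual
arrays reproducible when the design is edited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import SampleMeta, SpotRecord, write_design, write_gpr, write_long_table

DEFAULT_DESIGN = (
    ("metrs", "baseline", 1),
    ("metrs", "stimulated", 1),
    ("control", "baseline", 1),
    ("control", "stimulated", 1),
)

_GRID_COLS = 25  # spots per grid row in generated layouts


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the profiled co-culture experiment: 507 duplicate-
    spotted targets, 6 positive / 4 negative controls, one array per cell of
    the 2x2 genotype x condition design, log-normal abundances, 10% spot
    noise, 30% per-array scale drift, and loading concentrations spanning
    2-fold.
    """

    n_targets: int = 507
    duplicates: int = 2
    n_pos: int = 6
    n_neg: int = 4
    design: tuple[tuple[str, str, int], ...] = DEFAULT_DESIGN
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    spot_cv: float = 0.1
    bg_mean: float = 100.0
    bg_sd: float = 20.0
    array_scale_sd: float = 0.3
    conc_range: tuple[float, float] = (1.0, 2.0)
    planted_up: Mapping[str, float] = field(default_factory=dict)
    planted_down: Mapping[str, float] = field(default_factory=dict)
    n_nonspecific: int = 0
    nonspecific_ids: tuple[str, ...] | None = None
    control_log_offset: float = -3.0
    pos_level: float = 50000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.duplicates < 1:
            raise ValueError("n_targets and duplicates must be >= 1")
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(f"planted up/down sets overlap: {sorted(overlap)}")
        if any(fc <= 1 for fc in self.planted_up.values()):
            raise ValueError("planted_up fold changes must be > 1")
        if any(not 0 < fc < 1 for fc in self.planted_down.values()):
            raise ValueError("planted_down fold changes must be in (0, 1)")
        for name in ("baseline_log_sd", "spot_cv", "bg_sd", "array_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.conc_range[0] <= self.conc_range[1]:
            raise ValueError("conc_range must satisfy 0 < min <= max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("design",):
            if key in raw:
                raw[key] = tuple(tuple(cell) for cell in raw[key])
        for key in ("conc_range", "nonspecific_ids"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        for key in ("planted_up", "planted_down"):
            if key in raw and raw[key] is not None:
                raw[key] = dict(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters: per-probe truth and per-array truth."""

    probes: pd.DataFrame  # probe_id (index), baseline_abundance, fold_change, nonspecific
    arrays: pd.DataFrame  # array_id (index), genotype, condition, replicate, scale, protein_conc


@dataclass(frozen=True)
class SimulatedDataset:
    spots: list[SpotRecord]
    design: list[SampleMeta]
    truth: GroundTruth


def target_ids(n: int) -> list[str]:
    return [f"TGT{i:04d}" for i in range(1, n + 1)]


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """The full study condition: 507 targets, 15 up (FC 3), 10 down (FC 0.3),
    30 non-specific binders, default noise levels."""
    ids = target_ids(overrides.get("n_targets", 507))
    cfg = SimConfig(
        planted_up={p: 3.0 for p in ids[:15]},
        planted_down={p: 0.3 for p in ids[15:25]},
        n_nonspecific=30,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size=None):
    return np.maximum(rng.normal(mean, sd, size=size), 0.0)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Draw one synthetic dataset (spots, design, ground truth) from ``cfg``."""
    probes = target_ids(cfg.n_targets)
    probe_set = set(probes)
    for p in list(cfg.planted_up) + list(cfg.planted_down) + list(
        cfg.nonspecific_ids or ()
    ):
        if p not in probe_set:
            raise ValueError(f"planted probe {p!r} is not in the target set")

    ss = np.random.SeedSequence(cfg.seed)
    n_arrays = sum(n for _, _, n in cfg.design)
    truth_ss, *array_ss = ss.spawn(1 + n_arrays)
    rng = np.random.default_rng(truth_ss)

    abundance = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_targets)
    residual = rng.lognormal(
        cfg.baseline_log_mean + cfg.control_log_offset, cfg.baseline_log_sd, cfg.n_targets
    )
    fold = np.ones(cfg.n_targets)
    for i, p in enumerate(probes):
        if p in cfg.planted_up:
            fold[i] = cfg.planted_up[p]
        elif p in cfg.planted_down:
            fold[i] = cfg.planted_down[p]

    if cfg.nonspecific_ids is not None:
        ns_ids = list(cfg.nonspecific_ids)
    else:
        eligible = [p for p in probes if p not in cfg.planted_up and p not in cfg.planted_down]
        if cfg.n_nonspecific > len(eligible):
            raise ValueError("n_nonspecific exceeds the number of unplanted targets")
        ns_ids = sorted(rng.choice(eligible, size=cfg.n_nonspecific, replace=False))
    ns_mask = np.isin(probes, ns_ids)
    # Control-array level: low residual, except non-specific binders pinned
    # strictly above the largest residual so they occupy the top ranks.
    control_level = residual.copy()
    if ns_mask.any():
        ceiling = residual.max()
        control_level[ns_mask] = ceiling * (1.5 + rng.uniform(0.0, 1.0, ns_mask.sum()))

    truth_probes = pd.DataFrame(
        {
            "baseline_abundance": abundance,
            "fold_change": fold,
            "nonspecific": ns_mask,
        },
        index=pd.Index(probes, name="probe_id"),
    )

    spots: list[SpotRecord] = []
    design: list[SampleMeta] = []
    array_rows = []
    idx = 0
    for genotype, condition, n_rep in cfg.design:
        for rep in range(1, n_rep + 1):
            arr_rng = np.random.default_rng(array_ss[idx])
            array_id = f"A{idx + 1:02d}_{genotype}_{condition}_r{rep}"
            scale = float(arr_rng.lognormal(0.0, cfg.array_scale_sd))
            lo, hi = cfg.conc_range
            conc = float(lo if lo == hi else arr_rng.uniform(lo, hi))

            if genotype == "metrs":
                true = abundance * (fold if condition == "stimulated" else 1.0)
            else:
                true = control_level

            records = []
            for i, p in enumerate(probes):
                for _ in range(cfg.duplicates):
                    records.append((p, "target", true[i] * conc))
            for j in range(cfg.n_pos):
                records.append((f"POS{j + 1}", "pos_control", cfg.pos_level))
            for j in range(cfg.n_neg):
                records.append((f"NEG{j + 1}", "neg_control", 0.0))

            n_spots = len(records)
            noise = (
                arr_rng.lognormal(0.0, cfg.spot_cv, n_spots)
                if cfg.spot_cv > 0
                else np.ones(n_spots)
            )
            bg_fg = _truncated_normal(arr_rng, cfg.bg_mean, cfg.bg_sd, n_spots)
            bg_col = _truncated_normal(arr_rng, cfg.bg_mean, cfg.bg_sd, n_spots)
            for k, (pid, role, level) in enumerate(records):
                spots.append(
                    SpotRecord(
                        array_id=array_id,
                        block=1,
                        row=k // _GRID_COLS + 1,
                        col=k % _GRID_COLS + 1,
                        probe_id=pid,
                        probe_role=role,
                        fg_median=float(level * scale * noise[k] + bg_fg[k]),
                        bg_median=float(bg_col[k]),
                        flag=0,
                    )
                )
            design.append(
                SampleMeta(
                    array_id=array_id,
                    sample_id=f"S{idx + 1:02d}",
                    genotype=genotype,
                    condition=condition,
                    replicate=rep,
                    protein_conc=conc,
                )
            )
            array_rows.append(
                {
                    "array_id": array_id,
                    "genotype": genotype,
                    "condition": condition,
                    "replicate": rep,
                    "scale": scale,
                    "protein_conc": conc,
                }
            )
            idx += 1

    truth_arrays = pd.DataFrame(array_rows).set_index("array_id")
    return SimulatedDataset(spots, design, GroundTruth(truth_probes, truth_arrays))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize both truth tables into one TSV with a record_type column."""
    probes = truth.probes.reset_index()
    probes.insert(0, "record_type", "probe")
    arrays = truth.arrays.reset_index()
    arrays.insert(0, "record_type", "array")
    pd.concat([probes, arrays], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    probes = (
        df[df["record_type"] == "probe"]
        .set_index("probe_id")[["baseline_abundance", "fold_change", "nonspecific"]]
        .astype({"nonspecific": bool})
    )
    arrays = df[df["record_type"] == "array"].set_index("array_id")[
        ["genotype", "condition", "replicate", "scale", "protein_conc"]
    ]
    return GroundTruth(probes, arrays)


def write_arrays(
    dataset: SimulatedDataset,
    out_dir: str | Path,
    dialect: str = "gpr",
) -> list[Path]:
    """Write a simulated dataset to disk in a form array readers accept.

    ``gpr``: one ``<array_id>.gpr`` file per array.  ``long_table``: one
    ``arrays.csv`` holding every array.  Either way ``design.csv`` and
    ``ground_truth.tsv`` are written alongside.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    if dialect == "gpr":
        by_array: dict[str, list[SpotRecord]] = {}
        for s in dataset.spots:
            by_array.setdefault(s.array_id, []).append(s)
        for array_id in sorted(by_array):
            p = out_dir / f"{array_id}.gpr"
            write_gpr(by_array[array_id], p)
            paths.append(p)
    elif dialect == "long_table":
        p = out_dir / "arrays.csv"
        write_long_table(dataset.spots, p)
        paths.append(p)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    design_path = out_dir / "design.csv"
    write_design(dataset.design, design_path)
    truth_path = out_dir / "ground_truth.tsv"
    write_ground_truth(dataset.truth, truth_path)
    return paths + [design_path, truth_path]


def evaluate_recovery(truth: GroundTruth, calls: pd.DataFrame) -> dict[str, float]:
    """Score a calls table against the planted ground truth.

    Sensitivities are computed among the planted probes that survived
    exclusion (an excluded probe yields no call at all); the false-call rate
    is the fraction of non-excluded null probes (planted fold change 1,
    not non-specific) called up or down.
    """
    t = truth.probes
    up_ids = t.index[t["fold_change"] > 1]
    down_ids = t.index[t["fold_change"] < 1]
    null_ids = t.index[(t["fold_change"] == 1) & ~t["nonspecific"]]
    ns_ids = t.index[t["nonspecific"]]

    call = calls["call"]
    not_excluded = call != "excluded"

    def _sensitivity(ids, expected):
        eligible = [p for p in ids if not_excluded.get(p, False)]
        if not eligible:
            return float("nan"), 0
        hits = sum(call[p] == expected for p in eligible)
        return hits / len(eligible), len(eligible)

    sens_up, n_up = _sensitivity(up_ids, "up")
    sens_down, n_down = _sensitivity(down_ids, "down")
    null_eligible = [p for p in null_ids if not_excluded.get(p, False)]
    false_calls = sum(call[p] in ("up", "down") for p in null_eligible)
    return {
        "sensitivity_up": sens_up,
        "n_up_eligible": n_up,
        "sensitivity_down": sens_down,
        "n_down_eligible": n_down,
        "nonspecific_excluded_fraction": (
            float(np.mean([call.get(p) == "excluded" for p in ns_ids]))
            if len(ns_ids)
            else float("nan")
        ),
        "false_call_rate": (
            false_calls / len(null_eligible) if null_eligible else float("nan")
        ),
        "n_null_eligible": len(null_eligible),
    }


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def simulate_fasta(
    n: int,
    length_range: tuple[int, int] = (100, 600),
    met_rate: float = 0.02,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random protein sequences with a controlled internal-Met rate.

    Every sequence starts with the initiator Met (translation convention);
    each subsequent position is Met with probability ``met_rate``, otherwise
    uniform over the other 19 residues.  The probability that a protein of
    length L is taggable is therefore 1 - (1 - met_rate)^(L-1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= met_rate <= 1:
        raise ValueError("met_rate must be in [0, 1]")
    lo, hi = length_range
    if not 2 <= lo <= hi:
        raise ValueError("length_range must satisfy 2 <= min <= max")
    rng = np.random.default_rng(seed)
    others = np.array([a for a in AMINO_ACIDS if a != "M"])
    records = []
    for i in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        is_met = rng.random(length - 1) < met_rate
        body = others[rng.integers(0, len(others), length - 1)]
        body[is_met] = "M"
        records.append((f"SYN{i:05d}", "M" + "".join(body)))
    return records
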