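"""End-to-end orchestration: read, validate, collapse, normalize, call, report.

``run_pipeline`` wires the stages together and writes the full calls table,
the ranked up/down reports, the normalization audit and a run log (config,
package version, input checksums).  Validation is aggregated rather than
fail-fast: array/design mismatches tend to co-occur, so every detected
problem is reported at once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .differential import DiffConfig, FoldChangeClassifier
from .io import (
    SampleMeta,
    SpotRecord,
    read_design,
    read_gpr,
    read_long_table,
)
from .normalize import (
    NormalizationFactors,
    PositiveControlNormalizer,
    ProteinLoadingNormalizer,
    write_normalization_audit,
)
from .preprocess import SignalTable, collapse_duplicates

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Aggregated cross-validation failure: lists every detected problem."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "dataset validation failed:\n" + "\n".join(f"- {p}" for p in self.problems)
        )


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    array_paths: tuple[str, ...]
    design_path: str
    out_dir: str
    dialect: str = "gpr"
    diff: DiffConfig = field(default_factory=DiffConfig)
    floor: float = 0.0
    pos_summary: str = "mean"
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    table: SignalTable
    calls: pd.DataFrame
    up_report: pd.DataFrame
    down_report: pd.DataFrame
    factors: NormalizationFactors
    output_paths: dict[str, Path]


def validate_dataset(
    spots: Sequence[SpotRecord],
    design: Sequence[SampleMeta],
) -> tuple[Sequence[SpotRecord], Sequence[SampleMeta]]:
    """Cross-check spots against the design; raise an aggregated report.

    Checks: array id correspondence in both directions, duplicate design
    rows, identical target probe sets and duplicate counts across arrays,
    unique spot coordinates, and presence of the design cells the
    differential analysis requires (MetRS baseline + stimulated, and at
    least one control-genotype array).
    """
    problems: list[str] = []

    design_ids = [m.array_id for m in design]
    dupes = sorted({a for a in design_ids if design_ids.count(a) > 1})
    if dupes:
        problems.append(f"duplicate array_id(s) in design: {dupes}")
    design_set = set(design_ids)
    spot_set = {s.array_id for s in spots}
    for a in sorted(spot_set - design_set):
        problems.append(f"array {a!r} has spots but no design row")
    for a in sorted(design_set - spot_set):
        problems.append(f"array {a!r} is in the design but has no spots")

    coords: set[tuple[str, int, int, int]] = set()
    for s in spots:
        key = (s.array_id, s.block, s.row, s.col)
        if key in coords:
            problems.append(
                f"duplicate spot coordinates {key[1:]} on array {s.array_id!r}"
            )
        coords.add(key)

    common = sorted(spot_set & design_set)
    counts: dict[str, dict[str, int]] = {}
    for s in spots:
        if s.probe_role == "target" and s.array_id in design_set:
            counts.setdefault(s.array_id, {}).setdefault(s.probe_id, 0)
            counts[s.array_id][s.probe_id] += 1
    if len(common) > 1:
        ref_array = common[0]
        ref = counts.get(ref_array, {})
        for a in common[1:]:
            cur = counts.get(a, {})
            missing = sorted(set(ref) - set(cur))
            extra = sorted(set(cur) - set(ref))
            for p in missing[:10]:
                problems.append(f"probe {p!r} missing from array {a!r}")
            for p in extra[:10]:
                problems.append(f"probe {p!r} on array {a!r} absent from {ref_array!r}")
            for p in set(ref) & set(cur):
                if ref[p] != cur[p]:
                    problems.append(
                        f"probe {p!r} spotted {cur[p]}x on array {a!r} "
                        f"but {ref[p]}x on {ref_array!r}"
                    )

    cells = {(m.genotype, m.condition) for m in design}
    if ("metrs", "baseline") not in cells:
        problems.append("design lacks a metrs/baseline array (needed for fold changes)")
    if ("metrs", "stimulated") not in cells:
        problems.append("design lacks a metrs/stimulated array (needed for fold changes)")
    if not any(g == "control" for g, _ in cells):
        problems.append(
            "design lacks a control-genotype array (needed for non-specific exclusion)"
        )

    if problems:
        raise ValidationError(problems)
    return spots, design


def load_arrays(
    paths: Sequence[str | Path],
    dialect: str = "gpr",
) -> list[SpotRecord]:
    """Read spot data from GPR files (array id = file stem) or long tables.

    Paths are processed in sorted order so results are independent of
    file-listing order.
    """
    spots: list[SpotRecord] = []
    for p in sorted(Path(q) for q in paths):
        if dialect == "gpr":
            spots.extend(read_gpr(p, array_id=p.stem))
        elif dialect == "long_table":
            spots.extend(read_long_table(p))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return spots


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write reports to ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spots = load_arrays(cfg.array_paths, cfg.dialect)
    design = read_design(cfg.design_path)
    validate_dataset(spots, design)

    table = collapse_duplicates(spots, design, floor=cfg.floor)
    pos = PositiveControlNormalizer(summary=cfg.pos_summary).fit(table)
    table = pos.transform(table)
    conc = ProteinLoadingNormalizer().fit(table)
    table = conc.transform(table)
    factors = NormalizationFactors(
        pos_factor=dict(pos.pos_factor_),
        conc_factor=dict(conc.conc_factor_),
        pos_reference=pos.pos_reference_,
        conc_reference=conc.conc_reference_,
    )

    clf = FoldChangeClassifier(
        up_threshold=cfg.diff.up_threshold,
        down_threshold=cfg.diff.down_threshold,
        top_fraction=cfg.diff.top_fraction,
        top_k_up=cfg.diff.top_k_up,
        exclusion_mode=cfg.diff.exclusion_mode,
        pseudocount=cfg.diff.pseudocount,
    ).fit(table)

    paths = {
        "calls": out_dir / "calls.tsv",
        "up_report": out_dir / "up_report.tsv",
        "down_report": out_dir / "down_report.tsv",
        "audit": out_dir / "normalization_audit.tsv",
        "run_log": out_dir / "run_log.json",
    }
    clf.results_.to_csv(paths["calls"], sep="\t", float_format="%.6g")
    clf.up_report_.to_csv(paths["up_report"], sep="\t", float_format="%.6g")
    clf.down_report_.to_csv(paths["down_report"], sep="\t", float_format="%.6g")
    write_normalization_audit(table, factors, paths["audit"])

    run_log = {
        "package_version": __version__,
        "config": {
            "array_paths": [str(p) for p in sorted(cfg.array_paths)],
            "design_path": str(cfg.design_path),
            "dialect": cfg.dialect,
            "diff": asdict(cfg.diff),
            "floor": cfg.floor,
            "pos_summary": cfg.pos_summary,
        },
        "input_sha256": {
            str(p): _sha256(p) for p in sorted(cfg.array_paths)
        }
        | {str(cfg.design_path): _sha256(cfg.design_path)},
    }
    with paths["run_log"].open("w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        table=table,
        calls=clf.results_,
        up_report=clf.up_report_,
        down_report=clf.down_report_,
        factors=factors,
        output_paths=paths,
    )
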