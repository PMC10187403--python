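"""Non-specific-binding exclusion, fold-change calling and ranked reporting.

The cell-selective labeling chemistry only biotinylates proteins made in
MetRS(L274G)-expressing cells, so any probe that lights up strongly on an
array hybridized with material from *non*-expressing control cells is
binding non-specifically.  The exclusion rule used here marks a probe
non-specific if its signal on any control-genotype array falls in the top
tertile of that array's expression distribution (default), or, in the
pooled variant, above the pooled upper-tertile cutoff of all arrays.

For the remaining probes, the fold change is the mean normalized signal of
MetRS-expressing arrays in the stimulated condition divided by the mean in
the baseline condition.  Calls follow the array manufacturer's significance
bounds: up if FC > 1.5, down if FC < 0.65, strict at the boundaries.  The
up report keeps only the top 10 largest fold changes; the down report is
never truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import SampleMeta
from .preprocess import SignalTable

EXCLUSION_MODES = ("per_control_array_rank", "pooled_tertile")
CALLS = ("up", "down", "ns", "excluded")


class ConfigurationError(ValueError):
    """The design lacks a group required by the analysis."""


@dataclass(frozen=True)
class DiffConfig:
    """Thresholds and options for differential secretion calling.

    up_threshold / down_threshold are the manufacturer's significance bounds
    (strict: boundary values are non-significant).  top_fraction is the
    quantile mass treated as "top tertile" for the exclusion rule; top_k_up
    is the size of the up-report.  pseudocount (default 0 = off) is added to
    both numerator and denominator of the fold change for exploratory use
    with zero baselines.
    """

    up_threshold: float = 1.5
    down_threshold: float = 0.65
    top_fraction: float = 1.0 / 3.0
    top_k_up: int = 10
    exclusion_mode: str = "per_control_array_rank"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.down_threshold < 1 < self.up_threshold):
            raise ValueError(
                "thresholds must satisfy 0 < down_threshold < 1 < up_threshold"
            )
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.top_k_up < 1:
            raise ValueError("top_k_up must be >= 1")
        if self.exclusion_mode not in EXCLUSION_MODES:
            raise ValueError(
                f"exclusion_mode must be one of {EXCLUSION_MODES}, "
                f"got {self.exclusion_mode!r}"
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _require_fully_normalized(table: SignalTable) -> None:
    if table.stage != "fully_normalized":
        raise ValueError(
            f"differential analysis requires a fully_normalized table, "
            f"got stage {table.stage!r}"
        )


class NonspecificBindingFilter(BaseEstimator):
    """Flag probes whose control-genotype signal sits in the top tertile.

    Parameters
    ----------
    top_fraction : float, default 1/3
        Fraction of the distribution treated as "top".
    mode : {"per_control_array_rank", "pooled_tertile"}
        ``per_control_array_rank`` (default): on each control-genotype array
        the cutoff is the ceil(P * top_fraction)-th largest valid value
        (ties at the cutoff inclusive); a probe at or above the cutoff on
        any control array is excluded globally.  ``pooled_tertile``: the
        cutoff is the empirical (1 - top_fraction) quantile of all valid
        values pooled over all arrays, applied to control arrays only.

    Attributes
    ----------
    excluded_ : frozenset of probe ids
    triggering_arrays_ : dict probe_id -> tuple of control array ids
    cutoffs_ : dict array_id -> cutoff signal (pooled mode: key "pooled")
    """

    def __init__(
        self,
        top_fraction: float = 1.0 / 3.0,
        mode: str = "per_control_array_rank",
    ):
        self.top_fraction = top_fraction
        self.mode = mode

    def fit(self, X: SignalTable, y=None):
        table = X
        _require_fully_normalized(table)
        if self.mode not in EXCLUSION_MODES:
            raise ValueError(f"unknown exclusion mode {self.mode!r}")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        control_arrays = [m.array_id for m in table.meta if m.genotype == "control"]
        if not control_arrays:
            raise ConfigurationError(
                "non-specific-binding exclusion requires at least one "
                "control-genotype array"
            )

        triggering: dict[str, list[str]] = {}
        cutoffs: dict[str, float] = {}

        if self.mode == "per_control_array_rank":
            for a in control_arrays:
                col = table.values[a].dropna()
                if col.empty:
                    continue
                m = math.ceil(len(col) * self.top_fraction)
                cutoff = float(np.sort(col.to_numpy())[::-1][m - 1])
                cutoffs[a] = cutoff
                for p in col.index[col >= cutoff]:
                    triggering.setdefault(p, []).append(a)
        else:  # pooled_tertile
            pooled = table.values.to_numpy().ravel()
            pooled = pooled[~np.isnan(pooled)]
            cutoff = float(np.quantile(pooled, 1.0 - self.top_fraction))
            cutoffs["pooled"] = cutoff
            for a in control_arrays:
                col = table.values[a].dropna()
                for p in col.index[col >= cutoff]:
                    triggering.setdefault(p, []).append(a)

        self.control_arrays_ = tuple(control_arrays)
        self.cutoffs_ = cutoffs
        self.triggering_arrays_ = {p: tuple(sorted(v)) for p, v in triggering.items()}
        self.excluded_ = frozenset(triggering)
        return self


class FoldChangeClassifier(BaseEstimator):
    """End-stage estimator: exclusion, fold change, classification, ranking.

    Fits on a fully normalized :class:`SignalTable` whose design contains at
    least one MetRS-genotype array per condition and at least one
    control-genotype array.  Parameters mirror :class:`DiffConfig`.

    Attributes
    ----------
    results_ : DataFrame indexed by probe_id with columns signal_baseline,
        signal_stimulated, fold_change, call, exclusion_reason,
        triggering_arrays, rank.
    up_report_, down_report_ : DataFrame
        Ranked significant calls; the up report is truncated to
        ``top_k_up``, the down report is complete.
    filter_ : NonspecificBindingFilter
        The fitted exclusion filter.
    """

    def __init__(
        self,
        up_threshold: float = 1.5,
        down_threshold: float = 0.65,
        top_fraction: float = 1.0 / 3.0,
        top_k_up: int = 10,
        exclusion_mode: str = "per_control_array_rank",
        pseudocount: float = 0.0,
    ):
        self.up_threshold = up_threshold
        self.down_threshold = down_threshold
        self.top_fraction = top_fraction
        self.top_k_up = top_k_up
        self.exclusion_mode = exclusion_mode
        self.pseudocount = pseudocount

    def _config(self) -> DiffConfig:
        return DiffConfig(
            up_threshold=self.up_threshold,
            down_threshold=self.down_threshold,
            top_fraction=self.top_fraction,
            top_k_up=self.top_k_up,
            exclusion_mode=self.exclusion_mode,
            pseudocount=self.pseudocount,
        )

    def fit(self, X: SignalTable, y=None):
        table = X
        cfg = self._config()
        _require_fully_normalized(table)

        self.filter_ = NonspecificBindingFilter(
            top_fraction=cfg.top_fraction, mode=cfg.exclusion_mode
        ).fit(table)

        fc = compute_fold_changes(table, pseudocount=cfg.pseudocount)

        rows = []
        for p in table.probes:
            base = fc.loc[p, "signal_baseline"]
            stim = fc.loc[p, "signal_stimulated"]
            ratio = fc.loc[p, "fold_change"]
            excluded = p in self.filter_.excluded_
            call = classify_fold_change(ratio, excluded, cfg)
            if excluded:
                reason = "nonspecific_top_tertile"
            elif np.isnan(base) or np.isnan(stim):
                reason = "no_valid_spots"
            elif np.isnan(ratio):
                reason = "incalculable_fc"
            else:
                reason = "none"
            rows.append(
                {
                    "probe_id": p,
                    "signal_baseline": base,
                    "signal_stimulated": stim,
                    "fold_change": ratio,
                    "call": call,
                    "exclusion_reason": reason,
                    "triggering_arrays": ";".join(
                        self.filter_.triggering_arrays_.get(p, ())
                    ),
                }
            )
        results = pd.DataFrame(rows).set_index("probe_id")
        up, down = rank_and_select(results, cfg)
        results["rank"] = pd.Series(dtype="Int64")
        for report in (up, down):
            results.loc[report.index, "rank"] = report["rank"].astype("Int64")
        self.results_ = results
        self.up_report_ = up
        self.down_report_ = down
        return self


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def exclude_nonspecific(
    table: SignalTable,
    meta: Sequence[SampleMeta] | None = None,
    cfg: DiffConfig | None = None,
) -> dict[str, tuple[bool, tuple[str, ...]]]:
    """Per-probe (excluded, triggering control arrays) under the tertile rule.

    ``meta`` optionally overrides the design carried by the table.
    """
    cfg = cfg or DiffConfig()
    if meta is not None:
        table = SignalTable(
            table.values,
            table.missing_reason,
            table.duplicate_cv,
            table.pos_values,
            table.neg_values,
            meta,
            table.applied,
        )
    filt = NonspecificBindingFilter(
        top_fraction=cfg.top_fraction, mode=cfg.exclusion_mode
    ).fit(table)
    return {
        p: (p in filt.excluded_, filt.triggering_arrays_.get(p, ()))
        for p in table.probes
    }


def compute_fold_changes(
    table: SignalTable,
    meta: Sequence[SampleMeta] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-probe condition means over MetRS-genotype arrays and their ratio.

    The per-condition signal is the mean of valid normalized values over the
    MetRS-genotype replicate arrays of that condition; the fold change is
    stimulated / baseline, NaN (incalculable) if the baseline is <= 0 or
    either side has no valid value.
    """
    _require_fully_normalized(table)
    meta = list(meta) if meta is not None else table.meta
    base_arrays = [
        m.array_id for m in meta if m.genotype == "metrs" and m.condition == "baseline"
    ]
    stim_arrays = [
        m.array_id
        for m in meta
        if m.genotype == "metrs" and m.condition == "stimulated"
    ]
    if not base_arrays or not stim_arrays:
        raise ConfigurationError(
            "fold changes require at least one MetRS-genotype array per condition "
            f"(baseline: {len(base_arrays)}, stimulated: {len(stim_arrays)})"
        )
    base = table.values[base_arrays].mean(axis=1)  # skips NaN per pandas default
    stim = table.values[stim_arrays].mean(axis=1)
    if pseudocount > 0:
        fc = (stim + pseudocount) / (base + pseudocount)
        fc[base.isna() | stim.isna()] = np.nan
    else:
        fc = stim / base
        fc[(base <= 0) | base.isna() | stim.isna()] = np.nan
    return pd.DataFrame(
        {
            "signal_baseline": base,
            "signal_stimulated": stim,
            "fold_change": fc,
        }
    )


def classify_fold_change(
    fc: float,
    excluded: bool,
    cfg: DiffConfig | None = None,
) -> str:
    """Classify one fold change: up / down / ns / excluded.

    Thresholds are strict: a fold change exactly at a bound is ``ns``.
    An excluded probe, or an incalculable (NaN/None) fold change, is
    ``excluded``.
    """
    cfg = cfg or DiffConfig()
    if excluded or fc is None or np.isnan(fc):
        return "excluded"
    if fc > cfg.up_threshold:
        return "up"
    if fc < cfg.down_threshold:
        return "down"
    return "ns"


def rank_and_select(
    calls: pd.DataFrame,
    cfg: DiffConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the ranked up/down reports from a classified calls table.

    The up report is sorted by fold change descending and truncated to the
    ``top_k_up`` largest; the down report is sorted ascending and complete.
    Ties break lexicographically by probe id; ranks are 1..n per report.
    """
    cfg = cfg or DiffConfig()
    up = (
        calls[calls["call"] == "up"]
        .reset_index()
        .sort_values(by=["fold_change", "probe_id"], ascending=[False, True])
        .set_index("probe_id")
        .head(cfg.top_k_up)
    )
    up["rank"] = np.arange(1, len(up) + 1)
    down = (
        calls[calls["call"] == "down"]
        .reset_index()
        .sort_values(by=["fold_change", "probe_id"], ascending=[True, True])
        .set_index("probe_id")
    )
    down["rank"] = np.arange(1, len(down) + 1)
    keep = ["signal_baseline", "signal_stimulated", "fold_change", "rank"]
    return up[keep], down[keep]
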