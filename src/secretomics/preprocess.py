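"""Background subtraction and duplicate-spot collapse.

The antibody array prints each target antibody in duplicate.  The per-probe
signal used by the whole downstream analysis is the arithmetic mean of the
background-subtracted median intensities of the valid (unflagged) duplicate
spots.  Background-subtracted values are clamped at a floor (default 0):
signals are physical abundances, and an exact zero later renders a fold
change incalculable rather than negative or infinite.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LayoutError, SampleMeta, SpotRecord

STAGES = ("collapsed", "pos_normalized", "conc_normalized", "fully_normalized")


class SignalTable:
    """Probe x array matrix of collapsed (and later normalized) signals.

    Parameters
    ----------
    values : DataFrame, probes x arrays
        Collapsed signal in arbitrary fluorescence units; NaN marks a
        missing cell (see ``missing_reason``).
    missing_reason : DataFrame, probes x arrays
        ``"none"`` where a value is present, ``"no_valid_spots"`` where all
        duplicate spots of the probe were flagged bad.
    duplicate_cv : DataFrame, probes x arrays
        sd/mean of the valid background-subtracted duplicates (QC only;
        0 for a single valid spot or zero mean).
    pos_values, neg_values : mapping array_id -> ndarray
        Background-subtracted intensities of the valid control spots,
        retained so normalization can summarize them by mean or median.
    meta : sequence of SampleMeta
        Design rows for the arrays in ``values`` (same set of array ids).
    applied : frozenset of {"pos", "conc"}
        Which per-array normalizations have been applied.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        missing_reason: pd.DataFrame,
        duplicate_cv: pd.DataFrame,
        pos_values: Mapping[str, np.ndarray],
        neg_values: Mapping[str, np.ndarray],
        meta: Sequence[SampleMeta],
        applied: frozenset = frozenset(),
    ) -> None:
        if not values.index.equals(missing_reason.index) or not values.columns.equals(
            missing_reason.columns
        ):
            raise ValueError("values and missing_reason must be aligned")
        present = values.notna()
        if (values[present] < 0).any().any():
            raise ValueError("all present signals must be >= 0")
        if not ((missing_reason == "none") == present).all().all():
            raise ValueError("missing_reason inconsistent with NaN pattern")
        meta_ids = {m.array_id for m in meta}
        if meta_ids != set(values.columns):
            raise ValueError(
                f"design arrays {sorted(meta_ids)} do not match "
                f"signal arrays {sorted(values.columns)}"
            )
        unknown = applied - {"pos", "conc"}
        if unknown:
            raise ValueError(f"unknown normalization tag(s) {sorted(unknown)}")
        self.values = values
        self.missing_reason = missing_reason
        self.duplicate_cv = duplicate_cv
        self.pos_values = {a: np.asarray(v, dtype=float) for a, v in pos_values.items()}
        self.neg_values = {a: np.asarray(v, dtype=float) for a, v in neg_values.items()}
        self.meta = list(meta)
        self.applied = frozenset(applied)

    @property
    def stage(self) -> str:
        if self.applied == {"pos", "conc"}:
            return "fully_normalized"
        if self.applied == {"pos"}:
            return "pos_normalized"
        if self.applied == {"conc"}:
            return "conc_normalized"
        return "collapsed"

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def arrays(self) -> pd.Index:
        return self.values.columns

    def meta_by_array(self) -> dict[str, SampleMeta]:
        return {m.array_id: m for m in self.meta}

    def pos_summary(self, how: str = "mean") -> pd.Series:
        """Per-array summary of the positive-control spots (mean or median)."""
        if how not in ("mean", "median"):
            raise ValueError(f"unknown positive-control summary {how!r}")
        fn = np.mean if how == "mean" else np.median
        return pd.Series(
            {
                a: (fn(self.pos_values[a]) if len(self.pos_values.get(a, ())) else np.nan)
                for a in self.arrays
            },
            name=f"pos_{how}",
        ).reindex(self.arrays)

    def scale_arrays(
        self, factors: pd.Series, tag: str, scale_controls: bool = True
    ) -> "SignalTable":
        """Return a copy with every array's values multiplied by its factor.

        Missingness and exact zeros are preserved.  ``scale_controls``
        decides whether control-spot values follow the factor: a slide-
        performance correction scales them (so positive-control summaries
        end up equalized), while the loading correction does not — printed
        control spots do not depend on how much sample protein was loaded.
        """
        if tag in self.applied:
            raise ValueError(f"{tag!r} normalization already applied (stage {self.stage})")
        factors = factors.reindex(self.arrays)
        if factors.isna().any() or not np.isfinite(factors).all() or (factors <= 0).any():
            raise ValueError("normalization factors must be strictly positive and finite")
        if scale_controls:
            pos = {a: v * factors[a] for a, v in self.pos_values.items()}
            neg = {a: v * factors[a] for a, v in self.neg_values.items()}
        else:
            pos, neg = self.pos_values, self.neg_values
        return SignalTable(
            values=self.values.mul(factors, axis=1),
            missing_reason=self.missing_reason,
            duplicate_cv=self.duplicate_cv,
            pos_values=pos,
            neg_values=neg,
            meta=self.meta,
            applied=self.applied | {tag},
        )

    def copy(self) -> "SignalTable":
        return SignalTable(
            self.values.copy(),
            self.missing_reason.copy(),
            self.duplicate_cv.copy(),
            {a: v.copy() for a, v in self.pos_values.items()},
            {a: v.copy() for a, v in self.neg_values.items()},
            list(self.meta),
            self.applied,
        )


def subtract_background(spot: SpotRecord, floor: float = 0.0) -> float:
    """Background-subtracted median intensity, clamped at ``floor``."""
    return max(spot.fg_median - spot.bg_median, floor)


def collapse_duplicates(
    spots: Sequence[SpotRecord],
    meta: Sequence[SampleMeta],
    floor: float = 0.0,
) -> SignalTable:
    """Collapse duplicate spots to one background-subtracted value per (array, probe).

    For each target probe on each array, the value is the arithmetic mean of
    the background-subtracted intensities of spots with flag >= 0; flagged
    spots are excluded.  If no valid spot remains the cell is missing with
    reason ``no_valid_spots``.  Control-spot (POS/NEG) subtracted values are
    retained per array for normalization.

    Raises
    ------
    LayoutError
        If the target probe set differs between arrays.
    """
    meta_ids = [m.array_id for m in meta]
    by_array: dict[str, list[SpotRecord]] = {a: [] for a in meta_ids}
    for s in spots:
        if s.array_id not in by_array:
            raise LayoutError(f"spot array {s.array_id!r} absent from design")
        by_array[s.array_id].append(s)

    probe_sets = {
        a: {s.probe_id for s in arr_spots if s.probe_role == "target"}
        for a, arr_spots in by_array.items()
    }
    reference = None
    for a, pset in probe_sets.items():
        if reference is None:
            reference = pset
        elif pset != reference:
            diff = sorted(reference ^ pset)
            raise LayoutError(
                f"target probe set differs on array {a!r} (e.g. {diff[:5]})"
            )
    probes = sorted(reference or ())

    values = pd.DataFrame(np.nan, index=probes, columns=meta_ids, dtype=float)
    reason = pd.DataFrame("no_valid_spots", index=probes, columns=meta_ids)
    cv = pd.DataFrame(0.0, index=probes, columns=meta_ids, dtype=float)
    pos_values: dict[str, np.ndarray] = {}
    neg_values: dict[str, np.ndarray] = {}

    for a, arr_spots in by_array.items():
        per_probe: dict[str, list[float]] = {}
        pos, neg = [], []
        for s in arr_spots:
            if s.flag < 0:
                continue
            sub = subtract_background(s, floor)
            if s.probe_role == "target":
                per_probe.setdefault(s.probe_id, []).append(sub)
            elif s.probe_role == "pos_control":
                pos.append(sub)
            elif s.probe_role == "neg_control":
                neg.append(sub)
        pos_values[a] = np.array(pos, dtype=float)
        neg_values[a] = np.array(neg, dtype=float)
        for p, vals in per_probe.items():
            arr = np.array(vals, dtype=float)
            m = arr.mean()
            values.loc[p, a] = m
            reason.loc[p, a] = "none"
            if len(arr) > 1 and m > 0:
                cv.loc[p, a] = arr.std(ddof=1) / m

    return SignalTable(values, reason, cv, pos_values, neg_values, meta)
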