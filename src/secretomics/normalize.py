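"""Per-array multiplicative normalizations.

Two scalar corrections are applied to each array, mirroring standard
practice for sandwich antibody arrays:

1. **Positive-control scaling** — every array carries printed
   positive-control spots with a nominally fixed bright signal; equalizing
   their per-array summary to the grand mean corrects slide-to-slide
   differences in labeling, hybridization and scanning efficiency.
2. **Protein-loading scaling** — each sample's signals are divided by its
   loaded total-protein concentration (BCA assay), expressed as a factor
   relative to the mean concentration, so differences in the amount of
   conditioned-media protein applied do not masquerade as secretion changes.

Both corrections are per-array scalars, so they commute; downstream fold
changes are invariant to rescaling any single array's raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import SignalTable


class DegenerateArrayError(ValueError):
    """An array's positive-control summary is missing or non-positive."""


@dataclass(frozen=True)
class NormalizationFactors:
    """Audit record of the per-array factors actually applied."""

    pos_factor: Mapping[str, float]
    conc_factor: Mapping[str, float]
    pos_reference: float
    conc_reference: float


def _require_signal_table(X) -> SignalTable:
    if not isinstance(X, SignalTable):
        raise TypeError(f"expected a SignalTable, got {type(X).__name__}")
    return X


class PositiveControlNormalizer(TransformerMixin, BaseEstimator):
    """Equalize each array's positive-control summary to the grand mean.

    Parameters
    ----------
    summary : {"mean", "median"}, default "mean"
        Per-array summary statistic of the positive-control spot signals.

    Attributes
    ----------
    pos_reference_ : float
        Grand mean over arrays of the per-array positive-control summaries.
    pos_factor_ : Series, indexed by array_id
        ``pos_reference_ / summary[array]``; after ``transform`` every
        array's positive-control summary equals ``pos_reference_``.
    """

    def __init__(self, summary: str = "mean"):
        self.summary = summary

    def fit(self, X: SignalTable, y=None):
        table = _require_signal_table(X)
        if "pos" in table.applied:
            raise ValueError("positive-control normalization already applied")
        summaries = table.pos_summary(self.summary)
        bad = summaries.index[~(summaries > 0)].tolist()
        if bad:
            raise DegenerateArrayError(
                f"non-positive or missing positive-control summary on array(s) {bad}"
            )
        self.pos_reference_ = float(summaries.mean())
        self.pos_factor_ = self.pos_reference_ / summaries
        self.pos_factor_.name = "pos_factor"
        return self

    def transform(self, X: SignalTable) -> SignalTable:
        table = _require_signal_table(X)
        return table.scale_arrays(self.pos_factor_, "pos")


class ProteinLoadingNormalizer(TransformerMixin, BaseEstimator):
    """Scale each array by its loaded protein concentration relative to the mean.

    Attributes
    ----------
    conc_reference_ : float
        Mean protein concentration over arrays.
    conc_factor_ : Series, indexed by array_id
        ``conc_reference_ / protein_conc[array]`` — arrays loaded with more
        protein are scaled down proportionally.
    """

    def fit(self, X: SignalTable, y=None):
        table = _require_signal_table(X)
        if "conc" in table.applied:
            raise ValueError("protein-loading normalization already applied")
        conc = pd.Series(
            {m.array_id: m.protein_conc for m in table.meta}, name="protein_conc"
        ).reindex(table.arrays)
        if conc.isna().any():
            missing = conc.index[conc.isna()].tolist()
            raise ValueError(f"missing protein concentration for array(s) {missing}")
        self.conc_reference_ = float(conc.mean())
        self.conc_factor_ = self.conc_reference_ / conc
        self.conc_factor_.name = "conc_factor"
        return self

    def transform(self, X: SignalTable) -> SignalTable:
        table = _require_signal_table(X)
        return table.scale_arrays(self.conc_factor_, "conc", scale_controls=False)


def positive_control_normalize(
    table: SignalTable, summary: str = "mean"
) -> tuple[SignalTable, NormalizationFactors]:
    """Functional wrapper around :class:`PositiveControlNormalizer`."""
    est = PositiveControlNormalizer(summary=summary).fit(table)
    out = est.transform(table)
    factors = NormalizationFactors(
        pos_factor=dict(est.pos_factor_),
        conc_factor={},
        pos_reference=est.pos_reference_,
        conc_reference=float("nan"),
    )
    return out, factors


def concentration_normalize(
    table: SignalTable,
    meta=None,
) -> tuple[SignalTable, NormalizationFactors]:
    """Functional wrapper around :class:`ProteinLoadingNormalizer`.

    ``meta`` optionally overrides the design rows carried by the table.
    """
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
    est = ProteinLoadingNormalizer().fit(table)
    out = est.transform(table)
    factors = NormalizationFactors(
        pos_factor={},
        conc_factor=dict(est.conc_factor_),
        pos_reference=float("nan"),
        conc_reference=est.conc_reference_,
    )
    return out, factors


def normalize_table(
    table: SignalTable, summary: str = "mean"
) -> tuple[SignalTable, NormalizationFactors]:
    """Apply both normalizations (positive-control first, then loading)."""
    pos = PositiveControlNormalizer(summary=summary).fit(table)
    out = pos.transform(table)
    conc = ProteinLoadingNormalizer().fit(out)
    out = conc.transform(out)
    return out, NormalizationFactors(
        pos_factor=dict(pos.pos_factor_),
        conc_factor=dict(conc.conc_factor_),
        pos_reference=pos.pos_reference_,
        conc_reference=conc.conc_reference_,
    )


def write_normalization_audit(
    table: SignalTable,
    factors: NormalizationFactors,
    path: str | Path,
) -> None:
    """Write the per-array normalization audit TSV."""
    meta = table.meta_by_array()
    rows = []
    for a in table.arrays:
        pos_f = factors.pos_factor.get(a, float("nan"))
        rows.append(
            {
                "array_id": a,
                "pos_mean": factors.pos_reference / pos_f if pos_f == pos_f else float("nan"),
                "pos_factor": pos_f,
                "protein_conc": meta[a].protein_conc,
                "conc_factor": factors.conc_factor.get(a, float("nan")),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
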