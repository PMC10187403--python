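import numpy as np
import pandas as pd
import pytest

from secretomics.io import SampleMeta
from secretomics.preprocess import SignalTable


def build_table(
    values,
    meta_specs,
    pos_values=None,
    applied=frozenset(),
    missing=(),
):
    """Construct a SignalTable directly from a probe x array value dict.

    values: {array_id: {probe_id: value}}; meta_specs: iterable of
    (array_id, genotype, condition, replicate, protein_conc); missing:
    iterable of (probe_id, array_id) cells to blank out as no_valid_spots.
    """
    frame = pd.DataFrame(values, dtype=float)
    frame = frame.sort_index()
    reason = pd.DataFrame("none", index=frame.index, columns=frame.columns)
    for probe, array in missing:
        frame.loc[probe, array] = np.nan
        reason.loc[probe, array] = "no_valid_spots"
    cv = pd.DataFrame(0.0, index=frame.index, columns=frame.columns)
    meta = [
        SampleMeta(
            array_id=a,
            sample_id=f"S_{a}",
            genotype=g,
            condition=c,
            replicate=r,
            protein_conc=conc,
        )
        for a, g, c, r, conc in meta_specs
    ]
    pos = pos_values or {a: np.array([1000.0]) for a in frame.columns}
    neg = {a: np.array([0.0]) for a in frame.columns}
    return SignalTable(frame, reason, cv, pos, neg, meta, frozenset(applied))


@pytest.fixture
def four_array_meta():
    return [
        ("M_base", "metrs", "baseline", 1, 1.0),
        ("M_stim", "metrs", "stimulated", 1, 1.0),
        ("C_base", "control", "baseline", 1, 1.0),
        ("C_stim", "control", "stimulated", 1, 1.0),
    ]
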