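"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written as plain loops over primitive data, sharing no code
path with the package internals they verify.
"""

import math


def brute_collapse(spots, floor=0.0):
    """Mean background-subtracted value per (array, probe) for target spots.

    Returns {(array_id, probe_id): mean or None}; None when every duplicate
    is flagged bad.
    """
    cells = {}
    for s in spots:
        if s.probe_role != "target":
            continue
        cells.setdefault((s.array_id, s.probe_id), []).append(s)
    out = {}
    for key, group in cells.items():
        vals = [
            max(s.fg_median - s.bg_median, floor) for s in group if s.flag >= 0
        ]
        out[key] = sum(vals) / len(vals) if vals else None
    return out


def brute_exclude(values, control_arrays, top_fraction, mode):
    """Tertile exclusion on a {array: {probe: value-or-None}} nested dict."""
    excluded = set()
    if mode == "per_control_array_rank":
        for a in control_arrays:
            valid = [(p, v) for p, v in values[a].items() if v is not None]
            if not valid:
                continue
            m = math.ceil(len(valid) * top_fraction)
            cutoff = sorted((v for _, v in valid), reverse=True)[m - 1]
            for p, v in valid:
                if v >= cutoff:
                    excluded.add(p)
    elif mode == "pooled_tertile":
        pooled = sorted(
            v for col in values.values() for v in col.values() if v is not None
        )
        n = len(pooled)
        h = (n - 1) * (1.0 - top_fraction)
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        cutoff = pooled[lo] + (h - lo) * (pooled[hi] - pooled[lo])
        for a in control_arrays:
            for p, v in values[a].items():
                if v is not None and v >= cutoff:
                    excluded.add(p)
    else:
        raise ValueError(mode)
    return excluded


def brute_fold_changes(values, baseline_arrays, stimulated_arrays):
    """Mean-then-divide fold changes; None where incalculable."""
    probes = set()
    for col in values.values():
        probes.update(col)
    out = {}
    for p in sorted(probes):
        base_vals = [values[a][p] for a in baseline_arrays if values[a][p] is not None]
        stim_vals = [values[a][p] for a in stimulated_arrays if values[a][p] is not None]
        base = sum(base_vals) / len(base_vals) if base_vals else None
        stim = sum(stim_vals) / len(stim_vals) if stim_vals else None
        if base is None or stim is None or base <= 0:
            out[p] = (base, stim, None)
        else:
            out[p] = (base, stim, stim / base)
    return out


def brute_met_counts(sequence):
    """Per-character recount of total and internal methionines."""
    seq = sequence.rstrip("*")
    total = sum(1 for c in seq.upper() if c == "M")
    internal = sum(1 for i, c in enumerate(seq.upper()) if c == "M" and i >= 1)
    return total, internal
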