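"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately written as plain dictionary/loop code with
no shared machinery with the package, so agreement is evidence, not
tautology.
"""

import math

import numpy as np


def brute_zonal_mean(values, valid, unit_raster, unit_nodata=-1):
    """Per-unit mean by scan-order dictionary accumulation."""
    sums, counts = {}, {}
    rows, cols = values.shape
    for r in range(rows):
        for c in range(cols):
            uid = int(unit_raster[r, c])
            if uid == unit_nodata or not valid[r, c]:
                continue
            sums[uid] = sums.get(uid, 0.0) + float(values[r, c])
            counts[uid] = counts.get(uid, 0) + 1
    return {uid: sums[uid] / counts[uid] for uid in sums}


def brute_aggregate_mean(values, valid, factor):
    """Block means over valid cells; NaN for all-invalid blocks."""
    rows = values.shape[0] // factor
    cols = values.shape[1] // factor
    out = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            acc, n = 0.0, 0
            for di in range(factor):
                for dj in range(factor):
                    r, c = i * factor + di, j * factor + dj
                    if valid[r, c]:
                        acc += float(values[r, c])
                        n += 1
            if n:
                out[i, j] = acc / n
    return out


def brute_unit_triples(eco, lc, cont, excluded, valid=None):
    """Distinct (ecoregion, landcover, continent) triples of valid pixels."""
    triples = set()
    rows, cols = eco.shape
    for r in range(rows):
        for c in range(cols):
            if valid is not None and not valid[r, c]:
                continue
            if int(lc[r, c]) in excluded:
                continue
            triples.add((int(eco[r, c]), int(lc[r, c]), int(cont[r, c])))
    return triples


def brute_gap_fill(values, groups):
    """Group-mean imputation: values and groups are dicts keyed by unit id."""
    by_group = {}
    for uid, v in values.items():
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            by_group.setdefault(groups[uid], []).append(v)
    means = {g: sum(vs) / len(vs) for g, vs in by_group.items()}
    out = {}
    for uid, v in values.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out[uid] = means.get(groups[uid], float("nan"))
        else:
            out[uid] = v
    return out
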