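"""Independent brute-force reference implementations used as oracles.

Deliberately written with plain per-element loops and none of the
package's vectorized/windowed machinery, so agreement is meaningful.
"""

import math

import numpy as np

from tracerscreen.chem import label_delta


def group_mean_table(table):
    """feature id -> {(treatment, time): mean} via explicit loops."""
    acc = {}
    design = table.design
    for fid in table.features["id"]:
        cells = {}
        for _, srow in design.iterrows():
            key = (srow["treatment"], float(srow["time_h"]))
            v = table.intensities.loc[fid, srow["sample_id"]]
            cells.setdefault(key, []).append(float(v))
        acc[fid] = {
            k: (float(np.nanmean(vs)) if not all(math.isnan(x) for x in vs) else math.nan)
            for k, vs in cells.items()
        }
    return acc


def unique_argmax_treatment(means_row):
    best = max(means_row.values())
    winners = [k for k, v in means_row.items() if v == best]
    if len(winners) != 1:
        return None
    return winners[0][0]


def brute_force_pairs(table, config):
    """O(n^2) enumeration of all pairs passing criteria 1-4."""
    means = group_mean_table(table)
    feats = table.features
    ids = list(feats["id"])
    mz = dict(zip(ids, feats["mz"].astype(float)))
    rt = dict(zip(ids, feats["rt"].astype(float)))
    mode = dict(zip(ids, feats["ion_mode"]))
    thr = config.intensity_multiplier * config.noise_floor
    ok1 = {f: max(means[f].values()) > thr for f in ids}
    argmax = {f: unique_argmax_treatment(means[f]) for f in ids}
    deltas = {n: label_delta(config.shift_spec, n)
              for n in sorted(config.shift_spec.allowed_counts)}

    found = set()
    for a in ids:
        for b in ids:
            if a == b or mode[a] != mode[b] or mz[b] <= mz[a]:
                continue
            gap = mz[b] - mz[a]
            tol = config.delta_ppm_tol * 1e-6 * mz[a]
            n_match = None
            for n, d in deltas.items():
                if abs(gap - d) <= tol:
                    n_match = n
                    break
            if n_match is None:
                continue
            if abs(rt[a] - rt[b]) > config.rt_tol_min:
                continue
            if not (ok1[a] and ok1[b]):
                continue
            if argmax[a] != "unlabeled_tracer" or argmax[b] != "labeled_tracer":
                continue
            found.add((a, b, n_match))
    return found


def rank_average(values):
    """Average ranks (1-based) with tie sharing, by explicit sort."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_by_ranks(x, y):
    """Pearson correlation of average ranks."""
    return pearson(rank_average(list(x)), rank_average(list(y)))


def brute_force_cobehavior(table, thresholds, config):
    """Direct per-feature loop over criteria 1, 5, 6."""
    means = group_mean_table(table)
    thr = config.intensity_multiplier * config.noise_floor
    design = table.design
    vec_samples = {}
    for trt in ("control", "unlabeled_tracer", "labeled_tracer"):
        rows = design[design["treatment"] == trt]
        rows = rows.sort_values(["time_h", "replicate"])
        vec_samples[trt] = list(rows["sample_id"])

    found = set()
    for fid in table.features["id"]:
        row = means[fid]
        if not max(row.values()) > thr:
            continue
        hi = max(row.values())
        lo = min(row.values())
        hi_own = [k for k, v in row.items() if v == hi]
        lo_own = [k for k, v in row.items() if v == lo]
        tracer = ("unlabeled_tracer", "labeled_tracer")
        ok5 = (len(hi_own) == 1 and hi_own[0][0] in tracer) or (
            len(lo_own) == 1 and lo_own[0][0] in tracer)
        if not ok5:
            continue
        vecs = {trt: [float(table.intensities.loc[fid, s]) for s in ss]
                for trt, ss in vec_samples.items()}
        if any(min(v) == max(v) for v in vecs.values()):
            continue
        rho_t = spearman_by_ranks(vecs["unlabeled_tracer"], vecs["labeled_tracer"])
        rho_cu = spearman_by_ranks(vecs["control"], vecs["unlabeled_tracer"])
        rho_cl = spearman_by_ranks(vecs["control"], vecs["labeled_tracer"])
        if rho_t > thresholds.high and rho_cu <= thresholds.low and rho_cl <= thresholds.low:
            found.add(fid)
    return found
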