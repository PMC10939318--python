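"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written with explicit loops and no shared code with
the package internals, so agreement is meaningful evidence.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Subsequence DTW oracle (explicit-loop dynamic program, same semantics)
# ---------------------------------------------------------------------------

def dtw_oracle(template, signal, scaling, max_cost, min_dur, max_dur, rate,
               max_local_run=None, resolve_overlaps=True):
    """All accepted matches as (start, end, cost), plain Python loops."""
    tpl = [t / scaling for t in template]
    sig = [s / scaling for s in signal]
    m, n = len(tpl), len(sig)
    limit = max_local_run if max_local_run is not None else m * n + 1
    INF = float("inf")
    acc = [[INF] * n for _ in range(m)]
    step = [[0] * n for _ in range(m)]
    vrun = [[0] * n for _ in range(m)]
    hrun = [[0] * n for _ in range(m)]
    for j in range(n):
        acc[0][j] = (tpl[0] - sig[j]) ** 2
    for i in range(1, m):
        for j in range(n):
            local = (tpl[i] - sig[j]) ** 2
            best, best_step = INF, 1
            if j > 0:
                best, best_step = acc[i - 1][j - 1], 1
            if vrun[i - 1][j] < limit and acc[i - 1][j] < best:
                best, best_step = acc[i - 1][j], 2
            if j > 0 and hrun[i][j - 1] < limit and acc[i][j - 1] < best:
                best, best_step = acc[i][j - 1], 3
            if best == INF:
                continue
            acc[i][j] = local + best
            step[i][j] = best_step
            vrun[i][j] = vrun[i - 1][j] + 1 if best_step == 2 else 0
            hrun[i][j] = hrun[i][j - 1] + 1 if best_step == 3 else 0
    final = acc[m - 1]
    candidates = []
    for j in range(n):
        if not final[j] < max_cost:
            continue
        if (j == 0 or final[j] <= final[j - 1]) and (
            j == n - 1 or final[j] < final[j + 1]
        ):
            # backtrack
            i, jj = m - 1, j
            while i > 0:
                s = step[i][jj]
                if s == 1:
                    i, jj = i - 1, jj - 1
                elif s == 2:
                    i -= 1
                else:
                    jj -= 1
            start, end = jj, j + 1
            dur = (end - start) / rate
            if min_dur <= dur <= max_dur:
                candidates.append((start, end, final[j]))
    if not resolve_overlaps:
        return sorted(candidates)
    accepted = []
    for cand in sorted(candidates, key=lambda c: (c[2], c[0])):
        if all(cand[1] <= a[0] or cand[0] >= a[1] for a in accepted):
            accepted.append(cand)
    return sorted(accepted)


# ---------------------------------------------------------------------------
# Exhaustive one-to-one interval matching oracle
# ---------------------------------------------------------------------------

def matching_oracle(detected, reference, tol_samples):
    """(max cardinality, min total border distance) by exhaustive search."""
    n_det, n_ref = len(detected), len(reference)
    feasible = {}
    for i, (ds, de) in enumerate(detected):
        for j, (rs, re) in enumerate(reference):
            if abs(ds - rs) <= tol_samples and abs(de - re) <= tol_samples:
                feasible[(i, j)] = abs(ds - rs) + abs(de - re)
    memo = {}

    def best(i, used):
        if i == n_det:
            return (0, 0.0)
        key = (i, used)
        if key in memo:
            return memo[key]
        card, dist = best(i + 1, used)  # leave detected i unmatched
        result = (card, dist)
        for j in range(n_ref):
            if used & (1 << j) or (i, j) not in feasible:
                continue
            c, d = best(i + 1, used | (1 << j))
            cand = (c + 1, d + feasible[(i, j)])
            if cand[0] > result[0] or (cand[0] == result[0]
                                       and cand[1] < result[1]):
                result = cand
        memo[key] = result
        return result

    return best(0, 0)


# ---------------------------------------------------------------------------
# Sliding-window region detection oracle
# ---------------------------------------------------------------------------

def window_region_oracle(values, window, hop, threshold, statistic):
    """Mark samples covered by any passing window; explicit placement loop.

    ``values`` is a per-sample sequence the statistic is computed from;
    ``statistic`` maps a window slice to a scalar.  Returns a boolean
    per-sample list including trailing-edge inheritance from the last
    evaluated window.
    """
    n = len(values)
    mask = [False] * n
    last_start = None
    last_pass = False
    for start in range(0, n - window + 1, hop):
        stat = statistic(values[start:start + window])
        last_start, last_pass = start, stat < threshold
        if last_pass:
            for k in range(start, start + window):
                mask[k] = True
    if last_start is not None and last_pass:
        for k in range(last_start + window, n):
            mask[k] = True
    return mask


def mask_to_intervals(mask):
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        if not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out
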