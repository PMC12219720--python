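"""Independent brute-force reference implementations used only by tests.

Everything here is written for clarity, not speed, and shares no code with
the package: flood-fill patch labelling, direct adjacency tallies,
exhaustive partition search for natural breaks, and double-loop spatial
statistics.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def flood_fill_patches(window, connectivity=8, nodata=-9999):
    """List of (class, area, perimeter) via explicit flood fill."""
    window = np.asarray(window)
    nrows, ncols = window.shape
    seen = np.zeros(window.shape, bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    patches = []
    for r0 in range(nrows):
        for c0 in range(ncols):
            if seen[r0, c0] or window[r0, c0] == nodata:
                continue
            code = window[r0, c0]
            stack, cells = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nrows and 0 <= cc < ncols
                            and not seen[rr, cc]
                            and window[rr, cc] == code):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            perim = 0
            for r, c in cells:
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols):
                        perim += 1
                    elif window[rr, cc] != code:
                        perim += 1
            patches.append((int(code), len(cells), perim))
    return patches


def shdi_direct(window, nodata=-9999):
    vals = [v for v in np.asarray(window).ravel() if v != nodata]
    out = 0.0
    for code in set(vals):
        p = vals.count(code) / len(vals)
        out -= p * math.log(p)
    return out


def awmpfd_direct(window, connectivity=8, nodata=-9999):
    patches = flood_fill_patches(window, connectivity, nodata)
    total_area = sum(a for _, a, _ in patches)
    out = 0.0
    for _, a, p in patches:
        d = 1.0 if a == 1 else 2 * math.log(0.25 * p) / math.log(a)
        out += d * a / total_area
    return out


def contagion_direct(window, nodata=-9999):
    """FRAGSTATS CONTAG via cell-by-cell adjacency enumeration."""
    window = np.asarray(window)
    nrows, ncols = window.shape
    vals = [v for v in window.ravel() if v != nodata]
    codes = sorted(set(vals))
    if len(codes) == 1:
        return 100.0
    # double-count: every 4-adjacency contributes to g[a][b] and g[b][a]
    g = {(a, b): 0 for a in codes for b in codes}
    for r in range(nrows):
        for c in range(ncols):
            a = window[r, c]
            if a == nodata:
                continue
            for rr, cc in [(r, c + 1), (r + 1, c)]:
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    b = window[rr, cc]
                    if b == nodata:
                        continue
                    g[(a, b)] += 1
                    g[(b, a)] += 1
    total = 0.0
    m = len(codes)
    for a in codes:
        pa = vals.count(a) / len(vals)
        rowsum = sum(g[(a, b)] for b in codes)
        for b in codes:
            if rowsum == 0 or g[(a, b)] == 0:
                continue
            pp = pa * g[(a, b)] / rowsum
            total += pp * math.log(pp)
    return 100.0 * (1.0 + total / (2.0 * math.log(m)))


def cohesion_direct(window, class_code, connectivity=8, nodata=-9999):
    patches = [p for p in flood_fill_patches(window, connectivity, nodata)
               if p[0] == class_code]
    z = sum(1 for v in np.asarray(window).ravel() if v != nodata)
    if not patches:
        return 0.0
    sp = sum(p for _, _, p in patches)
    spa = sum(p * math.sqrt(a) for _, a, p in patches)
    return (1 - sp / spa) / (1 - 1 / math.sqrt(z)) * 100.0


# ---------------------------------------------------------------------------
# natural breaks
# ---------------------------------------------------------------------------

def jenks_exhaustive(values, k):
    """Optimal k-partition of sorted values by enumerating all ordered
    partitions; returns (classes per value in input order, total SSE)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def sse(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best, best_cuts = math.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(sse(x[bounds[i]:bounds[i + 1]]) for i in range(k))
        if total < best - 1e-12:
            best, best_cuts = total, bounds
    classes_sorted = np.empty(n, dtype=int)
    for ci in range(k):
        classes_sorted[best_cuts[ci]:best_cuts[ci + 1]] = ci + 1
    # map back to input order (stable for ties)
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    out = np.empty(n, dtype=int)
    out[order] = classes_sorted
    return out, best


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def morans_i_direct(values, wmat):
    """Double-loop Moran's I over a dense weight matrix."""
    x = np.asarray(values, dtype=float)
    n = x.size
    z = x - x.mean()
    s0 = num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += wmat[i, j]
            num += wmat[i, j] * z[i] * z[j]
    return (n / s0) * num / (z @ z)


def gstar_direct(values, wstar):
    """Per-cell Gi* z-scores with explicit formula; wstar includes self."""
    x = np.asarray(values, dtype=float)
    n = x.size
    xbar = x.mean()
    s = math.sqrt(((x - xbar) ** 2).mean())
    out = np.empty(n)
    for i in range(n):
        wi = wstar[i].sum()
        wi2 = (wstar[i] ** 2).sum()
        num = (wstar[i] * x).sum() - xbar * wi
        den = s * math.sqrt((n * wi2 - wi * wi) / (n - 1))
        out[i] = num / den
    return out


# ---------------------------------------------------------------------------
# stratified variance (q)
# ---------------------------------------------------------------------------

def q_direct(y, strata):
    """1 - within/total variance, population variances, plain loops."""
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    ssw = 0.0
    for h in set(strata.tolist()):
        sub = y[strata == h]
        ssw += sub.size * sub.var()
    return 1.0 - ssw / (y.size * y.var())
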