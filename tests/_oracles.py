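"""Independent brute-force oracles for the free-energy estimators.

Everything here is written with plain Python loops and ``math.exp`` — no
log-sum-exp, no vectorization — and deliberately mirrors the estimating
equations themselves rather than the package implementation, so agreement to
1e-10 is a genuine cross-check on ensembles small enough for naive
exponentials.
"""

import math


def find_bin(edges, z):
    """Bin index for z, -1 when out of range; right-closed last bin."""
    if z < edges[0] or z > edges[-1]:
        return -1
    if z == edges[-1]:
        return len(edges) - 2
    for b in range(len(edges) - 1):
        if edges[b] <= z < edges[b + 1]:
            return b
    return -1


def bennett_root_bisect(wf, wr, beta, lo=-500.0, hi=500.0, iters=200):
    """Bisection on the Bennett self-consistent equation (independent of brentq)."""
    nf, nr = len(wf), len(wr)
    M = math.log(nf / nr)

    def h(df):
        a = sum(1.0 / (1.0 + math.exp(min(M + beta * (w - df), 700.0))) for w in wf)
        b = sum(1.0 / (1.0 + math.exp(min(-M + beta * (w + df), 700.0))) for w in wr)
        return a - b

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _slice_numerators_forward(traces, edges, beta, weights):
    """A[t][b] contributions from one direction; traces are (z list, w list) pairs."""
    n_slices = len(traces[0][0])
    n_bins = len(edges) - 1
    A = [[0.0] * n_bins for _ in range(n_slices)]
    for (zs, ws), wt in zip(traces, weights):
        for t in range(n_slices):
            b = find_bin(edges, zs[t])
            if b >= 0:
                A[t][b] += math.exp(-beta * ws[t]) * wt / len(traces)
    return A


def _wham_iterate(A, centers, edges, k, beta, tol, max_iter):
    """Plain-loop WHAM fixed point shared by the HS and MA oracles."""
    n_slices = len(A)
    n_bins = len(edges) - 1
    bin_centers = [0.5 * (edges[b] + edges[b + 1]) for b in range(n_bins)]
    occupied = [any(A[t][b] > 0.0 for t in range(n_slices)) for b in range(n_bins)]
    dft = [0.0] * n_slices
    for _ in range(max_iter):
        g0 = [None] * n_bins
        for b in range(n_bins):
            if not occupied[b]:
                continue
            num = sum(A[t][b] * math.exp(beta * dft[t]) for t in range(n_slices))
            den = sum(math.exp(-beta * (0.5 * k * (centers[t] - bin_centers[b]) ** 2)
                               + beta * dft[t]) for t in range(n_slices))
            g0[b] = -math.log(num / den) / beta
        zt = []
        for t in range(n_slices):
            zt.append(sum(math.exp(-beta * (g0[b] + 0.5 * k
                                            * (centers[t] - bin_centers[b]) ** 2))
                          for b in range(n_bins) if occupied[b]))
        new = [-(math.log(zt[t]) - math.log(zt[0])) / beta for t in range(n_slices)]
        delta = max(abs(a - b) for a, b in zip(new, dft))
        dft = new
        if delta < tol:
            break
    gmin = min(v for v in g0 if v is not None)
    return [None if v is None else v - gmin for v in g0], dft


def brute_hummer_szabo(traces, centers, k, beta, edges, tol=1e-13, max_iter=5000):
    """Unidirectional time-slice PMF by explicit loops.

    ``traces``: list of (rc list, cumulative-work list); ``centers``: bias
    centers per slice for the direction being analyzed.
    """
    A = _slice_numerators_forward(traces, edges, beta, [1.0] * len(traces))
    return _wham_iterate(A, centers, edges, k, beta, tol, max_iter)


def brute_minh_adib(fwd, rev, centers, k, beta, edges, df,
                    tol=1e-13, max_iter=5000):
    """Bidirectional time-slice PMF by explicit loops.

    ``fwd``/``rev``: (rc list, cumulative-work list) per trace in each
    direction's own time; ``centers``: forward bias centers; ``df``: endpoint
    free-energy difference of the forward process.
    """
    n_f, n_r = len(fwd), len(rev)
    n_slices = len(centers)
    n_bins = len(edges) - 1
    A = [[0.0] * n_bins for _ in range(n_slices)]
    for zs, ws in fwd:
        denom = n_f + n_r * math.exp(-beta * (ws[-1] - df))
        for t in range(n_slices):
            b = find_bin(edges, zs[t])
            if b >= 0:
                A[t][b] += math.exp(-beta * ws[t]) / denom
    for zs, ws in rev:
        denom = n_f + n_r * math.exp(beta * (ws[-1] + df))
        for t in range(n_slices):
            s = n_slices - 1 - t
            b = find_bin(edges, zs[s])
            if b >= 0:
                A[t][b] += math.exp(beta * (ws[-1] - ws[s])) / denom
    return _wham_iterate(A, centers, edges, k, beta, tol, max_iter)
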