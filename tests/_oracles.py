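"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_otsu(frame, nbins=256):
    """Exhaustive Otsu: scan every split, maximize between-class variance.

    Ties (a plateau of maximizers, as arises for an empty gap between two
    well-separated modes) resolve to the midpoint of the contiguous run
    containing the first maximizer -- the same convention the implementation
    declares.
    """
    counts, edges = np.histogram(np.asarray(frame).ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = counts.sum()
    best_var, best_ts = -1.0, []
    for t in range(nbins - 1):
        w0 = counts[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            m0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
            m1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var * (1 + 1e-9):
            best_var, best_ts = var, [t]
        elif var >= best_var * (1 - 1e-9):
            best_ts.append(t)
    run = [best_ts[0]]
    for t in best_ts[1:]:
        if t == run[-1] + 1:
            run.append(t)
        else:
            break
    return edges[run[len(run) // 2] + 1]
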