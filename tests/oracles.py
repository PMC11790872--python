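"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_ward(points: np.ndarray):
    """Merge sequence [(members_a, members_b, delta_ss)] chosen by
    exhaustively minimising the within-cluster SS increase at each step."""

    def ss_of(cluster):
        pts = points[list(cluster)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            delta = ss_of(a | b) - ss_of(a) - ss_of(b)
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        merges.append((a, b, delta))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges
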