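"""Independent brute-force oracles shared by the test modules."""

from __future__ import annotations

import numpy as np


def brute_force_minimax(F, periodic, start, end):
    """Smallest threshold c such that start and end are connected through
    grid points with F <= c, found by bisection over the sorted values with
    a BFS connectivity check (8-connected, wrapping over periodic axes).

    Deliberately independent of the package's union-find watershed.
    """
    shape = F.shape
    values = np.unique(F)

    def connected(c):
        allowed = F <= c
        if not (allowed[start] and allowed[end]):
            return False
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            if node == end:
                return True
            for off0 in (-1, 0, 1):
                for off1 in (-1, 0, 1) if len(shape) == 2 else ((0,)):
                    if off0 == 0 and (len(shape) == 1 or off1 == 0):
                        continue
                    nb = []
                    ok = True
                    offs = (off0,) if len(shape) == 1 else (off0, off1)
                    for j, (i, d, n) in enumerate(zip(node, offs, shape)):
                        k = i + d
                        if periodic[j]:
                            k %= n
                        elif k < 0 or k >= n:
                            ok = False
                            break
                        nb.append(k)
                    if not ok:
                        continue
                    nb = tuple(nb)
                    if allowed[nb] and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        return False

    lo, hi = 0, len(values) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(values[mid]):
            hi = mid
        else:
            lo = mid + 1
    return values[lo]
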