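"""Shared independent oracles for the test suite."""
from __future__ import annotations

import numpy as np


def flood_fill_regions(grid: np.ndarray, tau: float, min_px: int,
                       connectivity: int = 4):
    """Exhaustive BFS region labeling oracle, independent of skimage.

    Returns a list of dicts {sign, pixels (frozenset of (r, c)), signed_sum,
    abs_sum}, elevated components first, each component's pixel set strictly
    above threshold and of size >= min_px.  Intentionally naive.
    """
    nrow, ncol = grid.shape
    if connectivity == 4:
        steps = ((1, 0), (-1, 0), (0, 1), (0, -1))
    else:
        steps = tuple((dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                      if (dr, dc) != (0, 0))
    out = []
    for sign in (1, -1):
        member = np.zeros_like(grid, dtype=bool)
        for r in range(nrow):
            for c in range(ncol):
                v = grid[r, c]
                if np.isfinite(v):
                    member[r, c] = v >= tau if sign == 1 else v <= -tau
        seen = np.zeros_like(member)
        for r in range(nrow):
            for c in range(ncol):
                if not member[r, c] or seen[r, c]:
                    continue
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < nrow and 0 <= nc < ncol
                                and member[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                if len(comp) >= min_px:
                    vals = [grid[p] for p in comp]
                    out.append({"sign": sign, "pixels": frozenset(comp),
                                "signed_sum": float(sum(vals)),
                                "abs_sum": float(sum(abs(v) for v in vals))})
    return out
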