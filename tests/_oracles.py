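"""Brute-force oracles shared by the metric tests and acceptance checks."""

import numpy as np
import pytest

from landrisk.metrics import label_patches

def flood_fill_patches(values, nodata, connectivity):
    """Brute-force BFS patch delineation; returns list of (code, cells, perimeter_edges)."""
    H, W = values.shape
    seen = np.zeros((H, W), dtype=bool)
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    patches = []
    for r0 in range(H):
        for c0 in range(W):
            if seen[r0, c0] or values[r0, c0] == nodata:
                continue
            code = values[r0, c0]
            stack, cells = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and not seen[rr, cc] and values[rr, cc] == code:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            perim = 0
            for r, c in cells:
                for dr, dc in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < H and 0 <= cc < W) or values[rr, cc] != code:
                        perim += 1
            patches.append((code, len(cells), perim))
    return patches


def adjacency_oracle(values, nodata, codes):
    """Explicit double-count 4-neighbor adjacency tally."""
    H, W = values.shape
    idx = {c: k for k, c in enumerate(codes)}
    g = np.zeros((len(codes), len(codes)), dtype=int)
    for r in range(H):
        for c in range(W):
            if values[r, c] == nodata:
                continue
            for dr, dc in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and values[rr, cc] != nodata:
                    g[idx[values[r, c]], idx[values[rr, cc]]] += 1
    return g


def assert_patches_match_oracle(grid, connectivity):
    ps = label_patches(grid, connectivity)
    oracle = flood_fill_patches(grid.values, grid.nodata, connectivity)
    assert ps.n_patches == len(oracle)
    got = sorted(zip(ps.class_codes, ps.cell_counts, ps.perimeters_m / grid.cell_size))
    want = sorted((c, n, p) for c, n, p in oracle)
    for (gc, gn, gp), (wc, wn, wp) in zip(got, want):
        assert (gc, gn) == (wc, wn)
        assert gp == pytest.approx(wp)


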