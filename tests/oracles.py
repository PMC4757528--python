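"""Independent brute-force oracles used by the test suite.

Deliberately written as plain Python loops / BFS so they share no code path
with the vectorized implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bruteforce_pe(s0, s_early, s_late, floor):
    """Per-voxel scalar-loop PE maps."""
    shape = s0.shape
    pe_e = np.zeros(shape)
    pe_l = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(*shape):
        b = s0[idx]
        if b > floor:
            valid[idx] = True
            pe_e[idx] = (s_early[idx] - b) / b * 100.0
            pe_l[idx] = (s_late[idx] - b) / b * 100.0
    return pe_e, pe_l, valid


def _neighbors(idx, shape, connectivity):
    z, y, x = idx
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                    yield (nz, ny, nx)


def bruteforce_components(mask, connectivity=26):
    """Flood-fill connected components; returns a list of voxel-index sets."""
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for start in np.ndindex(*mask.shape):
        if not mask[start] or seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for nb in _neighbors(cur, mask.shape, connectivity):
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components


def bruteforce_ftv_count(
    pe_early, ser, valid, voi, pe_t, ser_t, min_cluster, connectivity=26
):
    """Triple-loop FTV voxel count: PE gate -> component filter -> SER gate."""
    shape = pe_early.shape
    raw = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(*shape):
        raw[idx] = bool(valid[idx]) and bool(voi[idx]) and pe_early[idx] >= pe_t
    kept = np.zeros(shape, dtype=bool)
    for comp in bruteforce_components(raw, connectivity):
        if len(comp) >= min_cluster:
            for idx in comp:
                kept[idx] = True
    count = 0
    for idx in np.ndindex(*shape):
        if kept[idx] and ser[idx] >= ser_t:
            count += 1
    return count
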