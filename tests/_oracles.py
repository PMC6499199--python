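"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive (O(n^2) scans, explicit loops) and shares
no code with the package's kd-tree / vectorized paths.
"""
import numpy as np


def brute_isolation_keep(coords, radius, min_neighbors):
    """Single-pass isolation filter by full pairwise distances."""
    n = len(coords)
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        keep[i] = (np.sum(d <= radius) - 1) >= min_neighbors
    return keep


def brute_stray_keep(ranges, valid, window, range_thresh, alloc_thresh):
    """Per-cell recount of the structured stray filter."""
    rows, cols = ranges.shape
    h = window // 2
    keep = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            if not valid[i, j]:
                continue
            n_valid = n_close = 0
            for di in range(-h, h + 1):
                for dj in range(-h, h + 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols and valid[ii, jj]:
                        n_valid += 1
                        if abs(ranges[ii, jj] - ranges[i, j]) <= range_thresh:
                            n_close += 1
            keep[i, j] = n_valid > 0 and n_close >= alloc_thresh * n_valid
    return keep


def brute_nearest(query, candidates):
    """Exhaustive nearest-candidate index; ties -> lowest index (argmin rule)."""
    out = np.empty(len(query), dtype=np.int64)
    for i, q in enumerate(query):
        d = np.linalg.norm(candidates - q, axis=1)
        out[i] = int(np.argmin(d))
    return out


def brute_prune_relabel(coords, labels, min_size):
    """Two-stage pruning recomputation: unassign small clusters, NN-relabel, renumber."""
    labels = labels.copy()
    ids, sizes = np.unique(labels, return_counts=True)
    small = set(ids[sizes < min_size].tolist())
    survivors = [int(k) for k in ids if k not in small]
    doomed = np.array([l in small for l in labels])
    labeled_idx = np.nonzero(~doomed)[0]
    for i in np.nonzero(doomed)[0]:
        d = np.linalg.norm(coords[labeled_idx] - coords[i], axis=1)
        labels[i] = labels[labeled_idx[int(np.argmin(d))]]
    remap = {old: new for new, old in enumerate(sorted(survivors), start=1)}
    return np.array([remap[l] for l in labels], dtype=np.int64)


def check_poisson_disk(coords, seeds, d_min):
    """Return (min pairwise seed distance, max distance of any point to its nearest seed)."""
    sp = coords[seeds]
    k = len(sp)
    min_sep = np.inf
    for i in range(k):
        d = np.linalg.norm(sp[i + 1 :] - sp[i], axis=1)
        if d.size:
            min_sep = min(min_sep, d.min())
    cover = 0.0
    for p in coords:
        cover = max(cover, np.linalg.norm(sp - p, axis=1).min())
    return min_sep, cover


def brute_cell_max(r_norm, z_norm, values, cell, n_r, n_z):
    """Per-cell maximum by explicit scan over clusters."""
    grid = np.full((n_z, n_r), np.nan)
    for r, z, v in zip(r_norm, z_norm, values):
        if not np.isfinite(v):
            continue
        ir = min(int(r // cell), n_r - 1)
        iz = min(int(z // cell), n_z - 1)
        if not np.isfinite(grid[iz, ir]) or v > grid[iz, ir]:
            grid[iz, ir] = v
    return grid
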