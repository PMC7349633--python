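"""Independent brute-force oracles shared by the segmentation test suites."""

import numpy as np


def otsu_bruteforce(img, levels=256):
    """Exhaustive between-class variance scan over every threshold."""
    flat = np.asarray(img).ravel()
    best_t, best_var = None, -1.0
    for t in range(levels - 1):
        lo, hi = flat[flat <= t], flat[flat > t]
        if len(lo) == 0 or len(hi) == 0:
            var = 0.0
        else:
            w0, w1 = len(lo) / len(flat), len(hi) / len(flat)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def components_floodfill(mask, connectivity):
    """BFS flood fill from every foreground pixel; returns pixel lists."""
    mask = np.asarray(mask, bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    pr, pc = stack.pop()
                    comp.append((pr, pc))
                    for dr, dc in nbrs:
                        nr, nc = pr + dr, pc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps
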