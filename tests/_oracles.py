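"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — flood-fill patch
enumeration, pairwise adjacency counting, direct entropy sums — and
deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import deque


def flood_patches(codes, nodata=0, connectivity=8):
    """Enumerate single-class connected patches by breadth-first flood fill.

    Returns a list of (class_code, [cells...]) in discovery (row-major) order.
    """
    nr = len(codes)
    nc = len(codes[0])
    if connectivity == 4:
        nbr = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbr = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]
    seen = [[False] * nc for _ in range(nr)]
    patches = []
    for r in range(nr):
        for c in range(nc):
            if seen[r][c] or codes[r][c] == nodata:
                continue
            code = codes[r][c]
            cells = []
            queue = deque([(r, c)])
            seen[r][c] = True
            while queue:
                rr, cc = queue.popleft()
                cells.append((rr, cc))
                for dr, dc in nbr:
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc and not seen[r2][c2] \
                            and codes[r2][c2] == code:
                        seen[r2][c2] = True
                        queue.append((r2, c2))
            patches.append((code, cells))
    return patches


def like_adjacencies(codes, code, nodata=0):
    """Rook like-adjacency pairs of one class, each pair counted once."""
    nr, nc = len(codes), len(codes[0])
    g = 0
    for r in range(nr):
        for c in range(nc):
            if codes[r][c] != code:
                continue
            if c + 1 < nc and codes[r][c + 1] == code:
                g += 1
            if r + 1 < nr and codes[r + 1][c] == code:
                g += 1
    return g


def max_like_adjacencies(n_cells):
    n = int(math.isqrt(n_cells))
    m = n_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def class_metrics_oracle(codes, cell_area_ha, nodata=0, connectivity=8):
    """Per-class NP, MPS, LPI, PSCV, DIVISION, AI from first principles."""
    patches = flood_patches(codes, nodata, connectivity)
    total_cells = sum(1 for row in codes for v in row if v != nodata)
    total_area = total_cells * cell_area_ha
    by_class = {}
    for code, cells in patches:
        by_class.setdefault(code, []).append(len(cells))
    out = {}
    for code, sizes in sorted(by_class.items()):
        areas = [s * cell_area_ha for s in sizes]
        n_p = len(areas)
        mps = sum(areas) / n_p
        lpi = 100.0 * max(areas) / total_area
        mean = mps
        var = sum((a - mean) ** 2 for a in areas) / n_p  # population variance
        pscv = 100.0 * math.sqrt(var) / mps
        division = 1.0 - sum((a / total_area) ** 2 for a in areas)
        n_cells = sum(sizes)
        g = like_adjacencies(codes, code, nodata)
        max_g = max_like_adjacencies(n_cells)
        ai = 100.0 if max_g == 0 else 100.0 * g / max_g
        out[code] = {"NP": n_p, "MPS": mps, "LPI": lpi, "PSCV": pscv,
                     "DIVISION": division, "AI": ai}
    return out


def landscape_metrics_oracle(codes, cell_area_ha, nodata=0, connectivity=8):
    """Landscape-scale NP, MPS, LPI, PSCV, AI, SHDI from first principles."""
    patches = flood_patches(codes, nodata, connectivity)
    total_cells = sum(1 for row in codes for v in row if v != nodata)
    total_area = total_cells * cell_area_ha
    areas = [len(cells) * cell_area_ha for _, cells in patches]
    n_p = len(areas)
    mps = sum(areas) / n_p
    mean = mps
    var = sum((a - mean) ** 2 for a in areas) / n_p
    per_class = class_metrics_oracle(codes, cell_area_ha, nodata, connectivity)
    class_cells = {}
    for row in codes:
        for v in row:
            if v != nodata:
                class_cells[v] = class_cells.get(v, 0) + 1
    props = {k: n / total_cells for k, n in class_cells.items()}
    ai = sum(props[k] * per_class[k]["AI"] for k in per_class)
    shdi = -sum(p * math.log(p) for p in props.values())
    return {"NP": n_p, "MPS": mps, "LPI": 100.0 * max(areas) / total_area,
            "PSCV": 100.0 * math.sqrt(var) / mps, "AI": ai, "SHDI": shdi}


def cohen_kappa_oracle(counts):
    """Kappa from a confusion matrix by direct arithmetic."""
    total = sum(sum(row) for row in counts)
    k = len(counts)
    p0 = sum(counts[i][i] for i in range(k)) / total
    pc = sum(
        (sum(counts[i]) / total) * (sum(counts[j][i] for j in range(k)) / total)
        for i in range(k))
    return (p0 - pc) / (1 - pc)


def roc_oracle(pos_scores, neg_scores):
    """Probability a random positive outscores a random negative, ties half."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
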