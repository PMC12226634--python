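"""Independent brute-force metric oracles (pure-python set enumeration)."""

import math


def brute_overlap(a, b):
    universe = sorted(set(a.ravel().tolist()) | set(b.ravel().tolist()))
    dices, ious = [], []
    for c in universe:
        pa = {(i, j) for i in range(a.shape[0]) for j in range(a.shape[1]) if a[i, j] == c}
        pb = {(i, j) for i in range(b.shape[0]) for j in range(b.shape[1]) if b[i, j] == c}
        inter = len(pa & pb)
        dices.append(2 * inter / (len(pa) + len(pb)))
        ious.append(inter / len(pa | pb))
    return sum(dices) / len(dices), sum(ious) / len(ious)


def brute_boundary(a, c):
    H, W = a.shape
    out = set()
    for i in range(H):
        for j in range(W):
            if a[i, j] != c:
                continue
            if i in (0, H - 1) or j in (0, W - 1):
                out.add((i, j))
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if a[i + di, j + dj] != c:
                    out.add((i, j))
                    break
    return out


def brute_contour_distance(a, b):
    H, W = a.shape
    diag = math.hypot(H, W)
    classes = (set(a.ravel().tolist()) | set(b.ravel().tolist())) - {0}
    dists = []
    for c in sorted(classes):
        in_a = bool((a == c).any())
        in_b = bool((b == c).any())
        if not (in_a and in_b):
            dists.append(diag)
            continue
        ba, bb = brute_boundary(a, c), brute_boundary(b, c)
        d_ab = sum(min(math.dist(p, q) for q in bb) for p in ba) / len(ba)
        d_ba = sum(min(math.dist(p, q) for q in ba) for p in bb) / len(bb)
        dists.append((d_ab + d_ba) / 2)
    return sum(dists) / len(dists) if dists else float("nan")
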