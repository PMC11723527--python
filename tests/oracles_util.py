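"""Independent brute-force oracles shared by unit and acceptance tests.

Each function is a literal, unoptimized transcription of the corresponding
rule, written against plain Python data structures and kept independent of
the library implementations it checks.
"""

import numpy as np


def oracle_cluster_segments(psame: np.ndarray, p_min: float, ratio_max: float):
    """Step-by-step manual execution of the three-scenario greedy clustering.

    ``psame[a, b]`` is the mean same-domain probability between segments a
    and b. Returns clusters (lists of segment ids, ≥2 members) in creation
    order of surviving groups.
    """
    n = psame.shape[0]
    pairs = []
    for a in range(n):
        for b in range(a + 1, n):
            if psame[a, b] > p_min:
                pairs.append((a, b))
    pairs.sort(key=lambda ab: (-psame[ab[0], ab[1]], ab[0], ab[1]))

    groups = {}  # id -> member list
    where = {}  # segment -> group id
    counter = 0

    def within(members):
        vals = [psame[x, y] for i, x in enumerate(members) for y in members[i + 1 :]]
        return sum(vals) / len(vals) if vals else None

    def between(ms1, ms2):
        vals = [psame[x, y] for x in ms1 for y in ms2]
        return sum(vals) / len(vals)

    for a, b in pairs:
        ga, gb = where.get(a), where.get(b)
        if ga is None and gb is None:
            groups[counter] = [a, b]
            where[a] = where[b] = counter
            counter += 1
        elif ga is None or gb is None:
            free = a if ga is None else b
            gid = gb if ga is None else ga
            members = groups[gid]
            btw = between([free], members)
            wth = within(members)
            if wth is None:
                wth = btw
            if btw > 0 and wth / btw < ratio_max:
                members.append(free)
                where[free] = gid
            else:
                groups[counter] = [free]
                where[free] = counter
                counter += 1
        elif ga != gb:
            m1, m2 = groups[ga], groups[gb]
            p12 = between(m1, m2)
            p1 = within(m1)
            p2 = within(m2)
            p1 = p12 if p1 is None else p1
            p2 = p12 if p2 is None else p2
            if p1 < ratio_max * p12 or p2 < ratio_max * p12:
                for m in m2:
                    where[m] = ga
                m1.extend(m2)
                del groups[gb]
    return [sorted(m) for _, m in sorted(groups.items()) if len(m) >= 2]


def oracle_disorder(pae: np.ndarray, min_sep=20, cutoff=6.0, window=5, max_neighbors=10):
    """Double-loop PAE-neighbor count + tiled-window disorder rule."""
    L = pae.shape[0]
    counts = []
    for i in range(L):
        c = 0
        for j in range(L):
            if abs(i - j) >= min_sep and pae[i, j] < cutoff:
                c += 1
        counts.append(c)
    flagged = set()
    start = 0
    while start < L:
        win = list(range(start, min(start + window, L)))
        if sum(counts[i] for i in win) <= max_neighbors:
            flagged.update(i + 1 for i in win)
        start += window
    return flagged


def oracle_detection(ref_domains, pred_domains):
    """Set-arithmetic detection / split-count / best-IoU per reference."""
    out = []
    pred_union = set()
    for p in pred_domains:
        pred_union |= p
    for r in ref_domains:
        detected = len(r & pred_union) >= 0.5 * len(r)
        n_split = sum(1 for p in pred_domains if len(r & p) > 0.5 * len(r))
        best_iou, best_idx = 0.0, None
        for i, p in enumerate(pred_domains):
            if len(r & p) > 0 and (best_idx is None or len(r & p) > len(r & pred_domains[best_idx])):
                best_idx = i
        if best_idx is not None:
            p = pred_domains[best_idx]
            best_iou = len(r & p) / len(r | p)
        out.append((detected, n_split, best_iou, best_idx))
    return out


def oracle_correct_fraction(ref_domains, pred_domains, overlap=0.75):
    n = 0
    for r in ref_domains:
        for p in pred_domains:
            inter = len(r & p)
            if inter > overlap * len(r) and inter > overlap * len(p):
                n += 1
                break
    return n / len(ref_domains)
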