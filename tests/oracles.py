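"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python dynamic
programming for alignment, an exhaustive greedy cover, and direct
transcriptions of the similarity formulas. They follow the same documented
conventions (gap cost open + k*extend, traceback priority diagonal > up >
left with gaps closing early, first-maximal start cell in row-major order)
so agreement is exact.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_align(q: str, t: str, score, gap_open: int = 11, gap_extend: int = 1):
    """Quadratic-space affine Smith-Waterman returning
    (score, n_identical, n_aligned_cols, q_start, q_end, t_start, t_end),
    spans 1-based inclusive, zeros when there is no positive alignment."""
    m, n = len(q), len(t)
    go = gap_open + gap_extend
    ge = gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + score(q[i - 1], t[j - 1]), E[i][j], F[i][j]
            )
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    i, j = bi, bj
    state = "H"
    n_id = n_cols = 0
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            if H[i][j] == H[i - 1][j - 1] + score(q[i - 1], t[j - 1]):
                n_cols += 1
                if q[i - 1] == t[j - 1]:
                    n_id += 1
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            if F[i][j] == H[i - 1][j] - go:
                state = "H"
            i -= 1
        else:
            if E[i][j] == H[i][j - 1] - go:
                state = "H"
            j -= 1
    return best, n_id, n_cols, i + 1, bi, j + 1, bj


def sw_align_canonical(q_acc, q_res, t_acc, t_res, score,
                       gap_open: int = 11, gap_extend: int = 1):
    """Canonical-orientation wrapper: the sequence with the smaller
    (residues, accession) pair is the DP query; fields are reported in the
    caller's (q, t) frame. Mirrors the documented symmetry convention."""
    if (q_res, q_acc) > (t_res, t_acc):
        s, n_id, n_cols, ts, te, qs, qe = sw_align(
            t_res, q_res, score, gap_open, gap_extend
        )
    else:
        s, n_id, n_cols, qs, qe, ts, te = sw_align(
            q_res, t_res, score, gap_open, gap_extend
        )
    return s, n_id, n_cols, qs, qe, ts, te


def greedy_cover(adjacency: dict, lengths: dict | None = None) -> list:
    """Exhaustive greedy set cover over an explicit graph: at each step scan
    every uncovered vertex, compute its uncovered closed neighbourhood, and
    take the largest (ties: longer sequence, then smaller id). Returns a
    sorted list of (representative, frozenset(members))."""
    lengths = lengths or {}
    uncovered = set(adjacency)
    clusters = []
    while uncovered:
        candidates = []
        for v in uncovered:
            covered = {v} | {u for u in adjacency[v] if u in uncovered}
            candidates.append((-len(covered), -lengths.get(v, 0), v, covered))
        candidates.sort(key=lambda c: c[:3])
        _, _, v, covered = candidates[0]
        clusters.append((v, frozenset(covered)))
        uncovered -= covered
    return sorted(clusters)


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def go_ancestors(term: str, parents: dict) -> set:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents[t]:
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def go_sim(a: str, b: str, parents: dict, p: dict) -> float:
    import math

    common = go_ancestors(a, parents) & go_ancestors(b, parents)
    if not common:
        return 0.0
    lca = sorted(common, key=lambda t: (p[t], t))[0]
    denom = math.log(p[a]) + math.log(p[b])
    if denom == 0.0:
        return 1.0 if a == b else 0.0
    return 2.0 * math.log(p[lca]) / denom


def go_set_sim(ax: set, ay: set, parents: dict, p: dict) -> float | None:
    if not ax or not ay:
        return None
    total = 0.0
    for a in ax:
        total += max(go_sim(a, b, parents, p) for b in ay)
    for b in ay:
        total += max(go_sim(a, b, parents, p) for a in ax)
    return total / (len(ax) + len(ay))


def dice(kx: set, ky: set) -> float | None:
    if not kx and not ky:
        return None
    if not kx or not ky:
        return 0.0
    return 2.0 * len(kx & ky) / (len(kx) + len(ky))
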