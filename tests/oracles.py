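"""Independent oracles used to check plastocmp implementations.

These deliberately share no code with the package's computational paths:
the affine-gap aligner oracle is a straight Gotoh recursion, the parsimony
oracle enumerates internal-node state assignments, and the variant oracle
is a plain column scan.
"""

from __future__ import annotations

from itertools import product

import numpy as np

NEG = -(10**9)


def gotoh_score(a: str, b: str, match=1, mismatch=-1, gap_open=-4, gap_extend=-1) -> int:
    """Optimal global affine-gap alignment score; a gap of length L scores
    gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # first gap column
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    M = np.full(m + 1, NEG, dtype=np.int64)
    X = np.full(m + 1, NEG, dtype=np.int64)  # gap in b (consuming a)
    Y = np.full(m + 1, NEG, dtype=np.int64)  # gap in a (consuming b)
    M[0] = 0
    if m:
        Y[1:] = gap_open + gap_extend * np.arange(1, m + 1)
    for i in range(1, n + 1):
        Mp, Xp, Yp = M, X, Y
        M = np.full(m + 1, NEG, dtype=np.int64)
        X = np.empty(m + 1, dtype=np.int64)
        Y = np.full(m + 1, NEG, dtype=np.int64)
        X = np.maximum(np.maximum(Mp, Yp) + first, Xp + gap_extend)
        s = np.where(bb == ord(a[i - 1]), match, mismatch)
        best_prev = np.maximum(np.maximum(Mp[:-1], Xp[:-1]), Yp[:-1])
        M[1:] = best_prev + s
        # Y via running max: opening at column k+1 and extending to j costs
        # gap_open + (j - k) * gap_extend
        base = np.maximum(M, X) - gap_extend * np.arange(m + 1)
        run = np.maximum.accumulate(base[:-1])
        Y[1:] = run + gap_open + gap_extend * np.arange(1, m + 1)
    return int(max(M[m], X[m], Y[m]))


def score_gapped_rows(ra: str, rb: str, match=1, mismatch=-1, gap_open=-4, gap_extend=-1) -> int:
    """Score an explicit gapped alignment (independent re-implementation)."""
    s = 0
    prev = None
    for x, y in zip(ra, rb):
        if x == "-":
            s += gap_extend + (gap_open if prev != "a" else 0)
            prev = "a"
        elif y == "-":
            s += gap_extend + (gap_open if prev != "b" else 0)
            prev = "b"
        else:
            s += match if x == y else mismatch
            prev = None
    return s


# ---------------------------------------------------------------------------
# Parsimony


def all_unrooted_tuples(n: int):
    """Every unrooted topology on taxa 0..n-1 as a nested tuple hanging off
    leaf 0."""

    def insertions(node, x):
        yield (node, x)
        if isinstance(node, tuple):
            for l2 in insertions(node[0], x):
                yield (l2, node[1])
            for r2 in insertions(node[1], x):
                yield (node[0], r2)

    def gen(sub, nxt):
        if nxt == n:
            yield sub
            return
        for cand in insertions(sub, nxt):
            yield from gen(cand, nxt + 1)

    yield from gen((1, 2), 3)


def tuple_to_newick(sub, labels) -> str:
    def w(node):
        if isinstance(node, int):
            return labels[node]
        return f"({w(node[0])},{w(node[1])})"

    return f"({labels[0]},{w(sub[0])},{w(sub[1])});" if isinstance(sub, tuple) else ""


def brute_force_fitch(sub, leaf_state_sets: list[set]) -> int:
    """Minimum changes for one site by enumerating all internal-node state
    assignments.  ``leaf_state_sets[i]`` is the allowed state set of leaf i
    (full set for missing data)."""
    edges = []
    internal = []

    def build(node):
        if isinstance(node, int):
            return ("leaf", node)
        me = ("int", len(internal))
        internal.append(me)
        a = build(node[0])
        b = build(node[1])
        edges.append((me, a))
        edges.append((me, b))
        return me

    top = build(sub)
    edges.append((("leaf", 0), top))
    states = "ACGT"
    best = None
    for assign in product(range(4), repeat=len(internal)):
        # leaves choose their cheapest compatible state given neighbours;
        # simpler: enumerate leaf states too via per-edge minimisation:
        # cost(leaf edge) = 0 if internal state in leaf set else 1
        cost = 0
        for u, v in edges:
            su = assign[u[1]] if u[0] == "int" else None
            sv = assign[v[1]] if v[0] == "int" else None
            if u[0] == "int" and v[0] == "int":
                cost += int(su != sv)
            elif v[0] == "leaf":
                cost += int(states[su] not in leaf_state_sets[v[1]])
            else:  # u leaf (root edge)
                cost += int(states[sv] not in leaf_state_sets[u[1]])
        if best is None or cost < best:
            best = cost
    return best


def brute_force_fitch_matrix(sub, rows: list[str]) -> int:
    """Brute-force tree length over all sites of aligned rows (gap/N are
    missing)."""
    full = set("ACGT")
    total = 0
    for col in zip(*rows):
        sets = [full if c in "-N?" else {c} for c in col]
        if len({frozenset(s) for s in sets}) == 1 and len(sets[0]) == 1:
            continue
        total += brute_force_fitch(sub, sets)
    return total


# ---------------------------------------------------------------------------
# Variants


def column_scan_variants(ref_row: str, qry_row: str):
    """Plain-python event scan: returns list of (type, ref_pos, ref, alt)."""
    events = []
    refpos = 0
    i = 0
    n = len(ref_row)
    while i < n:
        r, q = ref_row[i], qry_row[i]
        if r != "-":
            refpos_here = refpos + 1
        if r == "-" and q != "-":  # insertion run
            j = i
            alt = ""
            while j < n and ref_row[j] == "-":
                alt += qry_row[j]
                j += 1
            if set(alt) != {"N"}:
                events.append(("insertion", refpos, "", alt))
            i = j
            continue
        if q == "-" and r != "-":  # deletion run
            j = i
            ref = ""
            while j < n and qry_row[j] == "-" and ref_row[j] != "-":
                ref += ref_row[j]
                j += 1
            if set(ref) != {"N"}:
                events.append(("deletion", refpos + 1, ref, ""))
            refpos += len(ref)
            i = j
            continue
        if r != q and "N" not in (r, q):  # substitution run
            j = i
            ref = alt = ""
            while (
                j < n
                and ref_row[j] != "-"
                and qry_row[j] != "-"
                and ref_row[j] != qry_row[j]
                and "N" not in (ref_row[j], qry_row[j])
            ):
                ref += ref_row[j]
                alt += qry_row[j]
                j += 1
            t = "SNP" if len(ref) == 1 else "MNV"
            events.append((t, refpos + 1, ref, alt))
            refpos += len(ref)
            i = j
            continue
        refpos += 1
        i += 1
    return events


def count_differences(ref_row: str, qry_row: str) -> int:
    return sum(
        1
        for r, q in zip(ref_row, qry_row)
        if r != q and r != "N" and q != "N"
    )
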