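"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops, set
algebra, hand-rolled ranking) and deliberately shares no code with circkit.
"""

from __future__ import annotations

import itertools

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def frequency_bruteforce(counts, min_reads):
    """Per-column count of cells >= min_reads, by explicit double loop."""
    n_rows = len(counts)
    n_cols = len(counts[0]) if n_rows else 0
    out = []
    for j in range(n_cols):
        c = 0
        for i in range(n_rows):
            if counts[i][j] >= min_reads:
                c += 1
        out.append(c)
    return out


def abundance_ranks_bruteforce(abundances, names):
    """Descending ranks with lexicographic tie-break, by sort-and-slice."""
    order = sorted(range(len(names)), key=lambda i: (-abundances[i], names[i]))
    ranks = [0] * len(names)
    for rank, i in enumerate(order, 1):
        ranks[i] = rank
    return ranks


def spearman_bruteforce(x, y):
    """Rank-then-Pearson with average ranks for ties."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def venn_counts_bruteforce(source_sets):
    """Exact-region counts from set algebra over {source: set of keys}."""
    sources = sorted(source_sets)
    universe = set().union(*source_sets.values())
    counts = {}
    for r in range(1, len(sources) + 1):
        for combo in itertools.combinations(sources, r):
            inside = set(universe)
            for s in combo:
                inside &= source_sets[s]
            for s in sources:
                if s not in combo:
                    inside -= source_sets[s]
            counts[frozenset(combo)] = len(inside)
    return counts


def pcr_products_bruteforce(fwd, rev, template, circular, max_len):
    """All products by O(n^2) enumeration of exact primer sites."""
    search = template + template if circular else template
    L = len(template)
    primers = {"forward": fwd, "reverse": rev}
    plus_sites, minus_sites = [], []
    for lab, p in primers.items():
        for i in range(len(search) - len(p) + 1):
            if search[i:i + len(p)] == p:
                plus_sites.append((lab, i, len(p)))
            if search[i:i + len(p)] == revcomp(p):
                minus_sites.append((lab, i, len(p)))
    products = set()
    for lab_f, i, lf in plus_sites:
        if circular and i >= L:
            continue
        for lab_r, j, lr in minus_sites:
            end = j + lr
            length = end - i
            if length < max(lf, lr) or length > max_len:
                continue
            if circular and length > L:
                continue
            products.add((i % L if circular else i,
                          end % L if circular else end, length))
    return products


def concordance_bruteforce(pairs, mode):
    """Concordance from explicit counting over (call_a, call_b) pairs."""
    npp = nnn = nd = 0
    for a, b in pairs:
        if a not in ("positive", "negative") or b not in ("positive", "negative"):
            continue
        if a == b == "positive":
            npp += 1
        elif a == b == "negative":
            nnn += 1
        else:
            nd += 1
    denom = npp + nnn + (2 * nd if mode == "literal" else nd)
    return None if denom == 0 else (npp + nnn) / denom, npp + nnn + nd


def molar_mass_bruteforce(seq, topology, end_extra=None):
    """Per-base dictionary sum; linear adds water + optional end-group extra."""
    masses = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}
    total = 0.0
    for b in seq:
        total += masses[b]
    if topology == "linear":
        total += 18.02 + (end_extra or 0.0)
    return total


def best_split_bruteforce(values):
    """Exhaustive 1-D two-cluster split minimizing within-cluster SS."""
    xs = sorted(values)
    best = None
    best_cut = None
    for i in range(1, len(xs)):
        lo, hi = xs[:i], xs[i:]
        mlo = sum(lo) / len(lo)
        mhi = sum(hi) / len(hi)
        wss = sum((v - mlo) ** 2 for v in lo) + sum((v - mhi) ** 2 for v in hi)
        if best is None or wss < best - 1e-12:
            best, best_cut = wss, (lo[-1] + hi[0]) / 2.0
    return best_cut
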