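"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: plain dict/loop
group-mean arithmetic for the ANOVA sums of squares, an exhaustive
suffix/prefix scan for read merging, and per-position tallies for group
certainty.
"""

from collections import Counter, defaultdict

import numpy as np


def brute_force_anova_ss(table, factor_names, include_donor=True,
                         response="response"):
    """Term sums of squares from explicit group-mean loops (no pandas groupby)."""
    rows = table.to_dict("records")
    y = [r[response] for r in rows]
    n = len(y)
    grand = sum(y) / n

    def group_mean(keyfn):
        acc = defaultdict(list)
        for r in rows:
            acc[keyfn(r)].append(r[response])
        return {k: sum(v) / len(v) for k, v in acc.items()}, \
               {k: len(v) for k, v in acc.items()}

    ss = {}
    if include_donor and "donor" in table.columns and table["donor"].nunique() > 1:
        m, c = group_mean(lambda r: r["donor"])
        ss["donor"] = sum(c[k] * (m[k] - grand) ** 2 for k in m)
    mains = {}
    for f in factor_names:
        m, c = group_mean(lambda r, f=f: r[f])
        mains[f] = m
        ss[f] = sum(c[k] * (m[k] - grand) ** 2 for k in m)
    for i, fa in enumerate(factor_names):
        for fb in factor_names[i + 1:]:
            m, c = group_mean(lambda r, fa=fa, fb=fb: (r[fa], r[fb]))
            ss[f"{fa}:{fb}"] = sum(
                c[k] * (m[k] - mains[fa][k[0]] - mains[fb][k[1]] + grand) ** 2
                for k in m
            )
    ss["total"] = sum((v - grand) ** 2 for v in y)
    ss["residual"] = ss["total"] - sum(v for k, v in ss.items() if k != "total")
    return ss


def longest_exact_overlap(fwd: str, rev_rc: str) -> int:
    """Exhaustive scan for the longest suffix(fwd) == prefix(rev_rc) match."""
    best = 0
    for l in range(1, min(len(fwd), len(rev_rc)) + 1):
        if fwd[-l:] == rev_rc[:l]:
            best = l
    return best


def group_certainty(seqs: list[str]) -> float:
    """Mean per-position plurality fraction across equal-length members."""
    assert len({len(s) for s in seqs}) == 1
    fracs = []
    for col in zip(*seqs):
        fracs.append(Counter(col).most_common(1)[0][1] / len(seqs))
    return float(np.mean(fracs))


def identity_percent(a: str, b: str) -> float:
    """Global identity of two equal-length strings (hamming-based)."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
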