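"""Independent brute-force oracles, deliberately naive.

These re-derive the quantities under test from their definitions (triple
loops over residue combinations, all-pairs concordance counts) and must
stay independent of the library's optimized code paths.
"""

import math
from collections import Counter

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def naive_pair_mi(col1, col2, tau=None, r=None, base=math.e):
    """MI by direct summation over residue combinations.

    ``tau``/``r`` apply the per-term filters; both ``None`` means the plain
    textbook quantity.  Species with a gap or non-standard residue at either
    column are excluded before counting.
    """
    pairs = [(a, b) for a, b in zip(col1, col2) if a in STANDARD_AA and b in STANDARD_AA]
    n = len(pairs)
    if n == 0:
        return 0.0
    joint = Counter(pairs)
    cx = Counter(a for a, _ in pairs)
    cy = Counter(b for _, b in pairs)
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        px = cx[x] / n
        py = cy[y] / n
        if tau is not None:
            if px < tau or py < tau:
                continue
            if c * n < (1.0 + r / 100.0) * cx[x] * cy[y]:
                continue
        mi += pxy * math.log(pxy / (px * py), base)
    return mi


def bruteforce_auc(known, unknown):
    """Proportion of concordant (known > unknown) pairs, half credit for ties."""
    wins = 0.0
    for k in known:
        for u in unknown:
            if k > u:
                wins += 1.0
            elif k == u:
                wins += 0.5
    return wins / (len(known) * len(unknown))
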