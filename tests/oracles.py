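"""Independent brute-force oracles used to cross-check the package.

These deliberately use different machinery from the implementation
(regexes instead of expansion-set membership, all-pairs loops instead of
sorted sweeps, closed forms instead of library calls).
"""

from __future__ import annotations

import math
import re

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern))


def regex_scan(sequence: str, pattern: str) -> set[tuple[int, int, str]]:
    """All overlapping matches (start, end, strand) with the same emission
    rule as the scanner: a window matching both strands reports '+'."""
    seq = sequence.upper()
    k = len(pattern)
    fwd = iupac_regex(pattern)
    rev = iupac_regex(rc(pattern))
    out: set[tuple[int, int, str]] = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if fwd.fullmatch(window):
            out.add((i, i + k, "+"))
        elif rev.fullmatch(window):
            out.add((i, i + k, "-"))
    return out


def allpairs_nearest(features_a, features_b, exclude_self=False):
    """All-pairs closest-edge distances (inf when no candidate)."""
    out = []
    for chrom_a, sa, ea in features_a:
        best = math.inf
        skipped = False
        for chrom_b, sb, eb in features_b:
            if chrom_a != chrom_b:
                continue
            if exclude_self and not skipped and (sb, eb) == (sa, ea):
                skipped = True
                continue
            if sa < eb and sb < ea:
                gap = 0
            elif sb >= ea:
                gap = sb - ea
            else:
                gap = sa - eb
            best = min(best, gap)
        out.append(best)
    return out


def chi2_2x2_closed_form(a, b, c, d):
    """Textbook Pearson chi-squared on a 2x2 table, no correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact by direct hypergeometric enumeration
    (log-factorial arithmetic, no scipy)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lf = [0.0] * (n + 1)
    for i in range(2, n + 1):
        lf[i] = lf[i - 1] + math.log(i)

    def logp(x):
        y = row1 - x
        z = col1 - x
        w = n - row1 - z
        if min(y, z, w) < 0:
            return -math.inf
        return (
            lf[row1] + lf[n - row1] + lf[col1] + lf[n - col1]
            - lf[n] - lf[x] - lf[y] - lf[z] - lf[w]
        )

    observed = logp(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        lp = logp(x)
        if lp <= observed + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)
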