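"""Independent brute-force oracles, deliberately coded without reference
to the package implementation.

``classify_by_rule_text`` transliterates the published calling rule
sentence by sentence over explicit per-donor (KD, NT) aggregate values:

  reduced:   a reduction in all replicate experiments, ratio <= 0.5 in at
             least three of them (a protein dropping to undetectable in
             KD while present in NT counts as such a reduction), and
             undetectable in at most two replicates;
  increased: an increase in all replicate experiments and ratio >= 1.2
             in at least three; a donor where the protein is lost in KD
             contradicts "an increase in all";
  a donor with the protein absent from the NT control gives no usable
  ratio and is disregarded; proteins detected in fewer than three
  replicates are excluded.

``hypergeom_tail_exact`` sums the hypergeometric mass function with
exact rational arithmetic.
"""

from fractions import Fraction
from math import comb


def classify_by_rule_text(donors, min_detected=3):
    """donors: iterable of (kd_value, nt_value) aggregates, 0 = undetected."""
    donors = list(donors)
    if sum(1 for kd, nt in donors if kd > 0 or nt > 0) < min_detected:
        return "INELIGIBLE"

    informative = reductions = increases = 0
    le_half = ge_one_two = undetectable = 0
    for kd, nt in donors:
        if nt > 0 and kd > 0:
            informative += 1
            r = kd / nt
            if r < 1:
                reductions += 1
            if r > 1:
                increases += 1
            if r <= 0.5:
                le_half += 1
            if r >= 1.2:
                ge_one_two += 1
        elif nt > 0 and kd == 0:
            # reduced to undetectable: a reduction, and it counts toward
            # the <=0.5 events, but at most two such replicates allowed
            informative += 1
            reductions += 1
            undetectable += 1
        # nt == 0: no usable ratio, disregarded

    if (
        informative > 0
        and reductions == informative
        and le_half + undetectable >= 3
        and undetectable <= 2
    ):
        return "DOWN"
    if informative > 0 and increases == informative and ge_one_two >= 3:
        return "UP"
    return "NS"


def hypergeom_tail_exact(k, K, n, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational sum."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc
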