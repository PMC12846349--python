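"""Independent reference implementations used only as test oracles.

Each oracle deliberately takes a different computational route from the
library code it checks: exhaustive recursion instead of dynamic
programming, exact rational arithmetic instead of log-gamma, Biopython
translation instead of codon scanning.
"""

from math import comb

from Bio.Seq import Seq


def brute_force_alignment_score(a: str, b: str, match: float, mismatch: float,
                                gap: float) -> float:
    """Maximum score over all global alignments by plain recursion
    (enumerates every alignment path; exponential, small inputs only)."""
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive same-margin enumeration in exact
    integer arithmetic (all same-denominator hypergeometric weights;
    point-probability rule with the conventional 1 + 1e-7 tie tolerance)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)]
    w_obs = weights[a - k_min]
    total = sum(w for w in weights if w * 10**7 <= w_obs * (10**7 + 1))
    return min(1.0, total / comb(n, c1))


def minus1_readthrough(cds_plus_context: str, orf_len: int, motif: str,
                       window_nt: int = 60) -> dict:
    """Six-frame-translation style oracle for the -1 PRF test.

    Finds the in-window motif occurrence closest to the stop, recodes the
    message by shifting back one nucleotide after the motif, translates the
    -1 tail with Biopython and reads off the first stop.
    Returns {found, premature, extension_nt}.
    """
    L = orf_len
    window_start = max(0, L - window_nt)
    occurrences = []
    p = cds_plus_context.find(motif, window_start)
    while p != -1 and p + len(motif) <= L:
        occurrences.append(p)
        p = cds_plus_context.find(motif, p + 1)
    if not occurrences:
        return {"found": False, "premature": False, "extension_nt": 0}
    m = occurrences[-1]  # closest to the stop
    slip = m + len(motif) - 1
    tail = cds_plus_context[slip:]
    tail = tail[:len(tail) - len(tail) % 3]
    protein = str(Seq(tail).translate())
    star = protein.find("*")
    if star == -1:
        return {"found": True, "premature": False, "extension_nt": 0,
                "unterminated": True}
    stop_start = slip + 3 * star
    if stop_start < L - 3:
        return {"found": True, "premature": True, "extension_nt": 0}
    return {"found": True, "premature": False,
            "extension_nt": stop_start + 3 - (L - 3)}
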