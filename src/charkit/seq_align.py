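"""Self-contained global alignment and conservation statistics.

A Needleman-Wunsch pairwise aligner with linear gap penalties and fully
deterministic traceback, a center-star progressive multiple aligner built
on it, and the conservation summaries (minimum pairwise identity,
invariant-site fraction) used to characterize allele sets of a locus.

The aligner is written out rather than delegated so that its tie-breaking
is pinned (prefer diagonal, then consuming the first sequence, then the
second) and the multiple alignment is reproducible without external
binaries. It is deliberately simple: linear gaps, no affine extension.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .errors import EmptyInputError, UndefinedValueError

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0  # linear, per gapped column

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("require match > mismatch")
        if self.gap >= 0:
            raise ValueError("require gap < 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class Alignment:
    """Gapped rows of equal length; degapping row i recovers input i exactly."""

    rows: list[str]
    ids: list[str]
    score: float | None = None  # pairwise only

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass
class ConservationProfile:
    n_columns: int
    invariant_fraction: float
    min_pairwise_identity: float
    column_frequencies: pd.DataFrame  # columns x symbols


def nw_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME,
             ids: tuple[str, str] = ("a", "b")) -> Alignment:
    """Optimal global alignment under a linear gap penalty.

    Traceback ties are broken deterministically: diagonal first, then the
    move consuming a character of ``a`` (gap in ``b``), then the move
    consuming ``b``.
    """
    if not a or not b:
        raise EmptyInputError("nw_align requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    g = scheme.gap
    # DP score matrix, (n+1) x (m+1)
    prev = [j * g for j in range(m + 1)]
    score_rows = [prev]
    for i in range(1, n + 1):
        cur = [i * g] + [0.0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scheme.match if ai == b[j - 1] else scheme.mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + g, cur[j - 1] + g)
        score_rows.append(cur)
        prev = cur
    # deterministic traceback
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        here = score_rows[i][j]
        if i > 0 and j > 0:
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            if here == score_rows[i - 1][j - 1] + s:
                ra.append(a[i - 1]); rb.append(b[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and here == score_rows[i - 1][j] + g:
            ra.append(a[i - 1]); rb.append(GAP)
            i -= 1
            continue
        ra.append(GAP); rb.append(b[j - 1])
        j -= 1
    return Alignment(rows=["".join(reversed(ra)), "".join(reversed(rb))],
                     ids=list(ids), score=score_rows[n][m])


def _merge_into_master(master_center: str, new_center: str,
                       other_rows: list[str]) -> tuple[str, list[str], str]:
    """Merge a pairwise alignment (new_center vs a new row) into the master
    gapped center, inserting gaps on either side ("once a gap, always a gap").

    Returns (merged_center, padded_other_rows_gaps_to_insert marker) --
    concretely the merged center, the existing rows re-gapped, and the new
    row re-gapped; other_rows[-1] is the incoming row.
    """
    i = j = 0
    cols = []  # per merged column: (source, master index or None, pairwise index or None)
    while i < len(master_center) or j < len(new_center):
        ci = master_center[i] if i < len(master_center) else None
        cj = new_center[j] if j < len(new_center) else None
        if ci == GAP and cj == GAP:
            cols.append(("both", i, j)); i += 1; j += 1
        elif ci == GAP:
            cols.append(("master", i, None)); i += 1
        elif cj == GAP:
            cols.append(("new", None, j)); j += 1
        elif ci is None:
            cols.append(("new", None, j)); j += 1
        elif cj is None:
            cols.append(("master", i, None)); i += 1
        else:  # both residues (identical center characters by construction)
            cols.append(("both", i, j)); i += 1; j += 1
    merged_center = "".join(
        master_center[i] if src != "new" else new_center[j]
        for src, i, j in cols)
    old_regapped = []
    for row in other_rows[:-1]:
        old_regapped.append("".join(
            row[i] if i is not None else GAP for src, i, j in cols))
    new_row = other_rows[-1]
    new_regapped = "".join(
        new_row[j] if j is not None else GAP for src, i, j in cols)
    return merged_center, old_regapped, new_regapped


def star_msa(seqs: list[str], scheme: ScoringScheme = DEFAULT_SCHEME,
             ids: list[str] | None = None) -> Alignment:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing its summed pairwise alignment
    score against all others (ties broken by input order); the remaining
    sequences are merged one at a time, propagating gaps.
    """
    if len(seqs) < 2:
        raise ValueError("star_msa requires at least two sequences")
    seqs = [s.upper() for s in seqs]
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    k = len(seqs)
    pair_score: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        pair_score[(i, j)] = nw_align(seqs[i], seqs[j], scheme).score
    sums = [sum(pair_score[tuple(sorted((i, j)))] for j in range(k) if j != i)
            for i in range(k)]
    center = max(range(k), key=lambda i: (sums[i], -i))

    master_center = seqs[center]
    others_order = [i for i in range(k) if i != center]
    rows: list[str] = []
    for idx in others_order:
        aln = nw_align(seqs[center], seqs[idx], scheme)
        master_center, rows, new_row = _merge_into_master(
            master_center, aln.rows[0], rows + [aln.rows[1]])
        rows.append(new_row)
    all_rows = [None] * k
    all_rows[center] = master_center
    for pos, idx in enumerate(others_order):
        all_rows[idx] = rows[pos]
    return Alignment(rows=all_rows, ids=list(ids), score=None)


def pairwise_identity(a_row: str, b_row: str) -> float:
    """Percent identity of two gapped rows.

    100 * matches / (columns where at least one row is non-gap); columns
    gapped in both rows are excluded from the denominator.
    """
    if len(a_row) != len(b_row):
        raise ValueError("rows differ in length")
    scored = matches = 0
    for x, y in zip(a_row.upper(), b_row.upper()):
        if x == GAP and y == GAP:
            continue
        scored += 1
        if x == y and x != GAP:
            matches += 1
    if scored == 0:
        raise UndefinedValueError("identity undefined for an all-gap pair")
    return 100.0 * matches / scored


def conservation_profile(msa: Alignment) -> ConservationProfile:
    """Column-wise conservation summary of a multiple alignment.

    An invariant column has a single non-gap symbol and no gaps across all
    rows; min_pairwise_identity is the minimum of pairwise_identity over
    all row pairs.
    """
    if len(msa.rows) < 2:
        raise ValueError("conservation profile requires >= 2 rows")
    ncol = msa.n_columns
    symbols = sorted({c for row in msa.rows for c in row})
    freq = {sym: [0] * ncol for sym in symbols}
    invariant = 0
    for c in range(ncol):
        col = [row[c] for row in msa.rows]
        for ch in col:
            freq[ch][c] += 1
        if GAP not in col and len(set(col)) == 1:
            invariant += 1
    min_id = min(pairwise_identity(a, b)
                 for a, b in itertools.combinations(msa.rows, 2))
    table = pd.DataFrame(freq, index=pd.RangeIndex(ncol, name="column"))
    return ConservationProfile(
        n_columns=ncol,
        invariant_fraction=invariant / ncol if ncol else 0.0,
        min_pairwise_identity=min_id,
        column_frequencies=table,
    )


def write_gapped_fasta(msa: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def read_gapped_fasta(path: str) -> Alignment:
    ids, rows, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur)); cur = []
                ids.append(line[1:].split()[0])
            elif line:
                cur.append(line)
    if cur:
        rows.append("".join(cur))
    if not rows:
        raise EmptyInputError(f"no sequences in {path!r}")
    return Alignment(rows=rows, ids=ids)
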