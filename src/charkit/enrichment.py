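"""Defense-system enrichment screen and host-range summarization.

Given a strain x system presence/absence table with a two-level grouping
(e.g. serogroup O11 vs non-O11, or phage-resistant vs sensitive), each
system is tested for association with the focal group by a two-sided
Fisher exact test assembled from the hypergeometric distribution, with
Benjamini-Hochberg control of the false discovery rate across systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import EmptyInputError

# relative tolerance of the point-probability two-sided rule: tables whose
# probability is within (1 + 1e-7) of the observed one are counted as "as
# extreme", guarding against ties lost to floating point
_POINT_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class Contingency2x2:
    """Counts with rows = focal group yes/no, columns = system present/absent."""

    a: int  # focal & present
    b: int  # focal & absent
    c: int  # other & present
    d: int  # other & absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    def odds_ratio(self) -> float:
        ad = self.a * self.d
        bc = self.b * self.c
        if bc == 0:
            return math.inf if ad > 0 else math.nan
        return ad / bc


@dataclass
class EnrichmentResult:
    system: str
    table: Contingency2x2
    odds_ratio: float
    p: float
    q: float
    significant: bool


def _hypergeom_logpmf(k: np.ndarray, total: int, n_present: int,
                      n_focal: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(total, n_present, n_focal)."""
    k = np.asarray(k, dtype=float)
    return (gammaln(n_present + 1) - gammaln(k + 1) - gammaln(n_present - k + 1)
            + gammaln(total - n_present + 1)
            - gammaln(n_focal - k + 1)
            - gammaln(total - n_present - (n_focal - k) + 1)
            - (gammaln(total + 1) - gammaln(n_focal + 1)
               - gammaln(total - n_focal + 1)))


def fisher_exact(table: Contingency2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    With margins fixed, the count ``a`` follows a hypergeometric
    distribution; the two-sided p-value is the sum of probabilities of all
    same-margin tables whose point probability does not exceed that of the
    observed table (up to a 1e-7 relative tolerance). Returns
    (p, odds ratio); the odds ratio is the sample cross-product ratio,
    infinite when b*c = 0 and a*d > 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    total = a + b + c + d
    n_focal = a + b
    n_present = a + c
    k_min = max(0, n_focal + n_present - total)
    k_max = min(n_focal, n_present)
    support = np.arange(k_min, k_max + 1)
    logpmf = _hypergeom_logpmf(support, total, n_present, n_focal)
    pmf = np.exp(logpmf)
    observed = pmf[a - k_min]
    p = float(pmf[pmf <= observed * _POINT_TOL].sum())
    return min(1.0, p), table.odds_ratio()


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1, returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


@dataclass
class PresenceAbsenceTable:
    """Strain x defense-system boolean matrix with a per-strain group label."""

    strain_ids: list[str]
    group: list[str]
    systems: list[str]
    matrix: np.ndarray  # shape (n_strains, n_systems), bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.strain_ids), len(self.systems)):
            raise ValueError("matrix shape does not match id lists")
        if len(self.group) != len(self.strain_ids):
            raise ValueError("group labels length mismatch")
        if len(self.systems) == 0:
            raise EmptyInputError("presence/absence table has no systems")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       group_col: str = "group") -> "PresenceAbsenceTable":
        """Strains as rows (index = strain id), systems as 0/1 columns plus
        a group column -- the shape produced by DefenseFinder post-processing."""
        if group_col not in df.columns:
            raise KeyError(f"no column {group_col!r} in table")
        systems = [c for c in df.columns if c != group_col]
        return cls(strain_ids=[str(i) for i in df.index],
                   group=[str(g) for g in df[group_col]],
                   systems=systems,
                   matrix=df[systems].to_numpy() != 0)

    def to_dataframe(self, group_col: str = "group") -> pd.DataFrame:
        out = pd.DataFrame(self.matrix.astype(int), index=self.strain_ids,
                           columns=self.systems)
        out.insert(0, group_col, self.group)
        return out


def enrichment_screen(table: PresenceAbsenceTable, alpha: float = 0.05,
                      focal: str | None = None) -> list[EnrichmentResult]:
    """Per-system Fisher tests of association with the focal group, with
    BH correction across all systems of the screen.

    ``focal`` names the group level whose enrichment is tested; by default
    the lexicographically first of the two levels.
    """
    levels = sorted(set(table.group))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if focal is None:
        focal = levels[0]
    if focal not in levels:
        raise ValueError(f"focal level {focal!r} not among {levels}")
    in_focal = np.array([g == focal for g in table.group])
    results = []
    pvals = []
    for j, system in enumerate(table.systems):
        present = table.matrix[:, j]
        t = Contingency2x2(
            a=int(np.sum(in_focal & present)),
            b=int(np.sum(in_focal & ~present)),
            c=int(np.sum(~in_focal & present)),
            d=int(np.sum(~in_focal & ~present)),
        )
        p, orat = fisher_exact(t)
        pvals.append(p)
        results.append(EnrichmentResult(system=system, table=t,
                                        odds_ratio=orat, p=p, q=np.nan,
                                        significant=False))
    for r, q in zip(results, bh_adjust(pvals)):
        r.q = q
        r.significant = q < alpha
    return results


def host_range_summary(lysis: list[bool],
                       serogroup: list[str]) -> dict[str, tuple[int, int]]:
    """Per-serogroup (susceptible, total) counts, plus an ``overall`` entry.

    Empty input yields an empty summary."""
    if len(lysis) != len(serogroup):
        raise ValueError("lysis/serogroup length mismatch")
    if not lysis:
        return {}
    df = pd.DataFrame({"lysis": [bool(x) for x in lysis],
                       "serogroup": [str(s) for s in serogroup]})
    out: dict[str, tuple[int, int]] = {}
    for grp, sub in df.groupby("serogroup", sort=True):
        out[grp] = (int(sub["lysis"].sum()), int(len(sub)))
    out["overall"] = (int(df["lysis"].sum()), int(len(df)))
    return out


def results_to_dataframe(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "system": [r.system for r in results],
        "a": [r.table.a for r in results],
        "b": [r.table.b for r in results],
        "c": [r.table.c for r in results],
        "d": [r.table.d for r in results],
        "odds_ratio": [r.odds_ratio for r in results],
        "p": [r.p for r in results],
        "q": [r.q for r in results],
        "significant": [r.significant for r in results],
    })
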