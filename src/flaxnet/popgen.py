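"""Sequence-variation summaries: segregating sites, haplotype counts,
nucleotide diversity, neutrality tests, and the four-gamete lower bound
on recombination events.

Gap and missing-data handling
-----------------------------
Substitution-based statistics (S, Watterson's theta, Tajima's D,
Fu & Li's D*/F*) use *complete deletion*: any column containing a gap is
excluded from the analysed site set, and multi-column gap runs are
collapsed into indel events carried separately (they enter the haplotype
network as single characters, never the substitution statistics).
Nucleotide diversity defaults to *pairwise deletion* — each sample pair
is compared over the columns where both carry an unambiguous base — and
can be switched to complete deletion via ``gap_mode``.  These defaults
reproduce the behaviour of the standard interactive tools for this kind
of locus survey.

Neutrality-test significance is reported as threshold bands (e.g.
``P > 0.10``, ``P < 0.05``), not exact permutation P values.  Tajima's D
bands use the beta-distribution approximation from the statistic's
original derivation; the D*/F* bands use a normal approximation of the
variance-normalised statistic and are labelled as approximate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import Alignment, InputError, RegionAnnotation

BASES = frozenset("ACGT")

#: sentinel used wherever a statistic is undefined (printed as "nd")
ND = float("nan")


def _is_nd(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


# ---------------------------------------------------------------------------
# site discovery


@dataclass
class IndelEvent:
    """A maximal run of columns sharing one gap presence/absence pattern,
    coded as a single binary character."""

    start: int  # 1-based inclusive
    end: int
    presence: tuple[bool, ...]  # True where the sample carries the gap

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        return f"indel:{self.start}-{self.end}"


@dataclass
class SiteTable:
    """Catalogue of variable columns within one analysed region."""

    positions: list[int]  # 1-based alignment columns, ascending
    alleles: dict[int, list[str]]  # position -> alleles, majority first
    states: dict[int, np.ndarray]  # position -> per-sample symbol
    gap_columns: list[int]
    indel_events: list[IndelEvent]
    n: int
    region: tuple[int, int]

    @property
    def S(self) -> int:
        """Number of segregating (substitution) sites."""
        return len(self.positions)

    @property
    def eta(self) -> int:
        """Total mutation count: one per derived allele at each site."""
        return sum(len(a) - 1 for a in self.alleles.values())

    def biallelic_positions(self) -> list[int]:
        return [p for p in self.positions if len(self.alleles[p]) == 2]

    def singleton_count(self) -> int:
        """Mutations whose derived allele is carried by exactly one sample."""
        eta_s = 0
        for p in self.positions:
            vec = self.states[p]
            for allele in self.alleles[p][1:]:
                if int(np.sum(vec == allele)) == 1:
                    eta_s += 1
        return eta_s

    def parsimony_informative(self) -> list[int]:
        out = []
        for p in self.positions:
            vec = self.states[p]
            counts = sorted(
                (int(np.sum(vec == a)) for a in self.alleles[p]), reverse=True
            )
            if len(counts) >= 2 and counts[1] >= 2:
                out.append(p)
        return out


def _find_indel_events(aln: Alignment, start: int, end: int) -> list[IndelEvent]:
    """Collapse maximal runs of identical gap patterns into single events."""
    cols = aln.columns(start, end)
    events: list[IndelEvent] = []
    run_start = None
    run_pattern: tuple[bool, ...] | None = None
    for offset in range(cols.shape[1]):
        pattern = tuple(bool(c == "-") for c in cols[:, offset])
        pos = start + offset
        if any(pattern):
            if run_pattern == pattern:
                continue
            if run_pattern is not None:
                events.append(IndelEvent(run_start, pos - 1, run_pattern))
            run_start, run_pattern = pos, pattern
        else:
            if run_pattern is not None:
                events.append(IndelEvent(run_start, pos - 1, run_pattern))
                run_start, run_pattern = None, None
    if run_pattern is not None:
        events.append(IndelEvent(run_start, end, run_pattern))
    return events


def segregating_sites(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
) -> SiteTable:
    """Find segregating substitution sites and indel events in a region.

    A column enters the substitution site list when it contains no gap
    (complete deletion) and at least two distinct unambiguous bases among
    the analysed samples.  Gap-bearing columns are collapsed into
    :class:`IndelEvent` records instead.
    """
    sub = aln.by_group(group) if group is not None else aln
    start, end = region if region is not None else (1, sub.L)
    cols = sub.columns(start, end)

    gap_columns: list[int] = []
    positions: list[int] = []
    alleles: dict[int, list[str]] = {}
    states: dict[int, np.ndarray] = {}

    for offset in range(cols.shape[1]):
        col = cols[:, offset]
        pos = start + offset
        if np.any(col == "-"):
            gap_columns.append(pos)
            continue
        observed = col[np.isin(col, list(BASES))]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) >= 2:
            order = np.argsort(-counts, kind="stable")
            positions.append(pos)
            alleles[pos] = [str(a) for a in uniq[order]]
            states[pos] = col.copy()

    return SiteTable(
        positions=positions,
        alleles=alleles,
        states=states,
        gap_columns=gap_columns,
        indel_events=_find_indel_events(sub, start, end),
        n=sub.n,
        region=(start, end),
    )


# ---------------------------------------------------------------------------
# diversity


def _pair_matrix(aln: Alignment, region: tuple[int, int] | None) -> np.ndarray:
    start, end = region if region is not None else (1, aln.L)
    return aln.columns(start, end)


def mean_pairwise_differences(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
    gap_mode: str = "pairwise",
) -> tuple[float, float]:
    """Average pairwise difference count and per-site diversity.

    Returns ``(k_bar, pi_per_bp)`` where ``k_bar`` is the mean number of
    nucleotide differences over all unordered sample pairs and
    ``pi_per_bp`` divides each pair's differences by the number of
    columns compared for that pair (pairwise deletion) or by the shared
    complete-deletion site count (complete deletion).
    """
    if gap_mode not in ("pairwise", "complete"):
        raise InputError(f"unknown gap_mode: {gap_mode!r}")
    sub = aln.by_group(group) if group is not None else aln
    if sub.n < 2:
        return ND, ND
    cols = _pair_matrix(sub, region)
    valid = np.isin(cols, list(BASES))
    if gap_mode == "complete":
        keep = valid.all(axis=0)
        cols = cols[:, keep]
        valid = valid[:, keep]

    total_diff = 0.0
    total_pi = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(sub.n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        diffs = int(np.sum((cols[i] != cols[j]) & both))
        total_diff += diffs
        total_pi += diffs / m if m > 0 else 0.0
        npairs += 1
    return total_diff / npairs, total_pi / npairs


def nucleotide_diversity(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
    gap_mode: str = "pairwise",
) -> float:
    """Nei's nucleotide diversity per site (mean pairwise difference / site)."""
    _, pi = mean_pairwise_differences(aln, region, group, gap_mode)
    return pi


def haplotype_count(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
) -> int:
    """Distinct sequences over the gap-free columns of the region."""
    sub = aln.by_group(group) if group is not None else aln
    cols = _pair_matrix(sub, region)
    keep = ~np.any(cols == "-", axis=0)
    cols = cols[:, keep]
    return len({tuple(row) for row in cols})


# ---------------------------------------------------------------------------
# neutrality tests


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's theta (total, not per site) from S segregating sites."""
    if n < 2:
        return ND
    return S / _harmonic(n)


def tajima_d(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
) -> float:
    """Tajima's D contrasting mean pairwise differences with Watterson's
    estimator, using the standard variance normalisation.

    Returns NaN ("nd") when fewer than 4 samples or no segregating site,
    matching the convention of printing "nd" for undefined cells.
    """
    sub = aln.by_group(group) if group is not None else aln
    table = segregating_sites(sub, region)
    S = table.S
    n = sub.n
    if n < 4 or S == 0:
        return ND
    # k_bar on the same complete-deletion site set as S
    k_bar, _ = mean_pairwise_differences(sub, region, gap_mode="complete")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return ND
    return (k_bar - S / a1) / math.sqrt(var)


def tajima_d_band(D: float, n: int) -> str:
    """Two-sided significance band for Tajima's D via the generalized
    beta approximation of the statistic's null distribution."""
    if _is_nd(D) or n < 4:
        return "nd"
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e2 = c2 / (a1**2 + a2)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    span = dmax - dmin
    alpha = -(1 + dmin * dmax) * dmax / span
    beta = (1 + dmin * dmax) * dmin / span
    if alpha <= 0 or beta <= 0:
        return "nd"
    dist = sps.beta(beta, alpha, loc=dmin, scale=span)
    p = 2 * min(dist.cdf(D), dist.sf(D))
    return _band(p)


def _band(p: float) -> str:
    if p < 0.01:
        return "P < 0.01"
    if p < 0.02:
        return "P < 0.02"
    if p < 0.05:
        return "P < 0.05"
    if p < 0.10:
        return "P < 0.10"
    return "P > 0.10"


def fu_li_star_tests(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
) -> tuple[float, float]:
    """Fu & Li's outgroup-free D* and F* statistics.

    D* contrasts the total mutation count with the number of singleton
    mutations; F* contrasts mean pairwise differences with singletons.
    Both use the corrected variance coefficients in standard use.
    Returns ``(nan, nan)`` when undefined (n < 4 or no variation).
    """
    sub = aln.by_group(group) if group is not None else aln
    table = segregating_sites(sub, region)
    n = sub.n
    eta = table.eta
    if n < 4 or eta == 0:
        return ND, ND
    eta_s = table.singleton_count()
    k_bar, _ = mean_pairwise_differences(sub, region, gap_mode="complete")

    a = _harmonic(n)
    b = _harmonic(n, 2)
    a_n1 = a + 1.0 / n

    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * a_n1 - 3) / (n - 2) - 1.0 / n)
    )

    v_dstar = (
        (n / (n - 1)) ** 2 * b
        + a**2 * dn
        - 2 * (n * a * (a + 1)) / (n - 1) ** 2
    ) / (a**2 + b)
    u_dstar = (n / (n - 1)) * (a - n / (n - 1)) - v_dstar
    denom_d = u_dstar * eta + v_dstar * eta**2
    dstar = (
        ((n / (n - 1)) * eta - a * eta_s) / math.sqrt(denom_d)
        if denom_d > 0
        else ND
    )

    v_fstar = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8 * b / n
    ) / (a**2 + b)
    u_fstar = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a_n1) / (3 * n * (n - 1))
    ) / a - v_fstar
    denom_f = u_fstar * eta + v_fstar * eta**2
    fstar = (
        (k_bar - ((n - 1) / n) * eta_s) / math.sqrt(denom_f)
        if denom_f > 0
        else ND
    )
    return dstar, fstar


def fu_li_band(stat: float) -> str:
    """Approximate two-sided band for D*/F* from a normal reference."""
    if _is_nd(stat):
        return "nd"
    return _band(2 * sps.norm.sf(abs(stat)))


# ---------------------------------------------------------------------------
# four-gamete recombination bound


def _four_gametes(
    va: np.ndarray, vb: np.ndarray, alleles_a: list[str], alleles_b: list[str]
) -> bool:
    ok = np.isin(va, list(BASES)) & np.isin(vb, list(BASES))
    combos = {(x, y) for x, y in zip(va[ok], vb[ok])}
    return len(combos) == 4


def incompatible_pairs(table: SiteTable) -> list[tuple[int, int]]:
    """All ordered biallelic site pairs showing all four gametes."""
    pos = table.biallelic_positions()
    out = []
    for i, j in itertools.combinations(range(len(pos)), 2):
        pi, pj = pos[i], pos[j]
        if _four_gametes(
            table.states[pi], table.states[pj], table.alleles[pi], table.alleles[pj]
        ):
            out.append((pi, pj))
    return out


def _reduce_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy reduction of incompatible intervals to a maximal disjoint set.

    Intervals are open: two incompatibilities (a, b) and (b, c) that only
    share an endpoint imply two distinct crossover regions.  Intervals
    containing another incompatible interval are redundant and dropped
    before the left-to-right greedy scan.
    """
    if not pairs:
        return []
    minimal = [
        (a, b)
        for a, b in pairs
        if not any(
            (c, d) != (a, b) and a <= c and d <= b for c, d in pairs
        )
    ]
    minimal.sort(key=lambda iv: (iv[1], iv[0]))
    chosen: list[tuple[int, int]] = []
    for a, b in minimal:
        if not chosen or a >= chosen[-1][1]:
            chosen.append((a, b))
    return chosen


def hudson_kaplan_rm(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
) -> tuple[int, list[tuple[int, int]]]:
    """Minimum number of recombination events (four-gamete lower bound).

    Scans all biallelic substitution-site pairs for the four-gamete
    condition, then reduces the incompatible intervals to a maximal set
    of disjoint intervals.  Returns ``(Rm, intervals)``.
    """
    sub = aln.by_group(group) if group is not None else aln
    table = segregating_sites(sub, region)
    intervals = _reduce_intervals(incompatible_pairs(table))
    return len(intervals), intervals


# ---------------------------------------------------------------------------
# grouped summary table


@dataclass
class DiversitySummary:
    S: int
    H: int
    pi_per_bp: float
    theta_w: float
    tajima_D: float
    fu_li_Dstar: float
    fu_li_Fstar: float
    Rm: int
    n: int
    L_effective: int


def diversity_summary(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    group: str | None = None,
    gap_mode: str = "pairwise",
) -> DiversitySummary:
    sub = aln.by_group(group) if group is not None else aln
    table = segregating_sites(sub, region)
    start, end = table.region
    width = end - start + 1
    gapfree = width - len(table.gap_columns)
    pi = nucleotide_diversity(sub, region, gap_mode=gap_mode) if sub.n >= 2 else ND
    if _is_nd(pi) is False and table.S == 0:
        pi = 0.0
    theta = (
        watterson_theta(table.S, sub.n) / gapfree
        if sub.n >= 2 and gapfree > 0
        else ND
    )
    dstar, fstar = fu_li_star_tests(sub, region)
    rm, _ = hudson_kaplan_rm(sub, region)
    return DiversitySummary(
        S=table.S,
        H=haplotype_count(sub, region),
        pi_per_bp=pi,
        theta_w=theta,
        tajima_D=tajima_d(sub, region),
        fu_li_Dstar=dstar,
        fu_li_Fstar=fstar,
        Rm=rm,
        n=sub.n,
        L_effective=gapfree,
    )


def group_summary(
    aln: Alignment,
    regions: RegionAnnotation | None = None,
    groups: list[str] | None = None,
    gap_mode: str = "pairwise",
) -> pd.DataFrame:
    """Region-by-group polymorphism matrix (S, H, pi/bp, Tajima's D).

    Rows are (group, parameter); columns are the named regions plus a
    ``Total`` column over the full alignment.  Undefined cells hold NaN
    and print as ``nd``.
    """
    if regions is None:
        regions = RegionAnnotation.whole(aln.L)
    known = set(aln.group_labels())
    if groups is None:
        groups = aln.group_labels()
    for g in groups:
        if g not in known:
            raise InputError(f"unknown group: {g!r}")
    cols = regions.names + ["Total"]
    rows = []
    index = []
    for g in groups:
        sub = aln.by_group(g)
        for param in ("S", "H", "pi_per_bp", "D"):
            index.append((f"{g} ({sub.n})", param))
            row = []
            for name in cols:
                reg = None if name == "Total" else regions.interval(name)
                if param == "S":
                    row.append(segregating_sites(sub, reg).S)
                elif param == "H":
                    row.append(haplotype_count(sub, reg))
                elif param == "pi_per_bp":
                    pi = nucleotide_diversity(sub, reg, gap_mode=gap_mode)
                    if not _is_nd(pi):
                        pi = pi if segregating_sites(sub, reg).S else 0.0
                    row.append(pi)
                else:
                    row.append(tajima_d(sub, reg))
            rows.append(row)
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["group", "parameter"]),
        columns=cols,
    )


def write_group_summary(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.to_csv(path, sep="\t", na_rep="nd", float_format="%.5g")
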