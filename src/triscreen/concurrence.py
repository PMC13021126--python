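"""Randomness-null expected counts, chi-square tests and relative proportions.

The null model asks: if, among women who have ever been screened at least
once (ever participants, N_EP), last-round participation in the three
programmes were mutually independent — and women never screened in any
programme (never participants, N_NP) never participate — how many women
would participate in all three programmes, or in none?

    E[all three] = N_EP * (N_breast/N_EP) * (N_cervix/N_EP) * (N_bowel/N_EP)
    E[none]      = N_EP * ((N_EP-N_breast)/N_EP) * ((N_EP-N_cervix)/N_EP)
                        * ((N_EP-N_bowel)/N_EP) + N_NP

Each headline cell is compared with its expectation by a 1-df Pearson
chi-square on the dichotomy {in cell, not in cell}.  Group comparisons use
relative proportions (RP), a ratio of two binomial proportions, with 95%
confidence intervals from the log-scale delta method:

    var(ln RP) = 1/a - 1/n1 + 1/b - 1/n2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .records import ParticipationPattern, Programme, round_half_up

__all__ = [
    "ConcurrenceCounts",
    "NullExpectation",
    "RPResult",
    "count_concurrence",
    "expected_all_three",
    "expected_none",
    "expected_pattern_counts",
    "cell_chi_square",
    "pattern_chi_square",
    "null_test",
    "relative_proportion",
    "build_table2",
]

Z95 = 1.96  # fixed normal quantile for all 95% intervals


@dataclass(frozen=True)
class ConcurrenceCounts:
    """Sufficient statistics of the randomness null."""

    n_total: int
    n_ep: int
    n_np: int
    n_breast: int
    n_cervix: int
    n_bowel: int
    obs_all3: int
    obs_none: int

    def __post_init__(self) -> None:
        if self.n_ep + self.n_np != self.n_total:
            raise ValueError("n_ep + n_np must equal n_total")
        if any(
            x < 0
            for x in (self.n_breast, self.n_cervix, self.n_bowel, self.obs_all3, self.obs_none)
        ):
            raise ValueError("counts must be non-negative")
        if self.n_ep and self.obs_all3 > min(self.n_breast, self.n_cervix, self.n_bowel):
            raise ValueError("obs_all3 exceeds a programme count")
        if self.obs_none < self.n_np:
            raise ValueError("obs_none cannot be below the never-participant count")
        if any(x > self.n_ep for x in (self.n_breast, self.n_cervix, self.n_bowel)):
            raise ValueError("programme counts cannot exceed n_ep")


@dataclass(frozen=True)
class NullExpectation:
    exp_all3: float
    exp_none: float
    chi2_all3: float
    p_all3: float
    chi2_none: float
    p_none: float


@dataclass(frozen=True)
class RPResult:
    """Relative proportion (a/n1)/(b/n2) with a log-normal 95% CI."""

    a: int
    n1: int
    b: int
    n2: int
    rp: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def count_concurrence(
    patterns: Iterable[ParticipationPattern],
    ever_flags: Mapping[str, bool],
) -> ConcurrenceCounts:
    """Reduce per-woman patterns plus ever/never status to null-model counts.

    ``ever_flags`` maps woman_id to True for women with >= 1 screen event ever
    in any programme.  A never participant with a True last-round flag is a
    data inconsistency and raises.
    """
    n_total = n_ep = nb = nc = nw = all3 = none = 0
    for p in patterns:
        try:
            ever = ever_flags[p.woman_id]
        except KeyError:
            raise KeyError(f"no ever/never flag for woman {p.woman_id}") from None
        if not ever and any(p.flags):
            raise ValueError(
                f"woman {p.woman_id} is flagged never-participant but has a "
                "positive last-round flag"
            )
        n_total += 1
        n_ep += ever
        nb += p.breast
        nc += p.cervical
        nw += p.bowel
        all3 += p.n_programmes == 3
        none += p.n_programmes == 0
    return ConcurrenceCounts(n_total, n_ep, n_total - n_ep, nb, nc, nw, all3, none)


def expected_all_three(c: ConcurrenceCounts) -> float:
    """Expected all-three count under independence among ever participants."""
    if c.n_ep == 0:
        return 0.0
    return c.n_ep * (c.n_breast / c.n_ep) * (c.n_cervix / c.n_ep) * (c.n_bowel / c.n_ep)


def expected_none(c: ConcurrenceCounts) -> float:
    """Expected none count; never participants contribute with certainty."""
    if c.n_ep == 0:
        return float(c.n_np)
    return (
        c.n_ep
        * ((c.n_ep - c.n_breast) / c.n_ep)
        * ((c.n_ep - c.n_cervix) / c.n_ep)
        * ((c.n_ep - c.n_bowel) / c.n_ep)
        + c.n_np
    )


def expected_pattern_counts(
    c: ConcurrenceCounts,
) -> dict[tuple[bool, bool, bool], float]:
    """All 8 expected pattern counts under the null; they sum to n_total."""
    out: dict[tuple[bool, bool, bool], float] = {}
    if c.n_ep == 0:
        for b in (True, False):
            for v in (True, False):
                for w in (True, False):
                    out[(b, v, w)] = 0.0
        out[(False, False, False)] = float(c.n_np)
        return out
    pb, pc, pw = c.n_breast / c.n_ep, c.n_cervix / c.n_ep, c.n_bowel / c.n_ep
    for b in (True, False):
        for v in (True, False):
            for w in (True, False):
                e = (
                    c.n_ep
                    * (pb if b else 1 - pb)
                    * (pc if v else 1 - pc)
                    * (pw if w else 1 - pw)
                )
                if not (b or v or w):
                    e += c.n_np
                out[(b, v, w)] = e
    return out


def cell_chi_square(observed: int, expected: float, n_total: int) -> tuple[float, float]:
    """1-df Pearson chi-square on the dichotomy {in cell, not in cell}.

    ``(O-E)^2/E + ((n-O)-(n-E))^2/(n-E)`` with the p-value from the upper
    tail of chi-square(1).  Requires ``0 < expected < n_total``.
    """
    if not 0 < expected < n_total:
        raise ValueError(f"expected must lie strictly between 0 and n_total, got {expected}")
    stat = (observed - expected) ** 2 / expected + (observed - expected) ** 2 / (
        n_total - expected
    )
    return stat, float(stats.chi2.sf(stat, df=1))


def pattern_chi_square(
    observed: Mapping[tuple[bool, bool, bool], int], c: ConcurrenceCounts
) -> tuple[float, float, int]:
    """Optional 8-cell Pearson chi-square of the full pattern table vs the null.

    Degrees of freedom are taken as 7 (cells minus one); no reduction is made
    for the plug-in marginal estimates, so the reference distribution is
    approximate and conservative.
    """
    expected = expected_pattern_counts(c)
    stat = 0.0
    for combo, e in expected.items():
        if e <= 0:
            continue
        stat += (observed.get(combo, 0) - e) ** 2 / e
    df = 7
    return stat, float(stats.chi2.sf(stat, df=df)), df


def null_test(c: ConcurrenceCounts) -> NullExpectation:
    """Both headline comparisons (all three; none) against the randomness null."""
    e3 = expected_all_three(c)
    e0 = expected_none(c)
    s3, p3 = cell_chi_square(c.obs_all3, e3, c.n_total)
    s0, p0 = cell_chi_square(c.obs_none, e0, c.n_total)
    return NullExpectation(e3, e0, s3, p3, s0, p0)


def relative_proportion(a: int, n1: int, b: int, n2: int, z: float = Z95) -> RPResult:
    """Ratio of proportions (a/n1)/(b/n2) with a log-normal delta-method CI.

    A zero numerator in either group makes the log-scale CI undefined; the
    result is then flagged degenerate with NaN bounds rather than silently
    returning an infinity.
    """
    if n1 <= 0 or n2 <= 0 or a > n1 or b > n2 or a < 0 or b < 0:
        raise ValueError("need 0 <= a <= n1 and 0 <= b <= n2 with n1, n2 > 0")
    if a == 0 or b == 0:
        rp = math.inf if (b == 0 and a > 0) else 0.0 if b > 0 else math.nan
        return RPResult(a, n1, b, n2, rp, math.nan, math.nan, degenerate=True)
    rp = (a / n1) / (b / n2)
    var = 1 / a - 1 / n1 + 1 / b - 1 / n2
    half = z * math.sqrt(var)
    return RPResult(
        a, n1, b, n2, rp, math.exp(math.log(rp) - half), math.exp(math.log(rp) + half)
    )


_OUTCOMES = {"two": 2, "one": 1, "none": 0}


def build_table2(patterns: Iterable[ParticipationPattern]) -> pd.DataFrame:
    """Participation in additional programmes, by index-programme participation.

    For each programme, women are split into participants and non-participants
    (the referent), and within each group counted by how many of the *other
    two* programmes they participated in (two / one / none).  Each outcome is
    compared between the groups by a relative proportion with its 95% CI.

    Returns a tidy frame with one row per (programme, participated, outcome):
    ``programme, participated, group_n, outcome, count, percent, rp, ci_low,
    ci_high`` — referent rows carry rp = 1 and NaN bounds, degenerate contrasts
    NaN everywhere.
    """
    pats = list(patterns)
    rows = []
    for prog in Programme:
        attr = {"breast": "breast", "cervical": "cervical", "bowel": "bowel"}[prog.value]
        groups: dict[bool, list[int]] = {True: [], False: []}
        for p in pats:
            others = p.n_programmes - int(getattr(p, attr))
            groups[bool(getattr(p, attr))].append(others)
        counts = {
            flag: {name: sum(1 for o in vals if o == k) for name, k in _OUTCOMES.items()}
            for flag, vals in groups.items()
        }
        n_yes, n_no = len(groups[True]), len(groups[False])
        for flag, group_n in ((False, n_no), (True, n_yes)):
            for name in _OUTCOMES:
                cnt = counts[flag][name]
                pct = int(round_half_up(100.0 * cnt / group_n)) if group_n else 0
                if not flag:
                    rp, lo, hi = 1.0, math.nan, math.nan
                elif group_n == 0 or n_no == 0:
                    rp = lo = hi = math.nan
                else:
                    res = relative_proportion(cnt, group_n, counts[False][name], n_no)
                    rp, lo, hi = res.rp, res.ci_low, res.ci_high
                rows.append(
                    {
                        "programme": prog.value,
                        "participated": flag,
                        "group_n": group_n,
                        "outcome": name,
                        "count": cnt,
                        "percent": pct,
                        "rp": rp,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
    return pd.DataFrame(rows)
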