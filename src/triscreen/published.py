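"""Summary counts reported for the studied English screening population.

The woman-level microdata (an NHS Digital extract for 3060 controls of a
national breast-screening case-control study) and the practice-level
microdata are not publicly deposited, but every headline analysis is a
deterministic function of the published summary counts, which are recorded
here: the 8-row last-round participation table, the ever/never split, and
the tertile-by-coverage-class counts for 7014 general practices with
complete 2017/18 Fingertips data.  Reconstructing per-woman patterns from
the 8-row table is exact because the patterns are the sufficient statistic
for every woman-level quantity the analysis reports.
"""

from __future__ import annotations

from .concurrence import ConcurrenceCounts
from .ecology import NationalAverages
from .records import ParticipationPattern

__all__ = [
    "N_TOTAL",
    "N_EVER",
    "N_NEVER",
    "TABLE1_COUNTS",
    "TABLE3_COUNTS",
    "NATIONAL_2017",
    "cohort_patterns",
    "cohort_counts",
]

N_TOTAL = 3060
N_EVER = 2989
N_NEVER = 71

#: Last-round participation combinations (breast, cervical, bowel) -> count.
TABLE1_COUNTS: dict[tuple[bool, bool, bool], int] = {
    (True, True, True): 1086,
    (True, True, False): 639,
    (True, False, True): 445,
    (False, True, True): 58,
    (True, False, False): 355,
    (False, True, False): 125,
    (False, False, True): 46,
    (False, False, False): 306,
}

#: Practice counts per characteristic tertile: (below, mixed, above) coverage
#: class, rows lowest/middle/highest tertile; 7014 practices in total.
TABLE3_COUNTS: dict[str, list[tuple[int, int, int]]] = {
    "imd": [(191, 645, 1478), (658, 941, 784), (1439, 759, 119)],
    "unemployment": [(249, 772, 1294), (677, 887, 819), (1362, 686, 268)],
    "ltc": [(1249, 659, 407), (585, 808, 991), (454, 878, 983)],
    "carers": [(1167, 704, 443), (625, 845, 918), (496, 796, 1020)],
    "smokers": [(323, 542, 1448), (681, 903, 801), (1284, 900, 132)],
    "satisfaction": [(1203, 719, 393), (769, 888, 729), (316, 738, 1259)],
}

#: National average coverage in 2017/18 (breast, cervical, bowel), percent.
NATIONAL_2017 = NationalAverages(72.1, 71.7, 57.3)


def cohort_patterns() -> tuple[list[ParticipationPattern], dict[str, bool]]:
    """Per-woman patterns implied by the 8-row table, plus ever/never flags.

    The 71 never participants are (necessarily) among the 306 women who
    participated in none of the programmes in the last round; which 71 is
    immaterial to every statistic computed downstream.
    """
    patterns: list[ParticipationPattern] = []
    ever: dict[str, bool] = {}
    i = 0
    never_left = N_NEVER
    for (b, c, w), count in TABLE1_COUNTS.items():
        for _ in range(count):
            wid = f"C{i:04d}"
            patterns.append(ParticipationPattern(wid, b, c, w))
            if not (b or c or w) and never_left > 0:
                ever[wid] = False
                never_left -= 1
            else:
                ever[wid] = True
            i += 1
    return patterns, ever


def cohort_counts() -> ConcurrenceCounts:
    """Null-model sufficient statistics of the studied cohort."""
    from .concurrence import count_concurrence

    patterns, ever = cohort_patterns()
    return count_concurrence(patterns, ever)
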