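"""Synthetic cohorts and practice files with the dependence structure the
analysis assumes.

Individual-level histories: each woman is a structural "never participant"
with probability ``p_never`` (no screen events ever, matching the null
model's N_NP class).  Otherwise her last-round participation triple comes
from a Gaussian copula — a latent trivariate standard normal with
equicorrelation ``rho`` (or a full correlation matrix) thresholded at the
marginal-rate quantiles — and a screen event is placed uniformly inside the
corresponding look-back window for each positive flag.  ``rho = 0`` is an
exact independence special case; increasing ``rho`` increases concurrent
participation with the marginals held fixed.  A pre-age-54 breast/cervical
pair is generated the same way from its own bivariate copula, and every ever
participant receives one guaranteed early cervical screen (ages 44-47, well
before any window) so that ever/never status is exact by construction.

Practice-level aggregates: six population characteristics are drawn
independently, tertiled, and the practice's coverage class follows a
baseline-category logit in the tertile indicators with stated above-vs-below
log-odds effects (the mixed class receives half the linear predictor, giving
the dose-response ordering).  The coverage triple is then drawn consistent
with the class, so classification recovers the generating class exactly.

Default parameters reproduce the marginal structure of the studied English
cohort of 3060 women aged 60-65 (last-round rates 2525/1908/1635 of 2989
ever participants, 71 never participants) and its 2017/18 practice-level
counterpart; the correlations were calibrated by bisection against the exact
multivariate-normal rectangle probability (see :func:`calibrate_rho`).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ecology import CHARACTERISTICS, NationalAverages, tertile_cut
from .records import (
    EventType,
    Programme,
    ScreeningEvent,
    WindowSpec,
    WomanRecord,
    MAIN_WINDOWS,
    PRE_AGE54_WINDOWS,
    add_years,
    years_before,
)

__all__ = [
    "EP_MARGINALS",
    "RHO_MAIN",
    "PRE54_MARGINAL",
    "RHO_PRE54",
    "WomanSimParams",
    "PracticeSimParams",
    "calibrate_rho",
    "sample_patterns",
    "simulate_women",
    "simulate_practices",
]

#: Last-round marginal participation rates among ever participants
#: (breast, cervical, bowel) in the studied cohort.
EP_MARGINALS: tuple[float, float, float] = (2525 / 2989, 1908 / 2989, 1635 / 2989)

#: Equicorrelation reproducing the observed all-three proportion 1086/2989
#: given EP_MARGINALS (frozen output of calibrate_rho).
RHO_MAIN: float = 0.3001

#: Common pre-age-54 breast/cervical marginal among ever participants and the
#: correlation reproducing 63% both / 29% one / 8% neither overall.
PRE54_MARGINAL: float = 0.79341
RHO_PRE54: float = 0.17887

P_NEVER_DEFAULT: float = 71 / 3060


def _corr_matrix(dependence: float | np.ndarray, k: int) -> np.ndarray:
    if np.isscalar(dependence):
        R = np.full((k, k), float(dependence))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(dependence, dtype=float)
        if R.shape != (k, k):
            raise ValueError(f"dependence matrix must be {k}x{k}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("dependence matrix must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("dependence matrix is not positive semi-definite")
    return R


def calibrate_rho(
    marginals: Sequence[float],
    target_joint: float,
    lo: float = 0.0,
    hi: float = 0.95,
    iters: int = 60,
) -> float:
    """Equicorrelation whose Gaussian copula attains a target all-positive
    probability, by bisection on the exact MVN rectangle probability."""
    q = stats.norm.ppf(np.asarray(marginals, dtype=float))
    k = len(q)

    def joint(rho: float) -> float:
        R = _corr_matrix(rho, k)
        return float(
            stats.multivariate_normal.cdf(q, mean=np.zeros(k), cov=R, abseps=1e-10, releps=1e-10)
        )

    if not joint(lo) <= target_joint <= joint(hi):
        raise ValueError("target joint probability not bracketed by [lo, hi]")
    for _ in range(iters):
        mid = (lo + hi) / 2
        if joint(mid) < target_joint:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def sample_patterns(
    n: int,
    marginals: Sequence[float],
    dependence: float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an (n, k) boolean participation array from the thresholded copula.

    With scalar ``dependence`` the latent normals use the one-factor
    representation ``sqrt(rho)*g + sqrt(1-rho)*e``; the draw order (shared
    factor first, then idiosyncratic noise) is fixed, so two calls with the
    same generator state and different ``rho`` share random numbers — useful
    for monotonicity checks.
    """
    m = np.asarray(marginals, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("marginal rates must be in [0, 1]")
    k = len(m)
    q = stats.norm.ppf(m)
    if np.isscalar(dependence):
        rho = float(dependence)
        _corr_matrix(rho, k)  # validates range
        g = rng.standard_normal(n)
        e = rng.standard_normal((n, k))
        z = math.sqrt(rho) * g[:, None] + math.sqrt(1.0 - rho) * e
    else:
        R = _corr_matrix(dependence, k)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
        z = rng.standard_normal((n, k)) @ L.T
    return z < q


@dataclass
class WomanSimParams:
    """Generator settings for individual-level screening histories.

    Defaults are the study conditions of the English cohort: 3060 women aged
    60-65 with reference dates in 2010-2011, 71/3060 never participants,
    ever-participant marginals (0.845, 0.638, 0.547), copula correlation
    0.3001, 78% with a bowel invitation at least a year before reference, and
    a 21% hysterectomy prevalence (carried, never used in classification).
    """

    n_women: int = 3060
    p_never: float = P_NEVER_DEFAULT
    marginal_rates: tuple[float, float, float] = EP_MARGINALS
    dependence: float | np.ndarray = RHO_MAIN
    marginal_pre54: tuple[float, float] = (PRE54_MARGINAL, PRE54_MARGINAL)
    dependence_pre54: float | np.ndarray = RHO_PRE54
    p_invited_prelag: float = 0.78
    p_invited_recent: float = 0.6  # of the remainder: invited within the last year
    p_hysterectomy: float = 0.21
    reference_start: dt.date = dt.date(2010, 1, 1)
    reference_end: dt.date = dt.date(2011, 12, 31)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_never", "p_invited_prelag", "p_invited_recent", "p_hysterectomy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for m in (*self.marginal_rates, *self.marginal_pre54):
            if not 0.0 <= m <= 1.0:
                raise ValueError("marginal rates must be in [0, 1]")
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        if self.reference_end < self.reference_start:
            raise ValueError("reference_end before reference_start")
        _corr_matrix(self.dependence, 3)
        _corr_matrix(self.dependence_pre54, 2)


def _uniform_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    """Uniform date in [start, end); requires start < end."""
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span)))


_WINDOW_BY_PROGRAMME: dict[Programme, WindowSpec] = {w.programme: w for w in MAIN_WINDOWS}
_PRE54_BY_PROGRAMME: dict[Programme, WindowSpec] = {w.programme: w for w in PRE_AGE54_WINDOWS}


def simulate_women(params: WomanSimParams) -> list[WomanRecord]:
    """Generate a cohort of WomanRecords with full event histories.

    Deterministic under a fixed ``params.seed``; all randomness flows through
    one ``numpy`` generator in a fixed draw order.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_women
    ref_span = (params.reference_end - params.reference_start).days + 1
    ref_offsets = rng.integers(0, ref_span, n)
    # attained age at reference in [60, 65): 60th birthday minus 0..1799 days
    extra_age_days = rng.integers(0, 1800, n)
    never = rng.random(n) < params.p_never
    flags_main = sample_patterns(n, params.marginal_rates, params.dependence, rng)
    flags_pre54 = sample_patterns(n, params.marginal_pre54, params.dependence_pre54, rng)
    hyst = rng.random(n) < params.p_hysterectomy
    invite_u = rng.random(n)
    flags_main[never] = False
    flags_pre54[never] = False

    women: list[WomanRecord] = []
    main_order = (Programme.BREAST, Programme.CERVICAL, Programme.BOWEL)
    for i in range(n):
        ref = params.reference_start + dt.timedelta(days=int(ref_offsets[i]))
        birth = years_before(ref, 60) - dt.timedelta(days=int(extra_age_days[i]))
        wid = f"W{i:05d}"
        events: list[ScreeningEvent] = []
        if not never[i]:
            # guaranteed early cervical screen at age 44-47: fixes ever status
            events.append(
                ScreeningEvent(
                    wid,
                    Programme.CERVICAL,
                    EventType.SCREEN,
                    _uniform_date(rng, add_years(birth, 44), add_years(birth, 47)),
                )
            )
            anchor54 = add_years(birth, 54)
            for j, prog in enumerate((Programme.BREAST, Programme.CERVICAL)):
                if flags_pre54[i, j]:
                    w = _PRE54_BY_PROGRAMME[prog]
                    events.append(
                        ScreeningEvent(
                            wid,
                            prog,
                            EventType.SCREEN,
                            _uniform_date(rng, years_before(anchor54, w.lookback_years), anchor54),
                        )
                    )
            for j, prog in enumerate(main_order):
                if flags_main[i, j]:
                    w = _WINDOW_BY_PROGRAMME[prog]
                    events.append(
                        ScreeningEvent(
                            wid,
                            prog,
                            EventType.SCREEN,
                            _uniform_date(rng, years_before(ref, w.lookback_years), ref),
                        )
                    )
        # bowel invitations model the staggered roll-out and are independent
        # of participation; every woman (never participants included) can be
        # invited
        if invite_u[i] < params.p_invited_prelag:
            lo, hi = years_before(ref, 3), years_before(ref, 1)
            inv = lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
            events.append(ScreeningEvent(wid, Programme.BOWEL, EventType.INVITATION, inv))
        elif invite_u[i] < params.p_invited_prelag + (1 - params.p_invited_prelag) * params.p_invited_recent:
            inv = ref - dt.timedelta(days=int(rng.integers(1, 365)))
            events.append(ScreeningEvent(wid, Programme.BOWEL, EventType.INVITATION, inv))
        events.sort(key=lambda e: (e.event_date, e.programme.value, e.event_type.value))
        women.append(WomanRecord(wid, birth, ref, bool(hyst[i]), events))
    return women


def _default_characteristics() -> dict[str, tuple[float, float, float, float]]:
    # name -> (mean, sd, clip_low, clip_high); plausible English practice values
    return {
        "imd": (21.7, 12.0, 1.0, 80.0),
        "unemployment": (3.9, 2.0, 0.2, 15.0),
        "ltc": (54.0, 8.0, 20.0, 90.0),
        "carers": (17.5, 4.5, 2.0, 40.0),
        "smokers": (17.0, 6.5, 2.0, 45.0),
        "satisfaction": (84.0, 8.0, 40.0, 100.0),
    }


def _default_effects() -> dict[str, tuple[float, float]]:
    # above-vs-below log odds for the middle and highest tertile (lowest = 0);
    # magnitudes follow the mutually adjusted gradients seen nationally:
    # deprivation, unemployment and smoking depress coverage, chronic-illness
    # burden, carers and satisfaction raise it
    return {
        "imd": (-1.20, -2.66),
        "unemployment": (-0.82, -1.61),
        "ltc": (2.11, 2.94),
        "carers": (1.18, 1.51),
        "smokers": (-0.67, -2.53),
        "satisfaction": (0.55, 1.50),
    }


@dataclass
class PracticeSimParams:
    """Generator settings for practice-level aggregates.

    ``effects`` are above-vs-below log odds per (middle, highest) tertile of
    each characteristic; the mixed class receives ``mixed_scale`` times the
    same linear predictor, so conditional on {below, mixed} the true
    mixed-vs-below coefficients are ``mixed_scale * effects``.
    """

    n_practices: int = 7014
    characteristics: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_characteristics
    )
    effects: Mapping[str, tuple[float, float]] = field(default_factory=_default_effects)
    mixed_scale: float = 0.5
    alpha_above: float = 0.0
    alpha_mixed: float = 0.45  # balances the three classes to rough thirds
    coverage_sd: float = 6.0
    national: NationalAverages = field(default_factory=NationalAverages)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_practices < 30:
            raise ValueError("n_practices must be at least 30")
        for name, (bm, bh) in self.effects.items():
            if name not in self.characteristics:
                raise ValueError(f"effect for unknown characteristic {name!r}")
            if not (math.isfinite(bm) and math.isfinite(bh)):
                raise ValueError(f"effects for {name!r} must be finite")


def simulate_practices(params: PracticeSimParams) -> pd.DataFrame:
    """Generate a practices table whose coverage class follows a known model.

    The returned frame has the analysis schema (practice_id, list_size, the
    three coverages, six characteristics) plus a ``true_class`` column so
    recovery studies can check classification exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_practices
    nat = np.array(params.national.as_tuple())

    chars = {}
    for name in CHARACTERISTICS:
        mean, sd, lo, hi = params.characteristics[name]
        chars[name] = np.clip(rng.normal(mean, sd, n), lo, hi).round(2)
    df = pd.DataFrame(chars)

    s = np.zeros(n)
    for name, (bm, bh) in params.effects.items():
        lab = tertile_cut(df[name]).labels
        s += np.where(lab == "middle", bm, 0.0) + np.where(lab == "highest", bh, 0.0)
    s -= s.mean()  # centre so the intercepts govern overall class balance

    eta = np.column_stack(
        [np.zeros(n), params.alpha_mixed + params.mixed_scale * s, params.alpha_above + s]
    )
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(prob, axis=1)
    cls_idx = (u[:, None] > cum).sum(axis=1)  # 0=below, 1=mixed, 2=above

    cov = np.empty((n, 3))
    spread = np.abs(rng.normal(0.0, params.coverage_sd, (n, 3)))
    mixed_pattern = rng.integers(1, 7, n)  # 1..6: at least one above, one below
    for j in range(3):
        above_j = np.where(
            cls_idx == 2,
            True,
            np.where(cls_idx == 0, False, (mixed_pattern >> j) & 1 == 1),
        )
        cov[:, j] = np.where(
            above_j,
            np.minimum(nat[j] + spread[:, j], 100.0),
            np.maximum(nat[j] - 0.05 - spread[:, j], 0.0),
        )
    cov = cov.round(1)
    # rounding must not push a below-average coverage onto the threshold
    for j in range(3):
        bad = (cls_idx != 2) & (cov[:, j] >= nat[j]) & ~(
            (cls_idx == 1) & ((mixed_pattern >> j) & 1 == 1)
        )
        cov[bad, j] = np.floor((nat[j] - 0.05) * 10) / 10

    df.insert(0, "practice_id", [f"P{i:05d}" for i in range(n)])
    df.insert(1, "list_size", np.clip(rng.lognormal(math.log(7500), 0.5, n), 500, 60000).astype(int))
    df.insert(2, "cov_breast", cov[:, 0])
    df.insert(3, "cov_cervical", cov[:, 1])
    df.insert(4, "cov_bowel", cov[:, 2])
    df["true_class"] = pd.Categorical.from_codes(cls_idx, ["below", "mixed", "above"])
    return df
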