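"""Ecological analysis of general-practice screening coverage.

Practices are labelled by whether their coverage is at-or-above the national
average in all three programmes concurrently (``above``), below in all three
(``below``), or a mixture (``mixed``).  Six practice population
characteristics are cut into approximate tertiles, and the association
between each characteristic and coverage class is summarised by odds ratios —
unadjusted, from the tertile-by-class contingency table, and mutually
adjusted, from one logistic regression per outcome contrast containing all
six characteristics as tertile indicators.

The two contrasts are fitted separately on subsets (mixed vs below on
mixed + below practices; above vs below on above + below practices), not as
one multinomial model.  These are area-level correlations: nothing here
licenses individual-level or causal conclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "CHARACTERISTICS",
    "COVERAGE_COLS",
    "NationalAverages",
    "TertileCut",
    "ORResult",
    "LogisticFit",
    "SeparationError",
    "ConvergenceError",
    "read_practices",
    "assign_coverage_class",
    "tertile_cut",
    "unadjusted_or",
    "fit_logistic",
    "build_table3",
]

#: The six practice population characteristics, in report order.
CHARACTERISTICS = ["imd", "unemployment", "ltc", "carers", "smokers", "satisfaction"]
COVERAGE_COLS = ["cov_breast", "cov_cervical", "cov_bowel"]
TERTILE_LABELS = ["lowest", "middle", "highest"]
CLASS_LABELS = ["below", "mixed", "above"]

Z95 = 1.96


@dataclass(frozen=True)
class NationalAverages:
    """National average coverage thresholds (percent), 2017/18 defaults."""

    breast: float = 72.1
    cervical: float = 71.7
    bowel: float = 57.3

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.breast, self.cervical, self.bowel)


@dataclass(frozen=True)
class TertileCut:
    """Tertile cutpoints (rounded to 2 decimals) and per-value labels."""

    cut_low: float
    cut_high: float
    labels: pd.Series  # values in TERTILE_LABELS


@dataclass(frozen=True)
class ORResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


class SeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    n_obs: int
    n_iter: int
    llf: float

    def odds_ratios(self, z: float = Z95) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
            }
        )


def read_practices(path: str | Path) -> pd.DataFrame:
    """Read a practices CSV and validate ranges (percentages in [0, 100])."""
    df = pd.read_csv(path)
    required = ["practice_id", "list_size"] + COVERAGE_COLS + CHARACTERISTICS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    pct_cols = COVERAGE_COLS + ["unemployment", "ltc", "carers", "smokers", "satisfaction"]
    bad = df[pct_cols].stack().pipe(lambda s: s[(s < 0) | (s > 100)])
    if len(bad):
        raise ValueError(f"{path}: {len(bad)} percentage value(s) outside [0, 100]")
    if (df["list_size"].dropna() <= 0).any():
        raise ValueError(f"{path}: list_size must be positive")
    return df


def assign_coverage_class(
    df: pd.DataFrame, national: NationalAverages = NationalAverages()
) -> pd.Series:
    """Label each practice below / mixed / above relative to national averages.

    ``above`` requires coverage at or above the national average in all three
    programmes concurrently (equality resolves upward); ``below`` requires
    strictly below in all three; everything else is ``mixed``.
    """
    at_or_above = df[COVERAGE_COLS].ge(national.as_tuple()).to_numpy()
    label = np.where(
        at_or_above.all(axis=1), "above", np.where(~at_or_above.any(axis=1), "below", "mixed")
    )
    return pd.Series(
        pd.Categorical(label, categories=CLASS_LABELS), index=df.index, name="coverage_class"
    )


def tertile_cut(values: Sequence[float] | pd.Series) -> TertileCut:
    """Cut values into approximate tertiles at 2-decimal-rounded quantiles.

    Cutpoints are the 1/3 and 2/3 sample quantiles rounded to two decimals;
    values at or below ``cut_low`` are ``lowest``, at or below ``cut_high``
    ``middle``, otherwise ``highest`` (ties resolve to the lower tertile).
    Heavy ties that empty a tertile raise with the offending cutpoints.
    """
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise ValueError("tertile_cut requires complete data")
    if s.nunique() < 3:
        raise ValueError("tertile_cut requires at least 3 distinct values")
    cut_low = round(float(s.quantile(1 / 3)), 2)
    cut_high = round(float(s.quantile(2 / 3)), 2)
    labels = pd.Series(
        np.where(s <= cut_low, "lowest", np.where(s <= cut_high, "middle", "highest")),
        index=s.index,
    )
    sizes = labels.value_counts()
    if set(TERTILE_LABELS) - set(sizes.index):
        raise ValueError(
            f"degenerate tertiles: cutpoints ({cut_low}, {cut_high}) leave an empty group"
        )
    return TertileCut(cut_low, cut_high, labels.astype(pd.CategoricalDtype(TERTILE_LABELS)))


def unadjusted_or(
    exposed_cases: int,
    exposed_noncases: int,
    referent_cases: int,
    referent_noncases: int,
    z: float = Z95,
) -> ORResult:
    """Odds ratio from a 2x2 table with a Wald CI on the log scale.

    ``(exposed_cases/exposed_noncases) / (referent_cases/referent_noncases)``
    with ``var(ln OR)`` the sum of reciprocal cells.  Any zero cell yields a
    flagged degenerate result.
    """
    cells = (exposed_cases, exposed_noncases, referent_cases, referent_noncases)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if any(c == 0 for c in cells):
        return ORResult(math.nan, math.nan, math.nan, degenerate=True)
    or_ = (exposed_cases / exposed_noncases) / (referent_cases / referent_noncases)
    half = z * math.sqrt(sum(1 / c for c in cells))
    return ORResult(or_, math.exp(math.log(or_) - half), math.exp(math.log(or_) + half))


def _find_separating_columns(y: np.ndarray, X: pd.DataFrame) -> list[str]:
    suspects = []
    for col in X.columns:
        if col == "const":
            continue
        x = X[col].to_numpy()
        if x.max() > x.min() and (y[x > x.min()].std() == 0 or y[x == x.min()].std() == 0):
            suspects.append(col)
    return suspects


def fit_logistic(
    y: Sequence[int] | np.ndarray,
    X: pd.DataFrame,
    add_intercept: bool = True,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton iterations).

    ``y`` is a 0/1 outcome; ``X`` holds the covariates (an intercept is added
    unless ``add_intercept`` is False).  Convergence is declared when the
    score (gradient) norm falls below 1e-6; failure raises
    :class:`ConvergenceError` with the iteration count, and detected complete
    separation raises :class:`SeparationError` naming suspect columns.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    Xd = sm.add_constant(X, has_constant="add") if add_intercept else X.copy()
    model = sm.Logit(y, Xd)
    try:
        res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        suspects = _find_separating_columns(y, Xd)
        raise SeparationError(
            "perfect separation detected"
            + (f"; suspect column(s): {', '.join(suspects)}" if suspects else "")
        ) from exc
    score_norm = float(np.abs(model.score(res.params)).max())
    n_iter = int(res.mle_retvals.get("iterations", maxiter))
    if not res.mle_retvals.get("converged", False) or score_norm > 1e-6:
        raise ConvergenceError(
            f"logistic fit did not converge: {n_iter} iterations, "
            f"score norm {score_norm:.3g}"
        )
    return LogisticFit(
        params=pd.Series(res.params, index=Xd.columns),
        bse=pd.Series(res.bse, index=Xd.columns),
        n_obs=len(y),
        n_iter=n_iter,
        llf=float(res.llf),
    )


def _indicator_design(tertiles: pd.DataFrame) -> pd.DataFrame:
    """Two indicator columns (middle, highest) per characteristic; lowest = ref."""
    cols = {}
    for ch in tertiles.columns:
        for lvl in ("middle", "highest"):
            cols[f"{ch}_{lvl}"] = (tertiles[ch] == lvl).astype(float)
    return pd.DataFrame(cols, index=tertiles.index)


def build_table3(
    practices: pd.DataFrame, national: NationalAverages = NationalAverages()
) -> tuple[pd.DataFrame, dict[str, LogisticFit]]:
    """Coverage-class odds ratios by tertiled practice characteristics.

    Drops practices with any missing characteristic or coverage, labels
    coverage classes, tertiles the six characteristics on the complete data,
    and reports per (characteristic, tertile): class counts, row percents,
    unadjusted ORs from the contingency table and mutually adjusted ORs from
    one all-characteristic logistic fit per contrast.

    Returns the tidy table and the two fitted models keyed ``mixed``/``above``.
    """
    needed = COVERAGE_COLS + CHARACTERISTICS
    complete = practices.dropna(subset=needed).copy()
    complete["coverage_class"] = assign_coverage_class(complete, national)
    tertiles = pd.DataFrame(
        {ch: tertile_cut(complete[ch]).labels for ch in CHARACTERISTICS}
    )
    design = _indicator_design(tertiles)

    fits: dict[str, LogisticFit] = {}
    for contrast in ("mixed", "above"):
        mask = complete["coverage_class"].isin(["below", contrast]).to_numpy()
        yy = (complete.loc[mask, "coverage_class"] == contrast).astype(int).to_numpy()
        fits[contrast] = fit_logistic(yy, design.loc[mask])

    rows = []
    for ch in CHARACTERISTICS:
        tab = (
            pd.crosstab(tertiles[ch], complete["coverage_class"])
            .reindex(index=TERTILE_LABELS, columns=CLASS_LABELS)
            .fillna(0)
            .astype(int)
        )
        ref = tab.loc["lowest"]
        for lvl in TERTILE_LABELS:
            cnt = tab.loc[lvl]
            n = int(cnt.sum())
            row: dict[str, object] = {
                "characteristic": ch,
                "tertile": lvl,
                "n": n,
                "n_below": int(cnt["below"]),
                "n_mixed": int(cnt["mixed"]),
                "n_above": int(cnt["above"]),
            }
            for cls in CLASS_LABELS:
                row[f"pct_{cls}"] = round(100.0 * cnt[cls] / n, 1) if n else math.nan
            for contrast in ("mixed", "above"):
                if lvl == "lowest":
                    row[f"or_{contrast}_unadj"] = 1.0
                    row[f"or_{contrast}_unadj_lo"] = math.nan
                    row[f"or_{contrast}_unadj_hi"] = math.nan
                    row[f"or_{contrast}_adj"] = 1.0
                    row[f"or_{contrast}_adj_lo"] = math.nan
                    row[f"or_{contrast}_adj_hi"] = math.nan
                    continue
                res = unadjusted_or(
                    int(cnt[contrast]), int(cnt["below"]), int(ref[contrast]), int(ref["below"])
                )
                row[f"or_{contrast}_unadj"] = res.estimate
                row[f"or_{contrast}_unadj_lo"] = res.ci_low
                row[f"or_{contrast}_unadj_hi"] = res.ci_high
                ors = fits[contrast].odds_ratios()
                key = f"{ch}_{lvl}"
                row[f"or_{contrast}_adj"] = float(ors.loc[key, "or"])
                row[f"or_{contrast}_adj_lo"] = float(ors.loc[key, "ci_low"])
                row[f"or_{contrast}_adj_hi"] = float(ors.loc[key, "ci_high"])
            rows.append(row)
    return pd.DataFrame(rows), fits
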