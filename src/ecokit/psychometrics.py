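"""Psychometric sigmoid fitting and assumption-driven group comparison.

The intensity-response curve of each animal is modelled as

    f(x) = b + L / (1 + exp(-k (x - x0)))

with baseline ``b``, span ``L``, slope ``k`` (per uA) and threshold ``x0``
(uA) — the stimulus intensity at the inflection point, i.e. at the
half-maximal response.  Responses are min-max scaled per animal and
intensities max-scaled before fitting; the threshold is reported back on
the uA scale.

Group comparisons follow the assumption-driven protocol: Shapiro-Wilk
normality and Levene homogeneity checks select a parametric (t / ANOVA /
repeated-measures ANOVA) or nonparametric (Mann-Whitney / Wilcoxon /
Kruskal-Wallis / Friedman) path, with Benjamini-Hochberg-adjusted pairwise
post hoc tests; the branch taken is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .exceptions import FitError, InputError
from .stats import (
    TestResult,
    benjamini_hochberg,
    mann_whitney_exact,
    spearman_exact,
    wilcoxon_exact,
)


def sigmoid(x, b: float, L: float, k: float, x0: float):
    """Overflow-safe evaluation of ``b + L / (1 + exp(-k (x - x0)))``."""
    z = np.clip(np.asarray(k * (np.asarray(x, dtype=float) - x0)), -700, 700)
    out = b + L * sps.logistic.cdf(z)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def normalize_for_fit(responses) -> np.ndarray:
    """Min-max scale one animal's responses to [0, 1] (order preserving)."""
    y = np.asarray(responses, dtype=float)
    if y.size < 2 or np.isclose(y.max(), y.min()):
        raise FitError("constant responses: normalization for fitting undefined")
    return (y - y.min()) / (y.max() - y.min())


@dataclass
class PsychometricFit:
    """Fitted sigmoid parameters and goodness of fit.

    ``b`` and ``L`` are on the scaled response axis; ``k`` is per uA and
    ``x0`` (the threshold) in uA.
    """

    b: float
    L: float
    k: float
    x0: float
    r2: float
    converged: bool
    message: str = ""

    @property
    def threshold(self) -> float:
        return self.x0

    def predict(self, x):
        return sigmoid(x, self.b, self.L, self.k, self.x0)


def fit_psychometric(intensities, responses, scale_responses: bool = True) -> PsychometricFit:
    """Nonlinear least-squares sigmoid fit of one animal's response curve.

    Intensities are max-scaled internally and the fitted slope and threshold
    mapped back to the uA scale.  Initial values: b = min(y), L = range(y),
    x0 = the level nearest the half-maximal response, k = 4 / range(x);
    bounds: L >= 0, b in [-1, 1] on the scaled axis (see inline note),
    x0 within the tested range, k in [0, 1] per uA.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise InputError("intensities and responses must have equal length")
    if np.unique(x).size < 4:
        raise InputError("need >= 4 distinct intensity levels (4 free parameters)")
    if scale_responses:
        y = normalize_for_fit(y)
    elif np.isclose(y.max(), y.min()):
        raise FitError("constant responses: fit degenerate")
    xmax = x.max()
    if xmax <= 0:
        raise InputError("intensities must include a positive level")
    xn = x / xmax

    half = y.min() + (y.max() - y.min()) / 2.0
    p0 = [y.min(), y.max() - y.min(), 4.0 / (xn.max() - xn.min()), xn[np.argmin(np.abs(y - half))]]
    # After min-max scaling the response at the lowest level maps to 0,
    # which sits *above* the sigmoid's lower asymptote, so the scaled-axis
    # baseline is slightly negative for any well-behaved curve; a hard
    # b >= 0 bound would bias the threshold.  The span stays nonnegative.
    lower = [-1.0, 0.0, 0.0, xn.min()]
    upper = [1.0, 1.5, 1.0 * xmax, xn.max()]  # k bound: [0, 1] per uA
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = optimize.curve_fit(
            sigmoid, xn, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as err:
        return PsychometricFit(
            b=np.nan, L=np.nan, k=np.nan, x0=np.nan, r2=np.nan,
            converged=False, message=str(err),
        )
    b, L, kn, x0n = popt
    r2 = goodness_of_fit_r2(y, sigmoid(xn, *popt))
    return PsychometricFit(
        b=float(b), L=float(L), k=float(kn / xmax), x0=float(x0n * xmax),
        r2=r2, converged=True,
    )


def goodness_of_fit_r2(observed, predicted) -> float:
    """Coefficient of determination, 1 - SSres/SStot (may be negative)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise InputError("zero total variance: R^2 undefined")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def goodness_of_fit(fit: PsychometricFit, intensities, responses) -> float:
    """R^2 of a fit against (scaled) data."""
    y = normalize_for_fit(responses)
    return goodness_of_fit_r2(y, fit.predict(np.asarray(intensities, dtype=float)))


@dataclass
class GroupComparisonResult:
    """Outcome of the assumption-driven group comparison."""

    test_name: str
    statistic: float
    p: float
    adjusted_p: float
    effect_size: float
    effect_size_name: str
    assumptions: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def _normality_ok(groups, alpha):
    ps = {}
    for name, g in groups.items():
        if len(g) >= 3:
            ps[name] = float(sps.shapiro(g).pvalue)
    return all(p > alpha for p in ps.values()), ps


def _two_group(a, b, paired, parametric, equal_var) -> tuple[str, TestResult, float, str]:
    if parametric:
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            name = "independent t-test" if equal_var else "Welch t-test"
        pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
        d = float((np.mean(a) - np.mean(b)) / pooled) if pooled > 0 else 0.0
        return name, TestResult(float(res.statistic), float(res.pvalue), exact=False), d, "cohen_d"
    if paired:
        res = wilcoxon_exact(a, b)
        n = np.sum(np.asarray(a) != np.asarray(b))
        rb = float(2.0 * res.statistic / (n * (n + 1) / 2.0) - 1.0) if n else 0.0
        return "Wilcoxon signed-rank", res, rb, "rank_biserial"
    res = mann_whitney_exact(a, b)
    rb = float(1.0 - 2.0 * res.statistic / (len(a) * len(b)))
    return "Mann-Whitney U", res, rb, "rank_biserial"


def compare_groups(
    groups: dict, paired: bool = False, alpha: float = 0.05, force: str | None = None
) -> GroupComparisonResult:
    """Compare >= 2 named groups of scalars with the protocol's test-selection rule.

    ``force`` may be ``"parametric"`` or ``"nonparametric"`` to bypass the
    assumption checks (their outcomes are still recorded).
    """
    if len(groups) < 2:
        raise InputError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 3 for a in arrays.values()):
        raise InputError("each group needs n >= 3")
    if paired and len({a.size for a in arrays.values()}) != 1:
        raise InputError("paired comparison requires equal group lengths")

    normal, shapiro_ps = _normality_ok(arrays, alpha)
    vals = list(arrays.values())
    levene_p = float(sps.levene(*vals).pvalue)
    homoscedastic = levene_p > alpha
    parametric = normal and homoscedastic
    if force == "parametric":
        parametric = True
    elif force == "nonparametric":
        parametric = False
    assumptions = {
        "shapiro_p": shapiro_ps,
        "levene_p": levene_p,
        "path": "parametric" if parametric else "nonparametric",
    }

    names = list(arrays)
    if len(arrays) == 2:
        name, res, es, es_name = _two_group(
            vals[0], vals[1], paired, parametric, equal_var=homoscedastic
        )
        stat, p = res.statistic, res.p
        posthoc = None
    else:
        if parametric:
            if paired:
                from statsmodels.stats.anova import AnovaRM

                long = pd.concat(
                    [
                        pd.DataFrame(
                            {"subject": np.arange(a.size), "group": k, "y": a}
                        )
                        for k, a in arrays.items()
                    ]
                )
                tbl = AnovaRM(long, "y", "subject", within=["group"]).fit().anova_table
                stat = float(tbl["F Value"].iloc[0])
                p = float(tbl["Pr > F"].iloc[0])
                name = "repeated-measures ANOVA"
            else:
                res = sps.f_oneway(*vals)
                stat, p = float(res.statistic), float(res.pvalue)
                name = "one-way ANOVA"
            grand = np.concatenate(vals)
            ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in vals)
            ss_tot = float(((grand - grand.mean()) ** 2).sum())
            es, es_name = (ss_between / ss_tot if ss_tot else 0.0), "eta_squared"
        else:
            if paired:
                res = sps.friedmanchisquare(*vals)
                name = "Friedman"
                k, n = len(vals), vals[0].size
                es, es_name = float(res.statistic / (n * (k - 1))), "kendall_w"
            else:
                res = sps.kruskal(*vals)
                name = "Kruskal-Wallis"
                n = sum(a.size for a in vals)
                es, es_name = float((res.statistic - len(vals) + 1) / (n - len(vals))), "epsilon_squared"
            stat, p = float(res.statistic), float(res.pvalue)
        rows = []
        for a_name, b_name in combinations(names, 2):
            pn, pres, pes, _ = _two_group(
                arrays[a_name], arrays[b_name], paired, parametric, equal_var=homoscedastic
            )
            rows.append(
                {"a": a_name, "b": b_name, "test": pn,
                 "statistic": pres.statistic, "p": pres.p, "effect_size": pes}
            )
        posthoc = pd.DataFrame(rows)
        posthoc["adjusted_p"] = benjamini_hochberg(posthoc["p"].to_numpy())

    return GroupComparisonResult(
        test_name=name,
        statistic=float(stat),
        p=float(p),
        adjusted_p=float(p),
        effect_size=float(es),
        effect_size_name=es_name,
        assumptions=assumptions,
        posthoc=posthoc,
    )


def correlate_thresholds(x, y) -> TestResult:
    """Spearman rank correlation between two threshold sets (two-sided p).

    Exact p by permutation enumeration at small n (see ``stats.spearman_exact``).
    """
    return spearman_exact(x, y)


def fit_table(
    responses: pd.DataFrame, channel_col: str | None = None
) -> pd.DataFrame:
    """Fit every animal in a zero-referenced response table.

    ``responses`` has columns ``animal_id``, ``intensity_uA``, ``response``
    (and optionally a channel column).  Animals whose fit fails are included
    with ``converged=False`` and excluded from downstream group statistics.
    """
    keys = ["animal_id"] + ([channel_col] if channel_col else [])
    rows = []
    for key, sub in responses.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        try:
            fit = fit_psychometric(sub["intensity_uA"], sub["response"])
        except (FitError, InputError) as err:
            fit = PsychometricFit(
                b=np.nan, L=np.nan, k=np.nan, x0=np.nan, r2=np.nan,
                converged=False, message=str(err),
            )
        rows.append(
            dict(zip(keys, key))
            | {"b": fit.b, "L": fit.L, "k": fit.k, "x0": fit.x0,
               "r2": fit.r2, "converged": fit.converged}
        )
    return pd.DataFrame(rows)
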