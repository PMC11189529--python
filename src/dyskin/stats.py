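"""Cohort-level statistics: nonparametric contrasts, effect sizes, FDR,
responder analysis, score correlations and TWSTRS score prediction.

Conventions
-----------
* Paired pre/post contrasts use the Wilcoxon signed-rank test with the
  matched-pairs rank-biserial correlation (W+ - W-)/(W+ + W-) on non-zero
  differences; positive effect = feature larger pre-operatively.
* Unpaired group contrasts use the Mann-Whitney U test with rank-biserial
  2*U_a/(n_a*n_b) - 1; positive effect = larger in group a.
* All tests are two-sided; multiplicity control is Benjamini-Hochberg FDR
  across the feature family of a single call; features are ranked by
  |effect size|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mean_rater_score",
    "holistic_score",
    "wilcoxon_effect",
    "mannwhitney_effect",
    "bh_fdr",
    "contrast_table",
    "responder_split",
    "responder_effect_difference",
    "feature_score_correlations",
    "sequential_feature_selection",
    "EffectResult",
    "SelectionResult",
]


@dataclass(frozen=True)
class EffectResult:
    p: float
    effect: float
    n: int
    statistic: float
    degenerate: bool = False


def mean_rater_score(scores: pd.DataFrame | np.ndarray) -> pd.Series | float:
    """Collapse rater x item scores into one mean score per item.

    Rows are raters, columns items; missing raters are ignored per item.
    A 1-D input is treated as several raters scoring a single item.
    """
    if isinstance(scores, pd.DataFrame):
        return scores.mean(axis=0, skipna=True)
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        return float(np.nanmean(arr))
    return pd.Series(np.nanmean(arr, axis=0))


def holistic_score(sub_scores) -> float:
    """Average of the available per-axis sub-item scores.

    Collapsing the ordinal sub-items into one mean defines a holistic
    severity measure; missing items are simply left out of the mean.
    """
    arr = np.asarray(sub_scores, dtype=float)
    if np.all(np.isnan(arr)):
        raise ValueError("no sub-scores available")
    return float(np.nanmean(arr))


def wilcoxon_effect(x_pre, x_post) -> EffectResult:
    """Paired Wilcoxon signed-rank test with matched-pairs rank-biserial.

    Zero differences are discarded (Wilcoxon's original treatment) for
    both the test and the effect size.  The effect is
    (W+ - W-)/(W+ + W-) with ranks taken on |pre - post|; positive values
    indicate the variable is larger pre.  All-zero differences yield a
    degenerate result (effect 0, p 1).
    """
    pre = np.asarray(x_pre, dtype=float)
    post = np.asarray(x_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    d = pre - post
    nz = d != 0
    if not nz.any():
        return EffectResult(p=1.0, effect=0.0, n=len(d), statistic=0.0, degenerate=True)
    dn = d[nz]
    ranks = sstats.rankdata(np.abs(dn))
    w_plus = float(ranks[dn > 0].sum())
    w_minus = float(ranks[dn < 0].sum())
    effect = (w_plus - w_minus) / (w_plus + w_minus)
    res = sstats.wilcoxon(dn, zero_method="wilcox", alternative="two-sided")
    return EffectResult(
        p=float(res.pvalue), effect=float(effect), n=int(nz.sum()),
        statistic=float(res.statistic),
    )


def mannwhitney_effect(x_a, x_b) -> EffectResult:
    """Mann-Whitney U test with rank-biserial effect 2*U_a/(n_a*n_b) - 1.

    U_a counts pairs where a > b, with half credit for ties; the effect is
    +1 for complete separation a above b, -1 for the reverse, 0 for
    stochastically equal groups.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided")
    u_a = float(res.statistic)
    effect = 2.0 * u_a / (len(a) * len(b)) - 1.0
    return EffectResult(
        p=float(res.pvalue), effect=float(effect), n=len(a) + len(b),
        statistic=u_a,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order).

    adj_(i) = min_{j >= i} (p_(j) * m / j), clipped at 1.  Monotone
    non-decreasing in the raw p, never smaller than it, and the identity
    for a single test.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _paired_arrays(
    cohort: pd.DataFrame, feature: str, cond_a: str, cond_b: str
) -> tuple[np.ndarray, np.ndarray]:
    wide = cohort.pivot_table(
        index="subject_id", columns="condition", values=feature, aggfunc="first"
    )
    wide = wide.dropna(subset=[cond_a, cond_b], how="any")
    return wide[cond_a].to_numpy(), wide[cond_b].to_numpy()


def _validate_pairs(cohort: pd.DataFrame, cond_a: str, cond_b: str) -> None:
    counts = cohort.groupby(["subject_id", "condition"]).size()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValueError(f"duplicate (subject, condition) rows: {list(dupes.index)}")
    have = cohort.groupby("subject_id")["condition"].agg(set)
    unmatched = sorted(s for s, c in have.items() if not {cond_a, cond_b} <= c)
    if unmatched:
        raise ValueError(
            f"paired design requires both conditions per subject; "
            f"unmatched subjects: {unmatched}"
        )


def contrast_table(
    cohort: pd.DataFrame,
    features: list[str],
    design: str = "paired",
    cond_a: str = "pre",
    cond_b: str = "post",
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature contrast with BH correction, ranked by |effect|.

    design='paired': Wilcoxon pre vs post within subjects (positive effect
    = larger pre).  design='unpaired': Mann-Whitney group_a vs group_b
    (positive effect = larger in group_a).  The FDR family is exactly the
    features passed in this one call.
    """
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    rows = []
    if design == "paired":
        _validate_pairs(cohort, cond_a, cond_b)
    else:
        if group_a is None or group_b is None:
            raise ValueError("unpaired design needs group_a and group_b")
        sub_a = cohort[cohort["group"] == group_a]
        sub_b = cohort[cohort["group"] == group_b]
        if len(sub_a) == 0 or len(sub_b) == 0:
            raise ValueError("empty group selection")
    for f in features:
        if design == "paired":
            a, b = _paired_arrays(cohort, f, cond_a, cond_b)
            res = wilcoxon_effect(a, b)
        else:
            res = mannwhitney_effect(sub_a[f].to_numpy(), sub_b[f].to_numpy())
        rows.append(
            {
                "feature": f,
                "n": res.n,
                "statistic": res.statistic,
                "p_raw": res.p,
                "effect": res.effect,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    out = out.sort_values("effect", key=lambda s: s.abs(), ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    cols = ["feature", "n", "statistic", "p_raw", "p_adj", "effect", "rank",
            "significant", "degenerate"]
    return out[cols].reset_index(drop=True)


def responder_split(pre_score: float, post_score: float, threshold: float = 0.30) -> str:
    """Classify a patient by relative clinical improvement after DBS.

    Responder iff (pre - post)/pre >= threshold (30% improvement counts as
    responder, inclusive boundary).  Undefined for pre_score = 0.
    """
    if pre_score <= 0:
        raise ValueError("relative improvement undefined for pre_score <= 0")
    improvement = (pre_score - post_score) / pre_score
    return "responder" if improvement >= threshold else "non_responder"


def responder_effect_difference(
    cohort: pd.DataFrame,
    features: list[str],
    responder_col: str = "responder",
    cond_a: str = "pre",
    cond_b: str = "post",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-feature pre/post effect size in responders minus non-responders.

    Positive differences mark features preferentially modulated in
    patients with a favourable DBS response.  A subgroup with fewer than
    ``min_pairs`` pairs flags the feature rather than failing.
    """
    resp = cohort[cohort[responder_col].astype(str).isin(["responder", "True", "true", "1"])]
    nonr = cohort[~cohort.index.isin(resp.index)]
    rows = []
    for f in features:
        entry = {"feature": f, "effect_responders": np.nan,
                 "effect_nonresponders": np.nan, "delta_effect": np.nan,
                 "flag": None}
        ra, rb = _paired_arrays(resp, f, cond_a, cond_b)
        na, nb = _paired_arrays(nonr, f, cond_a, cond_b)
        if len(ra) < min_pairs or len(na) < min_pairs:
            entry["flag"] = "subgroup too small"
        else:
            er = wilcoxon_effect(ra, rb).effect
            en = wilcoxon_effect(na, nb).effect
            entry.update(
                effect_responders=er, effect_nonresponders=en, delta_effect=er - en
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def feature_score_correlations(
    cohort: pd.DataFrame, features: list[str], scores: list[str]
) -> pd.DataFrame:
    """Pearson correlation of every feature against every clinical score.

    The BH family is all feature x score pairs of the call.  Pairs with
    fewer than 3 complete observations are missing.
    """
    rows = []
    for f in features:
        for s in scores:
            sub = cohort[[f, s]].dropna()
            if len(sub) < 3:
                rows.append({"feature": f, "score": s, "n": len(sub),
                             "r": np.nan, "p_raw": np.nan})
                continue
            r, p = sstats.pearsonr(sub[f], sub[s])
            rows.append({"feature": f, "score": s, "n": len(sub),
                         "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_fdr(out.loc[ok, "p_raw"].to_numpy())
    return out


@dataclass
class SelectionResult:
    selected: list[str]
    mae: float
    baseline_mae: float
    predictions: np.ndarray
    history: list[tuple[str, float]]


def _loo_mae(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Leave-one-out mean absolute error of OLS with intercept."""
    n = len(y)
    preds = np.empty(n)
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(Xd[mask], y[mask], rcond=None)
        preds[i] = Xd[i] @ beta
    return float(np.mean(np.abs(preds - y))), preds


def sequential_feature_selection(
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    candidates: list[str] | None = None,
    min_improvement: float = 1e-9,
) -> SelectionResult:
    """Additive (forward) feature selection for a linear score model.

    Starting from the intercept-only model, the candidate feature that
    most reduces the leave-one-out mean absolute error of the ordinary
    least-squares fit is added; selection stops when no candidate improves
    the criterion.  Features are standardised internally.  The candidate
    pool can be restricted (e.g. to static head-angle deviations only) to
    compare feature families.
    """
    y = np.asarray(target, dtype=float)
    if candidates is None:
        candidates = list(features.columns)
    X_all = features[candidates].astype(float)
    keep = np.isfinite(y) & X_all.notna().all(axis=1).to_numpy()
    y = y[keep]
    X_all = X_all.loc[keep]
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu = X_all.mean()
    sd = X_all.std(ddof=0).replace(0.0, 1.0)
    Z = ((X_all - mu) / sd).to_numpy()
    names = list(X_all.columns)

    baseline_mae, preds = _loo_mae(np.empty((n, 0)), y)
    selected: list[int] = []
    best_mae = baseline_mae
    history: list[tuple[str, float]] = []
    remaining = list(range(len(names)))
    while remaining:
        scores = []
        for j in remaining:
            mae, _ = _loo_mae(Z[:, selected + [j]], y)
            scores.append((mae, j))
        mae_new, j_best = min(scores)
        if mae_new < best_mae - min_improvement:
            selected.append(j_best)
            remaining.remove(j_best)
            best_mae = mae_new
            history.append((names[j_best], mae_new))
        else:
            break
    _, preds = _loo_mae(Z[:, selected], y)
    return SelectionResult(
        selected=[names[j] for j in selected],
        mae=best_mae,
        baseline_mae=baseline_mae,
        predictions=preds,
        history=history,
    )
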