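"""Model-guided bean segregation and statistical comparison of batches.

Beans are ranked by a model-predicted aroma attribute; the top and bottom
fractions (default 10%) become "high" and "low" prototype batches, and the
resulting groups (high / low / remainder) are compared on their TRUE
composition — class sums and odorant-series sums — by one-way ANOVA with
Tukey's HSD post-hoc test at alpha = 0.05, summarized as a compact letter
display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .grouping import aroma_targets


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def rank_and_select(predictions: pd.Series, fraction: float = 0.10):
    """Deterministic top/bottom selection by predicted value.

    Group size is ceil(fraction * n); ties are broken by bean id order.
    Returns ``(high_ids, low_ids)`` as lists.
    """
    preds = pd.Series(predictions, dtype=float)
    n = len(preds)
    k = int(np.ceil(fraction * n))
    if 2 * k > n:
        raise ConfigurationError(
            f"fraction {fraction} selects 2x{k} beans from only {n}: groups overlap"
        )
    # stable two-key sort: value, then id — deterministic under ties
    order = preds.reset_index()
    order.columns = ["bean_id", "value"]
    asc = order.sort_values(["value", "bean_id"], ascending=[True, True])
    low_ids = asc["bean_id"].head(k).tolist()
    desc = order.sort_values(["value", "bean_id"], ascending=[False, True])
    high_ids = desc["bean_id"].head(k).tolist()
    return high_ids, low_ids


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def compact_letter_display(group_names, means, significant) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i][j]`` is True when groups i and j differ; groups sharing
    a letter are not significantly different.  Starting from one set holding
    every group, each significant pair splits the sets containing both
    members; subsets of surviving sets are absorbed.  Letters are ordered by
    descending best group mean.
    """
    n = len(group_names)
    sets: list[set[int]] = [set(range(n))]
    for i in range(n):
        for j in range(i + 1, n):
            if not significant[i][j]:
                continue
            expanded: list[set[int]] = []
            for s in sets:
                if i in s and j in s:
                    expanded.append(s - {i})
                    expanded.append(s - {j})
                else:
                    expanded.append(s)
            kept: list[set[int]] = []
            for s in sorted(expanded, key=len, reverse=True):
                if s and not any(s <= t for t in kept):
                    kept.append(s)
            sets = kept
    sets.sort(key=lambda s: -max(means[i] for i in s))
    letters = {i: "" for i in range(n)}
    for pos, s in enumerate(sets):
        for i in s:
            letters[i] += chr(ord("a") + pos)
    return {group_names[i]: "".join(sorted(letters[i])) for i in letters}


def compare_groups(measured: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA + Tukey HSD over named groups of one attribute.

    Returns ``(anova_p, letters)`` with letters a compact letter display.
    If every group has zero within-group variance (exact separation), the
    ANOVA is undefined; p is reported as 0.0 when means differ (1.0 when
    they are all equal) and letters follow the mean ordering.
    """
    names = list(measured.keys())
    groups = [np.asarray(measured[g], dtype=float) for g in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigurationError("need >= 2 groups with >= 2 observations each")
    means = [float(g.mean()) for g in groups]
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within <= 0:
        distinct = len({round(m, 12) for m in means}) > 1
        p = 0.0 if distinct else 1.0
        sig = [
            [i != j and means[i] != means[j] for j in range(len(groups))]
            for i in range(len(groups))
        ]
        return p, compact_letter_display(names, means, sig)
    _, p = stats.f_oneway(*groups)
    if np.isnan(p):  # between-group SS cancels to ~0 (F microscopically < 0)
        p = 1.0
    tukey = stats.tukey_hsd(*groups)
    sig = (np.asarray(tukey.pvalue) < alpha).tolist()
    return float(p), compact_letter_display(names, means, sig)


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------


@dataclass
class SegregationResult:
    """Outcome of one segregation trial."""

    target: str
    fraction: float
    high_ids: list = field(default_factory=list)
    low_ids: list = field(default_factory=list)
    predictions: pd.Series = None
    group_stats: pd.DataFrame = None   # (group, attribute) -> mean, sd, n
    anova_p: pd.Series = None          # attribute -> p
    tukey_letters: pd.DataFrame = None  # group x attribute -> letter code
    degenerate_ties: bool = False

    def summary(self) -> pd.DataFrame:
        """mean ± sd table with significance letters, groups as rows."""
        mean = self.group_stats["mean"].unstack("attribute")
        return mean


def run_segregation_trial(
    X,
    profiles: pd.DataFrame,
    model,
    target: str,
    roster,
    fraction: float = 0.10,
    alpha: float = 0.05,
) -> SegregationResult:
    """Predict ``target`` per bean, select extreme fractions, compare groups.

    Parameters
    ----------
    X : (beans x bands) DataFrame or array
        Pre-treated spectra matching the model's training representation.
    profiles : beans x compounds DataFrame
        TRUE volatile profiles used for the group comparison.
    model : fitted PLS2Regression whose targets include ``target``.
    target : response name to segregate on (e.g. "Pyrazine" or "nutty").
    """
    bean_ids = (
        list(X.index) if isinstance(X, pd.DataFrame) else list(profiles.index)
    )
    y_hat = model.predict(np.asarray(X, dtype=float))
    y_hat = np.atleast_2d(y_hat.T).T
    try:
        col = model.target_names_.index(target)
    except ValueError:
        raise KeyError(f"model does not predict target {target!r}") from None
    predictions = pd.Series(y_hat[:, col], index=pd.Index(bean_ids, name="bean_id"))

    degenerate = predictions.nunique() == 1
    high_ids, low_ids = rank_and_select(predictions, fraction)
    rest_ids = [b for b in bean_ids if b not in set(high_ids) | set(low_ids)]

    truth = aroma_targets(profiles, roster)
    membership = {"high": high_ids, "low": low_ids, "remainder": rest_ids}

    stats_rows, p_vals, letter_rows = [], {}, {}
    for attr in truth.columns:
        groups = {g: truth.loc[ids, attr].to_numpy() for g, ids in membership.items()}
        p, letters = compare_groups(groups, alpha=alpha)
        p_vals[attr] = p
        letter_rows[attr] = letters
        for g, vals in groups.items():
            stats_rows.append(
                {
                    "group": g,
                    "attribute": attr,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                    "n": len(vals),
                }
            )
    group_stats = pd.DataFrame(stats_rows).set_index(["group", "attribute"])
    letters_df = pd.DataFrame(letter_rows)
    return SegregationResult(
        target=target,
        fraction=fraction,
        high_ids=high_ids,
        low_ids=low_ids,
        predictions=predictions,
        group_stats=group_stats,
        anova_p=pd.Series(p_vals),
        tukey_letters=letters_df,
        degenerate_ties=degenerate,
    )
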