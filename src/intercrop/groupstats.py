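"""Significance machinery for context comparisons.

One-way ANOVA across community contexts gates Tukey HSD pairwise
comparisons (both at alpha = 0.05 by default); results are rendered as a
compact letter display — contexts sharing a letter do not differ at alpha.
Letters are assigned deterministically by descending group mean, and the
display is invariant to input row order.  Welch's ANOVA is available as an
option for heteroscedastic groups.

The same machinery tests whether biological N2 fixation differs between
diversity levels, treating the weekly %Ndfa means as replicate
observations (fixation showed no week effect in the emulated trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["LetterDisplay", "compare_contexts", "diversity_effect_ndfa"]

log = logging.getLogger("intercrop.groupstats")


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display over groups.

    Groups sharing any letter have pairwise p >= alpha.  ``anova_p`` is the
    gating one-way ANOVA p-value; ``pairwise`` holds Tukey HSD p-values
    (empty when the gate did not reject).
    """

    letters: dict[str, str]
    means: dict[str, float]
    anova_p: float
    pairwise: dict[tuple[str, str], float]
    alpha: float
    excluded: tuple[str, ...] = ()

    @property
    def all_same(self) -> bool:
        return len(set(self.letters.values())) == 1


def _compact_letters(order: list[str], sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups by descending mean; ``sig_pairs`` the pairs that
    differ significantly.
    """
    sets: list[set[str]] = [set(order)]
    for pair in sorted(sig_pairs):
        a, b = pair
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another
        sets = [
            s for i, s in enumerate(new_sets)
            if not any(i != j and s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]
    # letter order follows the best-ranked member of each set
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    labels = {g: "" for g in order}
    for letter_idx, s in enumerate(sets):
        ch = chr(ord("a") + letter_idx)
        for g in s:
            labels[g] += ch
    return {g: "".join(sorted(v)) for g, v in labels.items()}


def compare_contexts(
    estimates: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> LetterDisplay:
    """Letter display over per-replicate estimates grouped by context.

    Groups with fewer than two estimates are excluded with a warning;
    at least two usable groups are required.  If the one-way ANOVA is not
    significant at ``alpha`` every group shares the letter 'a'; otherwise
    Tukey HSD pairwise p-values decide which groups separate.
    """
    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name in estimates:
        v = np.asarray(estimates[name], dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            excluded.append(name)
            log.warning("excluding context %r: %d usable estimate(s)", name, v.size)
            continue
        groups[name] = v
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 contexts with >= 2 estimates each; usable: {sorted(groups)}"
        )
    names = sorted(groups, key=lambda g: (-groups[g].mean(), g))
    samples = [groups[g] for g in names]
    if welch:
        anova_p = _welch_anova_p(samples)
    else:
        anova_p = float(stats.f_oneway(*samples).pvalue)
    means = {g: float(groups[g].mean()) for g in names}
    pairwise: dict[tuple[str, str], float] = {}
    sig_pairs: set[tuple[str, str]] = set()
    if anova_p < alpha:
        res = stats.tukey_hsd(*samples)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pair = tuple(sorted((names[i], names[j])))
                p = float(res.pvalue[i, j])
                pairwise[pair] = p
                if p < alpha:
                    sig_pairs.add(pair)
    letters = _compact_letters(names, sig_pairs)
    return LetterDisplay(
        letters=letters, means=means, anova_p=anova_p,
        pairwise=pairwise, alpha=alpha, excluded=tuple(sorted(excluded)),
    )


def _welch_anova_p(samples: list[np.ndarray]) -> float:
    """Welch's heteroscedasticity-robust one-way ANOVA p-value."""
    k = len(samples)
    ns = np.array([s.size for s in samples], dtype=float)
    means = np.array([s.mean() for s in samples])
    vars_ = np.array([s.var(ddof=1) for s in samples])
    w = ns / vars_
    mw = np.sum(w * means) / np.sum(w)
    num = np.sum(w * (means - mw) ** 2) / (k - 1)
    tmp = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f = num / den
    df2 = (k**2 - 1) / (3 * tmp)
    return float(stats.f.sf(f, k - 1, df2))


def diversity_effect_ndfa(
    ndfa_frame: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Test whether %Ndfa differs between diversity levels.

    Expects an ``ndfa_timeseries`` output frame (columns ``diversity`` and
    ``ndfa_mean``); the weekly means are the replicate observations.
    Returns a report with the ANOVA p-value, the letter display, and which
    levels differ from every other level (with a lower/higher label).
    """
    groups = {
        str(lvl): grp["ndfa_mean"].to_numpy()
        for lvl, grp in ndfa_frame.groupby("diversity", sort=True)
    }
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 diversity levels, got {sorted(groups)}"
        )
    display = compare_contexts(groups, alpha=alpha)
    distinct = []
    levels = sorted(display.letters)
    for lvl in levels:
        others = [o for o in levels if o != lvl]
        if others and all(
            display.pairwise.get(tuple(sorted((lvl, o))), 1.0) < alpha for o in others
        ):
            rest_mean = float(np.mean([display.means[o] for o in others]))
            distinct.append(
                {"level": lvl,
                 "relation": "lower" if display.means[lvl] < rest_mean else "higher"}
            )
    return {
        "anova_p": display.anova_p,
        "significant": display.anova_p < alpha,
        "letters": display.letters,
        "means": display.means,
        "pairwise_p": {f"{a}|{b}": p for (a, b), p in sorted(display.pairwise.items())},
        "distinct_levels": distinct,
        "alpha": alpha,
    }
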