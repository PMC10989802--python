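"""One-way ANOVA with Duncan's new multiple range test.

Used to test whether edge-distance distributions (or any grouped numeric
values) differ between networks / sign classes. Duncan's MRT compares the
ordered group means with a span-dependent critical range

    R_p = q*(p, df_error) * sqrt(MSE / n_h)

where ``n_h`` is the harmonic mean of the group sizes and ``q*`` is the
studentized-range quantile at Duncan's protection level
``1 - (1 - alpha)^(p - 1)`` for a span of ``p`` means. Group separations
are reported as a compact letter display: groups sharing a letter are not
significantly different.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

logger = logging.getLogger(__name__)


@dataclass
class PosthocResult:
    anova_f: float
    anova_p: float
    df_between: int
    df_error: int
    mse: float
    group_means: pd.Series          # ordered by descending mean
    group_sizes: pd.Series
    letters: dict[str, str]         # group -> compact letter string
    posthoc: str


def _letters_from_nonsig(groups: list[str], nonsig: np.ndarray) -> dict[str, str]:
    """Compact letter display from a boolean 'not significantly different' matrix.

    Groups are assumed ordered by mean; with a range test, non-significant
    sets are contiguous intervals, so letters correspond to the maximal
    intervals of mutual non-significance (insert-and-absorb outcome).
    """
    k = len(groups)
    intervals = []
    i = 0
    for i in range(k):
        j = i
        while j + 1 < k and all(nonsig[a][b]
                                for a in range(i, j + 2) for b in range(a + 1, j + 2)):
            j += 1
        intervals.append((i, j))
    # absorb intervals contained in an earlier one
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] for o in maximal):
            maximal.append(iv)
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in groups}
    for li, (a, b) in enumerate(maximal):
        ch = alphabet[li % len(alphabet)] * (li // len(alphabet) + 1)
        for idx in range(a, b + 1):
            letters[groups[idx]] += ch
    return letters


def anova_duncan(values, groups, alpha: float = 0.05, posthoc: str = "duncan"
                 ) -> PosthocResult:
    """One-way ANOVA followed by Duncan's MRT (or Tukey's HSD) letters.

    ``values`` and ``groups`` are equal-length sequences. Needs at least
    two groups with two observations each. When MSE is zero (all values
    identical within groups and between), F is undefined and every group
    shares one letter.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups, dtype=object)})
    sizes = df.groupby("group", sort=False)["value"].size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    means = df.groupby("group", sort=False)["value"].mean()
    grand = df["value"].mean()
    n = len(df)
    k = len(sizes)
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((df["value"] - means[df["group"]].values) ** 2).sum())
    df_b, df_e = k - 1, n - k
    mse = ss_within / df_e

    if mse == 0.0:
        logger.warning("anova_duncan: MSE = 0; F undefined, one shared letter")
        order = means.sort_values(ascending=False, kind="stable")
        return PosthocResult(float("nan"), float("nan"), df_b, df_e, 0.0,
                             order, sizes[order.index],
                             {g: "a" for g in order.index}, posthoc)

    f_stat = (ss_between / df_b) / mse
    p_val = float(f_dist.sf(f_stat, df_b, df_e))

    # order descending by mean; ties broken lexicographically for determinism
    order = means.reset_index()
    order = order.sort_values(["value", "group"], ascending=[False, True])
    glist = list(order["group"])
    m = means[glist].values
    n_h = k / float((1.0 / sizes[glist]).sum())  # harmonic mean group size
    se = np.sqrt(mse / n_h)

    nonsig = np.eye(k, dtype=bool)
    if posthoc == "duncan":
        # critical range for each span p = 2..k at Duncan's protection level
        spans = np.arange(2, k + 1)
        levels = 1.0 - (1.0 - alpha) ** (spans - 1)
        crit = {p: float(studentized_range.ppf(1.0 - lv, p, df_e)) * se
                for p, lv in zip(spans, levels)}
        # raw span test, then protection: a pair inside any non-significant
        # enclosing range is itself declared non-significant
        raw_ns = np.eye(k, dtype=bool)
        for i in range(k):
            for j in range(i + 1, k):
                raw_ns[i, j] = raw_ns[j, i] = (m[i] - m[j]) <= crit[j - i + 1]
        for i in range(k):
            for j in range(i + 1, k):
                ns = any(raw_ns[a, b] for a in range(0, i + 1)
                         for b in range(j, k))
                nonsig[i, j] = nonsig[j, i] = ns
    elif posthoc == "tukey":
        q = float(studentized_range.ppf(1.0 - alpha, k, df_e))
        for i in range(k):
            for j in range(i + 1, k):
                ns = (m[i] - m[j]) <= q * se
                nonsig[i, j] = nonsig[j, i] = ns
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}; choose duncan or tukey")

    letters = _letters_from_nonsig(glist, nonsig)
    return PosthocResult(float(f_stat), p_val, df_b, df_e, float(mse),
                         means[glist], sizes[glist], letters, posthoc)
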