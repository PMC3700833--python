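"""Relative qPCR quantification and group-comparison statistics.

Expression is quantified per biological replicate as 2^-ddCt against a
reference gene (5S rRNA in the original assay) and a calibrator group, then
summarized as mean +/- SE per group.  Group differences are assessed by
one-way ANOVA followed by Duncan's multiple range test, whose results are
reported in the conventional letter notation: groups sharing a letter are not
significantly different, lowercase at alpha = 0.05 and uppercase at 0.01.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_ct_table

__all__ = ["RelExpression", "ddct", "anova_oneway", "duncan_mrt", "duncan_letters"]


@dataclass
class RelExpression:
    """Replicate-level 2^-ddCt values and their per-group summary.

    The calibrator group goes through the same formula as every other group,
    so its mean equals 1 only in the zero-noise limit.
    """

    values: dict[str, np.ndarray]
    summary: pd.DataFrame  # index group; columns mean, se, n
    calibrator: str

    @property
    def groups(self) -> list[str]:
        return list(self.values)


def ddct(ct_table: pd.DataFrame, calibrator: str) -> RelExpression:
    """Per replicate: dCt = Ct_target - Ct_reference; ddCt subtracts the
    calibrator group's mean dCt; the reported value is 2^-ddCt.  Group means
    and standard errors are taken over the replicate values (SE = sample SD /
    sqrt(n)), matching error bars over biological replicates."""
    df = validate_ct_table(ct_table)
    wide = df.pivot_table(index=["group", "replicate"], columns="assay", values="ct")
    if wide["reference"].isna().any():
        missing = wide.index[wide["reference"].isna()].tolist()
        raise ValueError(f"missing reference Ct for records {missing}")
    dct = wide["target"] - wide["reference"]
    groups = list(dict.fromkeys(df["group"]))
    if calibrator not in groups:
        raise ValueError(f"calibrator group {calibrator!r} not present")
    cal_mean = dct.xs(calibrator, level="group").mean()
    rel = np.exp2(-(dct - cal_mean))
    values = {g: rel.xs(g, level="group").to_numpy(dtype=float) for g in groups}
    summary = pd.DataFrame(
        {
            "mean": [v.mean() for v in values.values()],
            "se": [v.std(ddof=1) / np.sqrt(len(v)) for v in values.values()],
            "n": [len(v) for v in values.values()],
        },
        index=pd.Index(groups, name="group"),
    )
    return RelExpression(values=values, summary=summary, calibrator=calibrator)


def anova_oneway(rel: RelExpression) -> tuple[float, float]:
    """One-way fixed-effects ANOVA on the replicate 2^-ddCt values."""
    arrays = list(rel.values.values())
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two replicates")
    grand = np.concatenate(arrays)
    if np.allclose(grand, grand[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def _pooled_mse(arrays: list[np.ndarray]) -> tuple[float, int]:
    df_err = sum(len(a) - 1 for a in arrays)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return (sse / df_err if df_err else 0.0), df_err


def duncan_letters(
    means: np.ndarray, n: float, mse: float, df_error: int, alpha: float
) -> list[str]:
    """Duncan letter grouping for group means (any order) with common
    per-group size n and error mean square from the ANOVA.

    The least significant range for p adjacent means is
    R_p = q(1 - alpha_p, p, df_error) * sqrt(MSE / n) with Duncan's protection
    level alpha_p = 1 - (1 - alpha)^(p - 1).  A pair of means differs iff
    their span exceeds R_p and no enclosing range was already declared
    homogeneous — so the homogeneous sets are exactly the maximal sorted
    intervals whose span is within their own R_p, and each such interval gets
    one letter.
    """
    k = len(means)
    order = np.argsort(means)
    sorted_means = means[order]
    if mse > 0:
        lsr = {
            p: stats.studentized_range.ppf(1.0 - (1.0 - (1.0 - alpha) ** (p - 1)), p, df_error)
            * np.sqrt(mse / n)
            for p in range(2, k + 1)
        }
    else:
        lsr = {p: 0.0 for p in range(2, k + 1)}

    def homogeneous(a: int, b: int) -> bool:
        if a == b:
            return True
        return sorted_means[b] - sorted_means[a] <= lsr[b - a + 1] + 1e-12

    intervals = [
        (a, b)
        for a in range(k)
        for b in range(a, k)
        if homogeneous(a, b)
    ]
    maximal = [
        (a, b)
        for (a, b) in intervals
        if not any((c <= a and b <= d) and (c, d) != (a, b) for (c, d) in intervals)
    ]
    maximal.sort()
    letters_sorted = ["" for _ in range(k)]
    for li, (a, b) in enumerate(maximal):
        letter = string.ascii_lowercase[li] if li < 26 else f"l{li}"
        for i in range(a, b + 1):
            letters_sorted[i] += letter
    out = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        out[orig] = letters_sorted[pos]
    return out


def duncan_mrt(rel: RelExpression, alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's multiple range test on the replicate values.

    Returns the group summary with a letter column at the requested alpha;
    uppercase letters are used at alpha <= 0.01, following the a/b/c vs A/B/C
    display convention.  Unbalanced designs fall back to the harmonic-mean
    group size with a warning.
    """
    arrays = list(rel.values.values())
    if len(arrays) < 2:
        raise ValueError("Duncan's test needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two replicates")
    sizes = np.array([len(a) for a in arrays], dtype=float)
    if len(set(sizes)) > 1:
        warnings.warn(
            "unbalanced groups: using the harmonic mean of group sizes",
            UserWarning,
            stacklevel=2,
        )
    n = len(sizes) / np.sum(1.0 / sizes)
    mse, df_err = _pooled_mse(arrays)
    means = np.array([a.mean() for a in arrays])
    letters = duncan_letters(means, n, mse, df_err, alpha)
    if alpha <= 0.01:
        letters = [l.upper() for l in letters]
    out = rel.summary.copy()
    out[f"letters_{alpha:g}"] = letters
    return out
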