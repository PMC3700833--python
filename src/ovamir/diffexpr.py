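"""Two-library differential expression for pooled digital counts.

The procedure is the classic one for era small-RNA studies with one pooled
library per condition: expression is normalized to reads per million clean
reads (NE), an NE of zero is imputed to 0.01 so log ratios stay finite, rows
with NE < 1 in both libraries are removed, and each remaining miRNA gets a
two-sided exact P-value from the Audic-Claverie conditional law

    p(y | x) = (N_b/N_a)^y * (x+y)! / ( x! * y! * (1 + N_b/N_a)^(x+y+1) )

— equivalently, y given x is negative-binomial with x+1 successes and success
probability N_a/(N_a+N_b), which is how the tails are evaluated here.  A miRNA
is called differentially expressed when |log2(NE_b/NE_a)| >= 1 and P <= 0.05
(both inclusive); ** marks P <= 0.01.  The test itself always runs on the raw
integer counts — imputation only exists to make ratios finite.

No multiple-testing correction is applied to the calls; a Benjamini-Hochberg
FDR column is emitted alongside for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "normalized_expression",
    "low_expression_filter",
    "exact_pvalue",
    "call_de",
    "de_report",
    "DEReport",
    "NE_IMPUTE",
    "NE_FLOOR",
]

NE_IMPUTE = 0.01   # NE assigned to a zero count
NE_FLOOR = 1.0     # rows below this NE in both libraries are removed
PER_MILLION = 1_000_000.0


def normalized_expression(raw: int, total: int) -> float:
    """Reads per million clean reads; a raw count of zero is imputed to 0.01."""
    if total <= 0:
        raise ValueError("library clean-read total must be positive")
    if raw < 0:
        raise ValueError("negative read count")
    if raw == 0:
        return NE_IMPUTE
    return PER_MILLION * raw / total


def low_expression_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Drop rows whose NE (post-imputation) is below 1 in BOTH libraries."""
    keep = (rows["ne_a"] >= NE_FLOOR) | (rows["ne_b"] >= NE_FLOOR)
    return rows.loc[keep]


def exact_pvalue(x: int, y: int, n_a: int, n_b: int) -> float:
    """Two-sided Audic-Claverie P-value for count x in library A (total n_a)
    against count y in library B (total n_b): twice the smaller tail of
    p(.|x), clipped to [0, 1].  Both tails include the observed y."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")
    p = n_a / (n_a + n_b)
    lower = nbinom.cdf(y, x + 1, p)
    upper = nbinom.sf(y - 1, x + 1, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _exact_pvalue_vec(x: np.ndarray, y: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    p = n_a / (n_a + n_b)
    lower = nbinom.cdf(y, x + 1, p)
    upper = nbinom.sf(y - 1, x + 1, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


@dataclass
class DEReport:
    """Summary of a DE run: direction counts, the high-fold subset, extrema."""

    n_up: int
    n_down: int
    n_equal: int
    high_fold: pd.DataFrame
    max_fold_up: float | None
    max_fold_down: float | None


def call_de(
    counts: CountTable,
    control: str | None = None,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Run the full pipeline: normalize -> impute -> NE<1 dual filter ->
    log2 ratio -> exact test -> threshold calls.

    ``control`` names the library used as denominator (library A, the
    immature-stage library in the original design); it defaults to the first
    column.  Returns one row per retained miRNA with columns ``ne_a``,
    ``ne_b``, ``log2_ratio``, ``fold_change`` (magnitude >= 1), ``direction``
    (up/down/equal relative to control), ``p_value``, ``sig_label`` and a
    supplementary ``bh_fdr`` column not used for calling.
    """
    libs = list(counts.counts.columns)
    if control is None:
        control = libs[0]
    if control not in libs:
        raise ValueError(f"control library {control!r} not in {libs}")
    lib_a = control
    lib_b = next(l for l in libs if l != control)
    n_a, n_b = counts.totals[lib_a], counts.totals[lib_b]

    df = pd.DataFrame(index=counts.counts.index)
    df["raw_a"] = counts.counts[lib_a]
    df["raw_b"] = counts.counts[lib_b]
    df["ne_a"] = [normalized_expression(r, n_a) for r in df["raw_a"]]
    df["ne_b"] = [normalized_expression(r, n_b) for r in df["raw_b"]]
    df = low_expression_filter(df)

    df = df.copy()
    df["log2_ratio"] = np.log2(df["ne_b"] / df["ne_a"])
    df["fold_change"] = np.exp2(np.abs(df["log2_ratio"]))
    df["p_value"] = _exact_pvalue_vec(
        df["raw_a"].to_numpy(), df["raw_b"].to_numpy(), n_a, n_b
    )
    significant = (np.abs(df["log2_ratio"]) >= lfc_min) & (df["p_value"] <= alpha)
    df["direction"] = "equal"
    df.loc[significant & (df["log2_ratio"] > 0), "direction"] = "up"
    df.loc[significant & (df["log2_ratio"] < 0), "direction"] = "down"
    df["sig_label"] = ""
    df.loc[significant, "sig_label"] = "*"
    df.loc[significant & (df["p_value"] <= 0.01), "sig_label"] = "**"
    if len(df):
        df["bh_fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["bh_fdr"] = pd.Series(dtype=float)
    df.index.name = "mirna"
    return df


def de_report(results: pd.DataFrame, fold_floor: float = 4.0) -> DEReport:
    """Summarize DE calls: up/down/equal counts, the rows above ``fold_floor``
    sorted by descending fold-change, and the per-direction maxima."""
    if results.empty:
        return DEReport(0, 0, 0, results, None, None)
    n_up = int((results["direction"] == "up").sum())
    n_down = int((results["direction"] == "down").sum())
    n_equal = int((results["direction"] == "equal").sum())
    called = results[results["direction"] != "equal"]
    high = called[called["fold_change"] > fold_floor].sort_values(
        "fold_change", ascending=False
    )
    up = called.loc[called["direction"] == "up", "fold_change"]
    down = called.loc[called["direction"] == "down", "fold_change"]
    return DEReport(
        n_up=n_up,
        n_down=n_down,
        n_equal=n_equal,
        high_fold=high,
        max_fold_up=float(up.max()) if len(up) else None,
        max_fold_down=float(down.max()) if len(down) else None,
    )
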