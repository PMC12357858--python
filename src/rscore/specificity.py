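"""Tumor-vs-normal differential statistics.

For each protein the component supplies three ranking metrics: the
two-sided Welch (unequal-variance) t-test p-value on log2-transformed
abundances, the fold change (ratio of group means with a pseudocount),
and the absolute change (difference of group means).  Lower p ranks
better; higher ratio and absolute change rank better.

No multiple-testing adjustment is applied: the ranking consumes raw
p-values, and a rank is invariant to any monotone adjustment anyway.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ComponentScore, QuantDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)

# smallest representable p for a zero-variance, unequal-means degenerate case
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class DiffStats:
    """Differential statistics for one protein."""

    p_diff: float
    ratio: float
    abs_change: float
    n_tumor: int
    n_normal: int


def differential_stats(
    tumor_values: np.ndarray | list[float],
    normal_values: np.ndarray | list[float],
    pseudocount: float,
) -> DiffStats:
    """Welch test on log2(value + pseudocount), plus ratio and difference.

    Requires >= 2 present values per group for the p-value and >= 1 per
    group for ratio / absolute change; with fewer than 2 per group the
    p-value is returned as NaN.  Two identical constant groups give
    p = 1 (zero t-statistic by convention).
    """
    tumor = np.asarray(pd.Series(tumor_values).dropna(), dtype=float)
    normal = np.asarray(pd.Series(normal_values).dropna(), dtype=float)
    if len(tumor) == 0 or len(normal) == 0:
        raise ValidationError("a group is entirely missing")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")

    abs_change = float(tumor.mean() - normal.mean())
    if pseudocount == 0 and normal.mean() == 0:
        raise ValidationError("ratio undefined: zero normal mean with zero pseudocount")
    ratio = float((tumor.mean() + pseudocount) / (normal.mean() + pseudocount))

    if len(tumor) < 2 or len(normal) < 2:
        p = float("nan")
    else:
        lt = np.log2(tumor + pseudocount)
        ln = np.log2(normal + pseudocount)
        if lt.std(ddof=1) == 0 and ln.std(ddof=1) == 0:
            # no within-group variability: zero t-statistic if the means
            # agree, otherwise infinitely significant (floored)
            p = 1.0 if lt.mean() == ln.mean() else _P_FLOOR
        else:
            with warnings.catch_warnings():
                # near-identical groups trip scipy's precision-loss warning;
                # the zero-variance cases are already handled above
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(lt, ln, equal_var=False).pvalue)
            p = max(p, _P_FLOOR)
    return DiffStats(
        p_diff=p,
        ratio=ratio,
        abs_change=abs_change,
        n_tumor=len(tumor),
        n_normal=len(normal),
    )


def default_pseudocount(dataset: QuantDataset) -> float:
    """Half the smallest nonzero abundance in the dataset (scale-aware)."""
    values = dataset.abundance.to_numpy(dtype=float)
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        return 0.5
    return float(positive.min() / 2.0)


def dataset_specificity(
    dataset: QuantDataset, pseudocount: float | None = None
) -> tuple[list[ComponentScore], pd.DataFrame]:
    """Per-protein tumor-vs-normal statistics for one dataset.

    Returns the three ComponentScores (p_diff, ratio, abs_change) and the
    underlying statistics table.  Proteins without at least one present
    value in each group are excluded (logged); proteins with one present
    value in a group keep ratio/abs_change but get no p-value.
    """
    tumor_samples = dataset.samples_for({"tumor"})
    normal_samples = dataset.samples_for({"normal"})
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise ValidationError(
            f"{dataset.dataset_id}: need >= 2 tumor and >= 2 normal samples"
        )
    if pseudocount is None:
        pseudocount = default_pseudocount(dataset)

    rows: dict[str, DiffStats] = {}
    skipped = one_group = 0
    for symbol in dataset.symbols:
        t = dataset.abundance.loc[symbol, tumor_samples].dropna()
        n = dataset.abundance.loc[symbol, normal_samples].dropna()
        if len(t) == 0 and len(n) == 0:
            skipped += 1
            continue
        if len(t) == 0 or len(n) == 0:
            # detected in one group only: undetected mean is 0, no p-value
            one_group += 1
            mt = float(t.mean()) if len(t) else 0.0
            mn = float(n.mean()) if len(n) else 0.0
            denom = mn + pseudocount
            rows[symbol] = DiffStats(
                p_diff=float("nan"),
                ratio=(mt + pseudocount) / denom if denom > 0 else float("nan"),
                abs_change=mt - mn,
                n_tumor=len(t),
                n_normal=len(n),
            )
            continue
        rows[symbol] = differential_stats(t.to_numpy(), n.to_numpy(), pseudocount)
    if skipped or one_group:
        logger.info(
            "%s: %d proteins undetected in both groups (excluded), %d detected "
            "in one group only (no p-value)",
            dataset.dataset_id, skipped, one_group,
        )

    table = pd.DataFrame(
        {
            "p_diff": {s: d.p_diff for s, d in rows.items()},
            "ratio": {s: d.ratio for s, d in rows.items()},
            "abs_change": {s: d.abs_change for s, d in rows.items()},
            "n_tumor": {s: d.n_tumor for s, d in rows.items()},
            "n_normal": {s: d.n_normal for s, d in rows.items()},
        }
    )
    table.index.name = "symbol"
    did = dataset.dataset_id
    scores = [
        ComponentScore(f"p_diff:{did}", did, "p_diff", table["p_diff"]),
        ComponentScore(f"ratio:{did}", did, "ratio", table["ratio"]),
        ComponentScore(f"abs_change:{did}", did, "abs_change", table["abs_change"]),
    ]
    return scores, table
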