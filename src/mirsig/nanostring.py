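"""nCounter count normalization and candidate-miRNA discovery.

The chain is: positive-control lane normalization -> top-100 global-mean
normalization -> background zeroing at mean + k*SD of the lane's negative
controls -> per-miRNA fold-change table (disease vs NC) -> candidate filter
(|fold| >= 1.5, mean normalized counts > 150).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, SampleSheet, ValidationError


@dataclass
class NormalizedCounts:
    """Counts after lane and global-mean scaling, with background bookkeeping.

    ``zeroed`` flags endogenous cells converted to zero by the background
    rule; ``background`` holds the per-lane negative-control mean and SD used
    (NaN until :func:`background_zero` has run).
    """

    values: pd.DataFrame
    probe_class: pd.Series
    lanes: pd.DataFrame
    zeroed: pd.DataFrame
    background: pd.DataFrame

    def as_count_matrix(self) -> CountMatrix:
        return CountMatrix(self.values, self.probe_class, self.lanes)

    def sample_means(self) -> pd.DataFrame:
        """Average replicate lanes to one column per sample (endogenous only)."""
        endog = self.values.loc[self.probe_class == "endogenous"]
        return endog.T.groupby(self.lanes["sample_id"]).mean().T


def lane_normalize(raw: CountMatrix) -> CountMatrix:
    """Remove lane-to-lane scale via positive-control sums.

    Each lane is multiplied by (grand mean of positive-control sums) /
    (its own positive-control sum), so the positive-control content becomes
    equal across lanes.
    """
    pos = raw.probes_of_class("positive_control")
    if len(pos) == 0:
        raise ValidationError("no positive-control probes present")
    sums = raw.counts.loc[pos].sum(axis=0)
    dead = sums.index[sums <= 0]
    if len(dead):
        raise ValidationError(
            f"lane(s) with zero positive-control signal: {list(dead)}"
        )
    factors = sums.mean() / sums
    return CountMatrix(raw.counts.mul(factors, axis=1), raw.probe_class, raw.lanes)


def global_mean_normalize(m: CountMatrix, top_n: int = 100) -> NormalizedCounts:
    """Content normalization on the mean of each lane's top-``top_n`` endogenous
    counts, scaled to the across-lane grand mean of those means.

    Top-``top_n`` selection breaks count ties by probe name so the scale
    factors are deterministic.
    """
    endog = m.probes_of_class("endogenous")
    if len(endog) < top_n:
        raise ValidationError(
            f"need >= {top_n} endogenous probes, found {len(endog)}"
        )
    sub = m.counts.loc[endog]
    # sort by (count desc, name asc) once per lane; deterministic under ties
    order_names = sub.index.sort_values()
    sub = sub.loc[order_names]
    top_means = pd.Series(
        {
            lane: sub[lane].sort_values(ascending=False, kind="stable")
            .iloc[:top_n]
            .mean()
            for lane in sub.columns
        }
    )
    if (top_means <= 0).any():
        bad = list(top_means.index[top_means <= 0])
        raise ValidationError(f"lane(s) with non-positive top-{top_n} mean: {bad}")
    factors = top_means.mean() / top_means
    values = m.counts.mul(factors, axis=1)
    zeroed = pd.DataFrame(False, index=values.index, columns=values.columns)
    background = pd.DataFrame(
        np.nan, index=pd.Index(values.columns, name="lane_id"), columns=["mean", "sd"]
    )
    return NormalizedCounts(values, m.probe_class, m.lanes, zeroed, background)


def background_zero(m: NormalizedCounts, k: float = 2.0) -> NormalizedCounts:
    """Zero endogenous values below the lane's background threshold.

    Threshold per lane = mean + ``k`` * SD (sample SD, n-1) of that lane's
    negative-control values; endogenous values *below* the threshold become 0
    and are flagged (values equal to the threshold are kept); control probes
    are untouched.
    """
    neg = m.values.index[m.probe_class == "negative_control"]
    if len(neg) < 2:
        raise ValidationError("need >= 2 negative-control probes per lane")
    bg = m.values.loc[neg]
    means = bg.mean(axis=0)
    sds = bg.std(axis=0, ddof=1)
    thresholds = means + k * sds
    below = m.values.lt(thresholds, axis=1)
    below.loc[m.probe_class != "endogenous"] = False
    values = m.values.mask(below, 0.0)
    background = pd.DataFrame(
        {"mean": means, "sd": sds}, index=pd.Index(m.values.columns, name="lane_id")
    )
    return NormalizedCounts(
        values, m.probe_class, m.lanes, m.zeroed | below, background
    )


def fold_change_table(
    m: NormalizedCounts,
    sheet: SampleSheet,
    grouping: str = "AD_MCI_vs_NC",
) -> pd.DataFrame:
    """Per-miRNA disease-vs-NC fold changes on normalized, sample-averaged counts.

    Fold change is NC mean / disease mean, so down-regulated miRNAs report
    values > 1 and up-regulated ones values < 1. The p-value is a two-sided
    Welch t-test on log2 values, excluding zeroed cells.
    """
    if grouping not in {"AD_MCI_vs_NC", "AD_vs_NC"}:
        raise ValueError(f"unknown grouping {grouping!r}")
    disease_labels = {"AD", "MCI"} if grouping == "AD_MCI_vs_NC" else {"AD"}
    per_sample = m.sample_means()
    diagnosis = sheet.diagnosis_of(per_sample.columns)
    disease_cols = per_sample.columns[diagnosis.isin(disease_labels).to_numpy()]
    nc_cols = per_sample.columns[(diagnosis == "NC").to_numpy()]
    if len(disease_cols) == 0 or len(nc_cols) == 0:
        raise ValidationError("both disease and NC groups must be non-empty")

    dis = per_sample[disease_cols]
    nc = per_sample[nc_cols]
    mean_disease = dis.mean(axis=1)
    mean_nc = nc.mean(axis=1)
    mean_count = per_sample[list(disease_cols) + list(nc_cols)].mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_nc / mean_disease
    undefined = (mean_disease == 0) | (mean_nc == 0)
    fc = fc.mask(undefined)

    direction = pd.Series("none", index=per_sample.index)
    direction[fc > 1] = "down"
    direction[fc < 1] = "up"
    direction[undefined] = "undefined"

    pvals = np.full(len(per_sample), np.nan)
    dis_a, nc_a = dis.to_numpy(), nc.to_numpy()
    for i in range(len(per_sample)):
        d = dis_a[i][dis_a[i] > 0]
        n = nc_a[i][nc_a[i] > 0]
        if len(d) >= 2 and len(n) >= 2:
            pvals[i] = stats.ttest_ind(
                np.log2(d), np.log2(n), equal_var=False
            ).pvalue

    return pd.DataFrame(
        {
            "mean_disease": mean_disease,
            "mean_nc": mean_nc,
            "fold_change": fc,
            "direction": direction,
            "mean_count": mean_count,
            "p_value": pvals,
        },
        index=per_sample.index.rename("mirna"),
    )


def filter_candidates(
    table: pd.DataFrame, min_fc: float = 1.5, min_mean_count: float = 150.0
) -> pd.DataFrame:
    """Candidate rule: |fold difference| >= ``min_fc`` in either direction
    ("at least 1.5 fold") AND mean normalized counts strictly > ``min_mean_count``.

    Returns the table with ``pass_fc``/``pass_count`` flags, restricted to the
    passing rows; applying the filter twice is a no-op.
    """
    fc = table["fold_change"]
    with np.errstate(divide="ignore"):
        magnitude = np.maximum(fc, 1.0 / fc)
    pass_fc = (magnitude >= min_fc).fillna(False)
    pass_count = table["mean_count"] > min_mean_count
    out = table.copy()
    out["pass_fc"] = pass_fc
    out["pass_count"] = pass_count
    return out[pass_fc & pass_count]
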