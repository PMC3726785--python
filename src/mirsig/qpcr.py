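"""TaqMan ddCt relative quantification and rank-invariant reference selection.

dCt = observed Ct minus a per-sample reference aggregate (by default the
geometric mean of the spike-in and endogenous-reference Ct values); ddCt
calibrates dCt against the NC group mean; linear fold change is 2**-ddCt.
The endogenous reference is picked as the assay whose within-sample
expression rank varies least across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CtMatrix, SampleSheet, ValidationError
from .nanostring import NormalizedCounts


@dataclass
class RelativeExpression:
    """Per-(sample, miRNA) relative quantification results.

    ``dct`` rows are target miRNAs, columns samples (cycles). ``ddct`` and
    ``linear_fc`` (2**-ddct) are filled by :func:`ddct_fold_change`;
    ``summary`` holds the per-miRNA group fold change and Welch p-value.
    """

    dct: pd.DataFrame
    references: tuple
    ref_aggregate: str = "geomean_ct"
    ddct: pd.DataFrame | None = None
    linear_fc: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    nc_samples: tuple = field(default_factory=tuple)


def rank_variances(expr: pd.DataFrame) -> pd.Series:
    """Across-sample variance of each assay's within-sample expression rank.

    ``expr`` rows are assays, columns samples, higher value = more abundant.
    Rank 1 = most abundant; ties share average ranks.
    """
    ranks = np.apply_along_axis(
        lambda col: stats.rankdata(-col, method="average"), 0, expr.to_numpy()
    )
    return pd.Series(np.var(ranks, axis=1, ddof=1), index=expr.index)


def select_rank_invariant(
    m: NormalizedCounts | CtMatrix | pd.DataFrame,
    retain_fraction: float = 0.25,
    drop_fraction: float = 0.10,
) -> str:
    """Pick the most rank-invariant assay as endogenous normalizer.

    Assays are ranked within each sample by expression (for Ct input,
    ascending Ct = descending expression); the worst ``drop_fraction`` of
    surviving assays (by across-sample rank variance, at least one per round)
    are discarded until ``retain_fraction`` of the panel remains; the survivor
    with minimal rank variance wins. Ties break toward higher mean expression,
    then lexicographically smaller name.
    """
    if isinstance(m, NormalizedCounts):
        expr = m.sample_means()
    elif isinstance(m, CtMatrix):
        expr = -m.ct.loc[m.assay_role != "spike_in"]
    else:
        expr = m
    if expr.isna().any().any():
        raise ValidationError("missing values among considered assays")
    if len(expr) < 3 or expr.shape[1] < 3:
        raise ValidationError("need at least 3 assays and 3 samples")

    survivors = expr.copy()
    target = max(3, int(np.ceil(retain_fraction * len(expr))))
    while len(survivors) > target:
        rv = rank_variances(survivors)
        n_drop = min(
            max(1, int(np.ceil(drop_fraction * len(survivors)))),
            len(survivors) - target,
        )
        # worst variance first; ties drop lower-expressed assays, then by name
        order = pd.DataFrame(
            {"rv": rv, "mean_expr": survivors.mean(axis=1), "name": rv.index}
        ).sort_values(["rv", "mean_expr", "name"], ascending=[False, True, True])
        survivors = survivors.drop(order.index[:n_drop])

    rv = rank_variances(survivors)
    ranking = pd.DataFrame(
        {"rv": rv, "mean_expr": survivors.mean(axis=1), "name": rv.index}
    ).sort_values(["rv", "mean_expr", "name"], ascending=[True, False, True])
    return str(ranking.index[0])


def relative_ct(ct: CtMatrix, refs: list[str], ref_aggregate: str = "geomean_ct") -> RelativeExpression:
    """dCt stage: per-sample reference aggregate subtracted from target Cts.

    ``geomean_ct`` takes the geometric mean of the reference Ct values
    themselves (sqrt(Ct1*Ct2) for two references); ``mean_ct`` takes their
    arithmetic mean (the usual multi-reference convention). Missing target Ct
    propagates as missing; a missing reference Ct is an error.
    """
    if ref_aggregate not in {"geomean_ct", "mean_ct"}:
        raise ValueError(f"unknown ref_aggregate {ref_aggregate!r}")
    missing_refs = [r for r in refs if r not in ct.assays]
    if missing_refs:
        raise ValidationError(f"reference assay(s) absent: {missing_refs}")
    ref_ct = ct.ct.loc[list(refs)]
    if ref_ct.isna().any().any():
        bad = ref_ct.stack(future_stack=True)
        bad = bad[bad.isna()].index[0]
        raise ValidationError(
            f"missing reference Ct for sample {bad[1]!r}, assay {bad[0]!r}"
        )
    if ref_aggregate == "geomean_ct":
        aggregate = np.exp(np.log(ref_ct).mean(axis=0))
    else:
        aggregate = ref_ct.mean(axis=0)
    targets = [a for a in ct.assays if a not in set(refs)]
    dct = ct.ct.loc[targets].sub(aggregate, axis=1)
    return RelativeExpression(dct=dct, references=tuple(refs), ref_aggregate=ref_aggregate)


def ddct_fold_change(r: RelativeExpression, sheet: SampleSheet) -> RelativeExpression:
    """Calibrate dCt against the NC mean and derive linear fold changes.

    ddCt = dCt - mean(dCt over NC samples), per miRNA; per-sample linear value
    2**-ddCt; group fold change reported as 2**(mean AD ddCt), so
    down-regulation in AD gives values > 1. The p-value is a two-sided Welch
    t-test on dCt (AD vs NC); missing values are excluded pairwise.
    """
    diagnosis = sheet.diagnosis_of(r.dct.columns)
    nc_cols = r.dct.columns[(diagnosis == "NC").to_numpy()]
    ad_cols = r.dct.columns[(diagnosis == "AD").to_numpy()]
    if len(nc_cols) == 0:
        raise ValidationError("no NC samples to calibrate against")
    nc_mean = r.dct[nc_cols].mean(axis=1)
    if nc_mean.isna().any():
        bad = list(nc_mean.index[nc_mean.isna()])
        raise ValidationError(f"no defined NC dCt for miRNA(s): {bad}")
    ddct = r.dct.sub(nc_mean, axis=0)
    linear = 2.0 ** (-ddct)

    rows = []
    for mirna in ddct.index:
        ad = ddct.loc[mirna, ad_cols].dropna()
        nc = ddct.loc[mirna, nc_cols].dropna()
        fc = 2.0 ** ad.mean() if len(ad) else np.nan
        p = (
            stats.ttest_ind(ad, nc, equal_var=False).pvalue
            if len(ad) >= 2 and len(nc) >= 2
            else np.nan
        )
        rows.append(
            {
                "mirna": mirna,
                "fold_change": fc,
                "direction": "down" if fc > 1 else ("up" if fc < 1 else "none"),
                "p_value": p,
                "n_ad": len(ad),
                "n_nc": len(nc),
            }
        )
    summary = pd.DataFrame(rows).set_index("mirna")
    return RelativeExpression(
        dct=r.dct,
        references=r.references,
        ref_aggregate=r.ref_aggregate,
        ddct=ddct,
        linear_fc=linear,
        summary=summary,
        nc_samples=tuple(nc_cols),
    )
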