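"""In-memory two-cohort study runs for benchmarking and replication.

`run_study` executes the complete chain — simulate discovery counts,
normalize, filter candidates, simulate TaqMan validation for both cohorts,
ddCt-quantify, exhaustive LDA search — without touching disk, so
multi-seed replication loops stay cheap. The file-writing pipeline in
:mod:`mirsig.pipeline` composes the same stage operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .nanostring import (
    background_zero,
    filter_candidates,
    fold_change_table,
    global_mean_normalize,
    lane_normalize,
)
from .qpcr import ddct_fold_change, relative_ct
from .signature import MetricsReport, evaluate_signatures
from .synthetic import (
    ENDOGENOUS_REFERENCE,
    SIGNATURE_MIRNAS,
    SPIKE_IN,
    SimulationConfig,
    simulate_nanostring,
    simulate_qpcr,
    simulate_sheet,
)


@dataclass
class StudyResult:
    """Everything one synthetic study run produces."""

    candidates: pd.DataFrame
    summary_cohort1: pd.DataFrame
    summary_cohort2: pd.DataFrame
    validated_panel: list
    reports: list = field(default_factory=list)

    @property
    def best(self) -> MetricsReport | None:
        if not self.reports:
            return None
        return max(self.reports, key=lambda r: (r.auc, r.accuracy))


def quantify_cohorts(
    config: SimulationConfig,
    sheet,
    panel: list[str],
    refs=(SPIKE_IN, ENDOGENOUS_REFERENCE),
    ref_aggregate: str = "geomean_ct",
) -> dict:
    """Simulate and ddCt-quantify the AD/NC validation assays per cohort."""
    out = {}
    for cohort in (1, 2):
        csheet = sheet.subset(cohort=cohort, diagnoses={"AD", "NC"})
        ct = simulate_qpcr(config, csheet, panel)
        rel = ddct_fold_change(
            relative_ct(ct, list(refs), ref_aggregate=ref_aggregate), csheet
        )
        out[cohort] = (rel, csheet)
    return out


def search_signatures(quant: dict, validated: list, priors: str = "empirical"):
    """Exhaustive subset search: fit on cohort 1, score on cohort 2."""
    (rel1, sheet1), (rel2, sheet2) = quant[1], quant[2]
    train_x = rel1.dct.loc[list(validated)].T
    test_x = rel2.dct.loc[list(validated)].T
    return evaluate_signatures(
        train_x,
        sheet1.diagnosis_of(train_x.index).to_numpy(),
        test_x,
        sheet2.diagnosis_of(test_x.index).to_numpy(),
        panel=list(validated),
        priors=priors,
    )


def run_study(
    config: SimulationConfig,
    grouping: str = "AD_MCI_vs_NC",
    min_fc: float = 1.5,
    min_count: float = 150.0,
    validation_min_fc: float = 1.5,
    validation_max_p: float = 0.05,
    qpcr_panel: list[str] | None = None,
) -> StudyResult:
    """One end-to-end study at the configured sizes and planted effects.

    ``qpcr_panel`` overrides the assays carried into TaqMan validation
    (default: the discovery candidates); the reference assays are always
    appended.
    """
    sheet = simulate_sheet(config)
    counts, disc_sheet = simulate_nanostring(config, sheet)
    normed = background_zero(global_mean_normalize(lane_normalize(counts)))
    table = fold_change_table(normed, disc_sheet, grouping=grouping)
    candidates = filter_candidates(table, min_fc=min_fc, min_mean_count=min_count)

    carried = list(candidates.index) if qpcr_panel is None else list(qpcr_panel)
    panel = sorted(set(carried) | {ENDOGENOUS_REFERENCE}) + [SPIKE_IN]
    quant = quantify_cohorts(config, sheet, panel)
    s1, s2 = quant[1][0].summary, quant[2][0].summary

    validated = [
        m
        for m in s1.index
        if s1.loc[m, "fold_change"] > validation_min_fc
        and s1.loc[m, "p_value"] < validation_max_p
    ]
    result = StudyResult(
        candidates=candidates,
        summary_cohort1=s1,
        summary_cohort2=s2,
        validated_panel=validated,
    )
    if validated:
        result.reports = search_signatures(quant, validated)
    return result


def null_study_reports(config: SimulationConfig) -> list:
    """Held-out signature reports when nothing is planted.

    Runs the TaqMan/search stages on the seven signature assays with all
    fold changes forced to 1, for null-calibration checks.
    """
    null_cfg = SimulationConfig(
        **{
            **config.__dict__,
            "effect_table": {m: 1.0 for m in SIGNATURE_MIRNAS},
            "effect_table_cohort2": {m: 1.0 for m in SIGNATURE_MIRNAS},
        }
    )
    sheet = simulate_sheet(null_cfg)
    panel = sorted(SIGNATURE_MIRNAS) + [ENDOGENOUS_REFERENCE, SPIKE_IN]
    quant = quantify_cohorts(null_cfg, sheet, panel)
    return search_signatures(quant, sorted(SIGNATURE_MIRNAS))
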