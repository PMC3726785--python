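"""End-to-end pipeline: simulate -> normalize -> discover -> quantify -> search.

All randomness flows from the single seed in the configuration; the stages
themselves are deterministic, so rerunning with an identical config
reproduces identical output files byte for byte (the run log carries no
timestamps for the same reason).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .datatypes import CountMatrix, SampleSheet
from .nanostring import (
    background_zero,
    filter_candidates,
    fold_change_table,
    global_mean_normalize,
    lane_normalize,
)
from .qpcr import ddct_fold_change, relative_ct, select_rank_invariant
from .signature import (
    POSITIVE,
    evaluate_signatures,
    rank_signatures,
    reports_table,
)
from .synthetic import (
    ENDOGENOUS_REFERENCE,
    SPIKE_IN,
    SimulationConfig,
    simulate_nanostring,
    simulate_qpcr,
    simulate_sheet,
)

log = logging.getLogger("mirsig")


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run.

    Stage defaults are the study's stated values: top-100 global mean, 2-SD
    background rule, 1.5-fold / >150-count candidate rule, spike-in +
    endogenous-reference ddCt, and specificity > 0.9 / sensitivity > 0.8 /
    AUC > 0.9 signature cutoffs. ``select_reference`` replaces the named
    endogenous reference with the rank-invariant pick (opt-in, as the
    selection is normally run once per platform).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    counts_path: str | None = None
    sheet_path: str | None = None
    top_n: int = 100
    bg_k: float = 2.0
    grouping: str = "AD_MCI_vs_NC"
    min_fc: float = 1.5
    min_count: float = 150.0
    validation_min_fc: float = 1.5
    validation_max_p: float = 0.05
    ref_aggregate: str = "geomean_ct"
    select_reference: bool = False
    retain_fraction: float = 0.25
    drop_fraction: float = 0.10
    priors: str = "empirical"
    min_spec: float = 0.9
    min_sens: float = 0.8
    min_auc: float = 0.9
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation = self.simulation.with_seed(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["baseline_ct_range"] = list(
            d["simulation"]["baseline_ct_range"]
        )
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str, rows_in: int, rows_out: int) -> None:
    log.info("stage=%s rows_in=%d rows_out=%d", name, rows_in, rows_out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing tables under ``config.outdir``.

    Returns a dict with the in-memory results (candidate table, per-cohort
    quantification, signature reports) and the paths written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write_yaml(outdir / "resolved_config.yaml")

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    sim = config.simulation
    # --- inputs ------------------------------------------------------------
    if config.counts_path is not None:
        raw = mio.read_count_matrix(config.counts_path)
        sheet = mio.read_sample_sheet(config.sheet_path)
        disc_sheet = sheet.subset(cohort=1)
    else:
        sheet = simulate_sheet(sim)
        raw, disc_sheet = simulate_nanostring(sim, sheet)
        mio.write_count_matrix(raw, outdir / "nanostring_counts.tsv")
        mio.write_sample_sheet(sheet, outdir / "sample_sheet.csv")
    _stage("input", raw.counts.shape[0], raw.counts.shape[1])

    # --- normalization chain ----------------------------------------------
    lane_norm = lane_normalize(raw)
    normed = background_zero(
        global_mean_normalize(lane_norm, top_n=config.top_n), k=config.bg_k
    )
    _stage("normalize", raw.counts.shape[0], normed.values.shape[0])

    # --- discovery ----------------------------------------------------------
    table = fold_change_table(normed, disc_sheet, grouping=config.grouping)
    candidates = filter_candidates(
        table, min_fc=config.min_fc, min_mean_count=config.min_count
    )
    table.to_csv(outdir / "fold_change_table.tsv", sep="\t")
    candidates.to_csv(outdir / "candidate_table.tsv", sep="\t")
    _stage("discover", len(table), len(candidates))
    results: dict = {
        "fold_change_table": table,
        "candidates": candidates,
        "outdir": outdir,
    }
    if len(candidates) == 0:
        log.warning("no candidate miRNAs passed the filter; stopping after discovery")
        return results

    # --- reference selection ------------------------------------------------
    endo_ref = ENDOGENOUS_REFERENCE
    if config.select_reference:
        endo_ref = select_rank_invariant(
            normed,
            retain_fraction=config.retain_fraction,
            drop_fraction=config.drop_fraction,
        )
        log.info("stage=select_reference assay=%s", endo_ref)
    refs = [SPIKE_IN, endo_ref]
    results["endogenous_reference"] = endo_ref

    # --- TaqMan validation (simulated assays on the candidate panel) -------
    panel = sorted(set(candidates.index) | {endo_ref, ENDOGENOUS_REFERENCE}) + [
        SPIKE_IN
    ]
    summaries = {}
    rels = {}
    for cohort in (1, 2):
        csheet = sheet.subset(cohort=cohort, diagnoses={"AD", "NC"})
        ct = simulate_qpcr(sim, csheet, panel)
        mio.write_ct_matrix(ct, outdir / f"ct_cohort{cohort}.tsv")
        rel = ddct_fold_change(
            relative_ct(ct, refs, ref_aggregate=config.ref_aggregate), csheet
        )
        mio.write_relative_expression(
            rel, outdir / f"relative_expression_cohort{cohort}.tsv"
        )
        rels[cohort] = (rel, csheet)
        summaries[cohort] = rel.summary
        _stage(f"quantify_cohort{cohort}", len(panel), len(rel.summary))
    summary = pd.concat(
        {f"cohort{c}": s[["fold_change", "p_value"]] for c, s in summaries.items()},
        axis=1,
    )
    summary.to_csv(outdir / "group_fold_changes.tsv", sep="\t")
    results["quantification"] = summaries

    # --- validated marker panel ---------------------------------------------
    s1 = summaries[1]
    validated = s1[
        (s1["fold_change"] > config.validation_min_fc)
        & (s1["p_value"] < config.validation_max_p)
    ].index
    validated = [m for m in validated if m not in set(refs)]
    _stage("validate", len(s1), len(validated))
    results["validated_panel"] = list(validated)
    if len(validated) == 0:
        log.warning("no qPCR-validated markers; stopping before signature search")
        return results

    # --- exhaustive signature search ----------------------------------------
    (rel1, sheet1), (rel2, sheet2) = rels[1], rels[2]
    train_x = rel1.dct.loc[list(validated)].T
    test_x = rel2.dct.loc[list(validated)].T
    train_y = sheet1.diagnosis_of(train_x.index).to_numpy()
    test_y = sheet2.diagnosis_of(test_x.index).to_numpy()
    reports = evaluate_signatures(
        train_x, train_y, test_x, test_y, panel=list(validated), priors=config.priors
    )
    ranked = rank_signatures(
        reports,
        min_spec=config.min_spec,
        min_sens=config.min_sens,
        min_auc=config.min_auc,
    )
    reports_table(reports).to_csv(outdir / "signature_report.tsv", sep="\t", index=False)
    reports_table(ranked).to_csv(
        outdir / "ranked_signatures.tsv", sep="\t", index=False
    )
    best = max(reports, key=lambda r: (r.auc, r.accuracy))
    best.roc.to_csv(outdir / "roc_best_signature.tsv", sep="\t", index=False)
    _stage("search", len(reports), len(ranked))
    results.update(
        {"reports": reports, "ranked": ranked, "best": best, "positive_class": POSITIVE}
    )
    return results
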