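"""Synthetic two-cohort plasma miRNA study generator.

Emulates the data structure of a case-control circulating-miRNA study:

* an nCounter-style digital count matrix over a ~654-miRNA human panel, run in
  triplicate lanes with multiplicative lane-to-lane scale effects, additive
  background, positive-control ladders and negative-control probes;
* TaqMan-style Ct matrices for a small validation panel, run in duplicate
  wells, with an exogenous spike-in (ath-159a analogue) and a rank-stable
  endogenous reference (hsa-miR-106a-5p analogue);
* planted AD-vs-NC down-regulation on a configurable set of miRNAs, with MCI
  samples at half the log effect.

Default sample sizes and planted fold changes follow the study design the
pipeline targets: cohort 1 with 11 AD / 9 MCI / 20 NC, cohort 2 with
20 AD / 17 NC, and seven signature miRNAs down-regulated 2.26-3.84x
(cohort 1) and 1.35-5.15x (cohort 2).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, CtMatrix, SampleSheet

SPIKE_IN = "ath-159a"
ENDOGENOUS_REFERENCE = "hsa-miR-106a-5p"

SIGNATURE_MIRNAS = (
    "hsa-let-7d-5p",
    "hsa-let-7g-5p",
    "hsa-miR-15b-5p",
    "hsa-miR-142-3p",
    "hsa-miR-191-5p",
    "hsa-miR-301a-3p",
    "hsa-miR-545-3p",
)

# NC/AD linear fold changes of the seven signature miRNAs (TaqMan stage),
# per validation cohort; >1 means down-regulated in AD.
TAQMAN_COHORT1_FOLD_CHANGES = dict(
    zip(SIGNATURE_MIRNAS, (3.01, 2.26, 3.45, 3.84, 3.38, 2.98, 2.49))
)
TAQMAN_COHORT2_FOLD_CHANGES = dict(
    zip(SIGNATURE_MIRNAS, (3.03, 2.62, 3.65, 5.04, 5.15, 1.35, 2.37))
)

_POS_LADDER = (24576.0, 6144.0, 1536.0, 384.0, 96.0, 24.0)

# rng stream tags so each simulator op draws an independent substream of seed
_STREAM_BASELINES = 101
_STREAM_NANOSTRING = 202
_STREAM_QPCR = 303


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic cohorts.

    Noise defaults are chosen to resemble well-powered plasma assays: ~12%
    lane-to-lane scale variation, mild count overdispersion, ~0.4-cycle
    biological sample-to-sample spread (varying ~30% across miRNAs),
    0.5-cycle loading/extraction shifts (removed by reference normalization)
    and 0.25-cycle per-well qPCR replicate noise.
    """

    n_ad_1: int = 11
    n_mci_1: int = 9
    n_nc_1: int = 20
    n_ad_2: int = 20
    n_nc_2: int = 17
    panel_size: int = 654
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    effect_table: dict = field(
        default_factory=lambda: dict(TAQMAN_COHORT1_FOLD_CHANGES)
    )
    effect_table_cohort2: dict = field(
        default_factory=lambda: dict(TAQMAN_COHORT2_FOLD_CHANGES)
    )
    mci_log_effect_fraction: float = 0.5
    lane_scale_sd: float = 0.12      # natural-log SD of lane factors
    count_dispersion: float = 0.05   # gamma-Poisson dispersion (0 = Poisson)
    background_mean: float = 10.0    # additive background counts per probe
    sample_effect_sd: float = 0.4    # log2 / cycles, biological spread
    ct_sample_shift_sd: float = 0.5  # cycles, per-sample loading shift
    ct_noise_sd: float = 0.25        # cycles, per-well replicate noise
    baseline_ct_range: tuple = (20.0, 30.0)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ad_1", "n_mci_1", "n_nc_1", "n_ad_2", "n_nc_2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.panel_size < len(self.effect_table):
            raise ValueError("panel_size smaller than the effect table")
        for table in (self.effect_table, self.effect_table_cohort2):
            for name, fc in table.items():
                if not fc > 0:
                    raise ValueError(f"fold change for {name} must be > 0")
        for name in (
            "lane_scale_sd",
            "count_dispersion",
            "ct_noise_sd",
            "sample_effect_sd",
            "ct_sample_shift_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def default_panel(panel_size: int = 654) -> list[str]:
    """Endogenous panel: the 7 signature miRNAs, the rank-stable reference,
    and synthetic filler names up to ``panel_size``."""
    named = list(SIGNATURE_MIRNAS) + [ENDOGENOUS_REFERENCE]
    if panel_size < len(named):
        return named[:panel_size]
    filler = [f"hsa-miR-sim-{i:04d}" for i in range(panel_size - len(named))]
    return named + filler


def _check_effects_in_panel(config: SimulationConfig, panel: list[str]) -> None:
    panel_set = set(panel)
    for table in (config.effect_table, config.effect_table_cohort2):
        for name in table:
            if name not in panel_set:
                raise ValueError(
                    f"effect table names miRNA absent from the panel: {name!r}"
                )


def panel_baselines(config: SimulationConfig) -> pd.DataFrame:
    """Per-miRNA log2 baseline abundance and biological SD (deterministic).

    Signature (effect-table) miRNAs sit in the high-abundance band the
    validated markers occupied (mean counts in the thousands); the endogenous
    reference is abundant with deliberately low biological spread, which is
    what makes it rank-invariant.
    """
    panel = default_panel(config.panel_size)
    _check_effects_in_panel(config, panel)
    rng = np.random.default_rng([config.seed, _STREAM_BASELINES])
    log2_baseline = np.clip(rng.normal(7.0, 2.5, size=len(panel)), 1.0, 14.0)
    bio_sd = config.sample_effect_sd * rng.uniform(0.7, 1.3, size=len(panel))
    out = pd.DataFrame(
        {"log2_baseline": log2_baseline, "bio_sd": bio_sd}, index=pd.Index(panel)
    )
    planted = sorted(set(config.effect_table) | set(config.effect_table_cohort2))
    out.loc[planted, "log2_baseline"] = rng.uniform(11.3, 12.6, size=len(planted))
    out.loc[ENDOGENOUS_REFERENCE, "log2_baseline"] = 11.0
    out.loc[ENDOGENOUS_REFERENCE, "bio_sd"] = 0.25 * config.sample_effect_sd
    return out


def simulate_sheet(config: SimulationConfig) -> SampleSheet:
    """Sample sheet for both cohorts with deterministic ids."""
    rows = []
    for cohort, diag, n in (
        (1, "AD", config.n_ad_1),
        (1, "MCI", config.n_mci_1),
        (1, "NC", config.n_nc_1),
        (2, "AD", config.n_ad_2),
        (2, "NC", config.n_nc_2),
    ):
        for i in range(n):
            rows.append((f"C{cohort}-{diag}-{i + 1:02d}", cohort, diag))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "cohort", "diagnosis"]))


def _effect_log2(config: SimulationConfig, cohort: int, diagnosis: str) -> dict:
    """Planted per-miRNA log2 down-regulation (added to Ct, subtracted from
    log2 expression) for one sample."""
    table = config.effect_table if cohort == 1 else config.effect_table_cohort2
    if diagnosis == "NC":
        return {}
    frac = 1.0 if diagnosis == "AD" else config.mci_log_effect_fraction
    return {name: frac * np.log2(fc) for name, fc in table.items()}


def simulate_nanostring(
    config: SimulationConfig, sheet: SampleSheet | None = None
) -> tuple[CountMatrix, SampleSheet]:
    """Simulate the discovery-stage count matrix (cohort 1, triplicate lanes).

    Counts are gamma-Poisson draws around lane-factor x expression means plus
    additive background; negative controls see background only; positive
    controls follow a fixed concentration ladder scaled only by the lane
    factor; spike-in expression is diagnosis-independent.
    """
    full_sheet = simulate_sheet(config) if sheet is None else sheet
    disc = full_sheet.subset(cohort=1)
    base = panel_baselines(config)
    panel = list(base.index)
    rng = np.random.default_rng([config.seed, _STREAM_NANOSTRING])

    pos_names = [f"POS_{chr(ord('A') + i)}" for i in range(config.n_pos_controls)]
    pos_mu = [
        _POS_LADDER[i] if i < len(_POS_LADDER) else _POS_LADDER[-1] / 4 ** (i - 5)
        for i in range(config.n_pos_controls)
    ]
    neg_names = [f"NEG_{i + 1:02d}" for i in range(config.n_neg_controls)]

    probe_names = panel + [SPIKE_IN] + pos_names + neg_names
    probe_class = pd.Series(
        ["endogenous"] * len(panel)
        + ["spike_in"]
        + ["positive_control"] * len(pos_names)
        + ["negative_control"] * len(neg_names),
        index=pd.Index(probe_names),
    )

    spike_log2 = 13.0  # abundant, constant spike-in

    lane_cols, lane_meta, count_cols = [], [], []
    for _, row in disc.table.iterrows():
        sid, cohort, diag = row["sample_id"], row["cohort"], row["diagnosis"]
        bio = rng.normal(0.0, base["bio_sd"].to_numpy())
        effects = _effect_log2(config, cohort, diag)
        log2_expr = base["log2_baseline"].to_numpy() + bio
        if effects:
            idx = base.index.get_indexer(list(effects))
            log2_expr[idx] -= np.fromiter(effects.values(), dtype=float)
        expr = 2.0 ** log2_expr
        spike_expr = 2.0 ** (spike_log2 + rng.normal(0.0, 0.1))
        for rep in range(1, config.n_replicates + 1):
            lane_factor = np.exp(rng.normal(0.0, config.lane_scale_sd))
            mu_endog = lane_factor * expr
            mu = np.concatenate(
                [
                    mu_endog + lane_factor * config.background_mean,
                    [lane_factor * (spike_expr + config.background_mean)],
                    lane_factor * np.asarray(pos_mu),
                    np.full(len(neg_names), lane_factor * config.background_mean),
                ]
            )
            if config.count_dispersion > 0:
                shape = 1.0 / config.count_dispersion
                lam = rng.gamma(shape, mu * config.count_dispersion)
            else:
                lam = mu
            counts = rng.poisson(lam).astype(float)
            lane_id = f"{sid}:{rep}"
            lane_cols.append(lane_id)
            lane_meta.append((lane_id, sid, rep))
            count_cols.append(counts)

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=probe_class.index, columns=lane_cols
    )
    lanes = pd.DataFrame(
        lane_meta, columns=["lane_id", "sample_id", "replicate"]
    ).set_index("lane_id")
    return CountMatrix(counts, probe_class, lanes), disc


def simulate_qpcr(
    config: SimulationConfig, sheet: SampleSheet, panel: list[str]
) -> CtMatrix:
    """Simulate duplicate-well TaqMan Ct values for ``panel`` over ``sheet``.

    Ct = assay baseline + per-sample loading shift + biological effect
    - planted log2 fold change is *added* (down-regulated -> later Ct) -
    with per-well Gaussian noise; the two wells are averaged before export.
    Cts beyond 40 cycles are treated as non-amplification (missing).
    """
    if SPIKE_IN not in panel:
        raise ValueError(f"panel must include the spike-in assay {SPIKE_IN!r}")
    if ENDOGENOUS_REFERENCE not in panel:
        raise ValueError(
            f"panel must include an endogenous reference candidate "
            f"({ENDOGENOUS_REFERENCE!r})"
        )
    base = panel_baselines(config)
    unknown = [a for a in panel if a != SPIKE_IN and a not in base.index]
    if unknown:
        raise ValueError(f"panel assays absent from the simulated panel: {unknown}")
    if len(sheet) == 0:
        raise ValueError("sample sheet and panel mismatch: no samples")

    # independent deterministic stream per (seed, sample set)
    crc = zlib.crc32("|".join(sheet.sample_ids).encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([config.seed, _STREAM_QPCR, crc])

    lo, hi = config.baseline_ct_range
    endog = [a for a in panel if a != SPIKE_IN]
    # linear log2->Ct map anchored so the most abundant panel assay sits at lo
    anchor = base["log2_baseline"].max()
    base_ct = pd.Series(
        {a: min(hi, lo + (anchor - base.at[a, "log2_baseline"])) for a in endog}
    )
    base_ct[SPIKE_IN] = 0.5 * (lo + hi)

    ct = np.zeros((len(panel), len(sheet)))
    for j, (_, row) in enumerate(sheet.table.iterrows()):
        effects = _effect_log2(config, row["cohort"], row["diagnosis"])
        shift = rng.normal(0.0, config.ct_sample_shift_sd)
        for i, assay in enumerate(panel):
            mean_ct = base_ct[assay] + shift
            if assay != SPIKE_IN:
                mean_ct += rng.normal(0.0, base.at[assay, "bio_sd"])
                mean_ct += effects.get(assay, 0.0)
            wells = mean_ct + rng.normal(0.0, config.ct_noise_sd, size=2)
            ct[i, j] = wells.mean()
    ct_df = pd.DataFrame(ct, index=pd.Index(panel), columns=list(sheet.sample_ids))
    ct_df = ct_df.mask(ct_df > 40.0)

    role = pd.Series("target", index=ct_df.index)
    role[SPIKE_IN] = "spike_in"
    if ENDOGENOUS_REFERENCE in role.index:
        role[ENDOGENOUS_REFERENCE] = "endogenous_reference"
    return CtMatrix(ct_df, role)
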