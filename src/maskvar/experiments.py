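"""End-to-end experiment runners over a (synthetic or loaded) cohort.

Three experiments mirror the sensitivity study design:

1. **Strategy comparison** — convert every patient's contours with each
   rasterisation strategy, measure per-patient mask discrepancy (V_d)
   against a designated baseline, extract features, compare them
   pairwise (P_d categories), compute per-feature Spearman rho and
   ICC(2,1) across strategies, and measure whole-table clustering
   entanglement versus the baseline.  Also emits the per-patient
   V_d-vs-(number of features with P_d > 0.5%) scatter data.
2. **Super-sampling threshold sweep** — fix the grid split and sweep the
   sub-voxel inclusion threshold (default 10..90% step 10), reporting
   masks, P_d heatmaps versus baseline and per-family category counts.
3. **Mixed import** — split the cohort into three groups, convert each
   group with a different strategy (emulating a multi-centre collection
   with heterogeneous import software), recombine, normalise the mixed
   and baseline tables separately, and report per-family clustering
   entanglement versus baseline for each modality.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import entanglement, hclust_complete, zscore_scale
from .compare_stats import categorise, icc2, percent_difference, spearman_rho
from .errors import UsageError
from .features import FEATURE_FAMILIES, ExtractionConfig, extract_features, feature_family
from .mask_metrics import classify_discrepancy, difference_map, voxel_discrepancy
from .phantom import Cohort
from .rasterize import BinaryMask, RasterStrategy, rasterize

__all__ = [
    "ComparisonReport",
    "DEFAULT_MIXED_STRATEGIES",
    "extract_table",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
]

log = logging.getLogger("maskvar")

#: mixed-import trio: standard conversion, strict single-split
#: super-sampling, and lenient deep-split super-sampling
DEFAULT_MIXED_STRATEGIES = (
    RasterStrategy(method="centre"),
    RasterStrategy(method="supersampled", split=1, threshold_pct=90.0),
    RasterStrategy(method="supersampled", split=3, threshold_pct=50.0),
)


def default_configs(cohort: Cohort) -> dict[str, ExtractionConfig]:
    """One extraction config per modality (FBN 32 throughout)."""
    return {tag: ExtractionConfig(modality_tag=tag) for tag in cohort.modalities}


@dataclass
class ComparisonReport:
    """Tabular outputs of an experiment run.

    ``vd``: per patient/modality/strategy V_d row (incl. discrepancy
    classification); ``pd_categories``: (modality, strategy) ->
    features x patients category labels; ``rho``/``icc``: per-feature
    stability tables; ``entanglement``: per modality/strategy (or
    family) values; ``scatter``: V_d vs count of features with
    P_d > 0.5%; ``feature_tables``: (modality, strategy) -> patients x
    features values; ``mask_voxels``: per-mask ROI voxel counts.
    """

    vd: pd.DataFrame = field(default_factory=pd.DataFrame)
    pd_categories: dict = field(default_factory=dict)
    rho: pd.DataFrame = field(default_factory=pd.DataFrame)
    icc: pd.DataFrame = field(default_factory=pd.DataFrame)
    entanglement: pd.DataFrame = field(default_factory=pd.DataFrame)
    scatter: pd.DataFrame = field(default_factory=pd.DataFrame)
    feature_tables: dict = field(default_factory=dict)
    mask_voxels: pd.DataFrame = field(default_factory=pd.DataFrame)
    family_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("vd", "rho", "icc", "entanglement", "scatter",
                     "mask_voxels", "family_counts"):
            df = getattr(self, name)
            if len(df):
                df.to_csv(out / f"{name}.csv", index=False)
        for (tag, label), df in self.pd_categories.items():
            df.to_csv(out / f"pd_categories_{tag}_{label}.csv")
        for (tag, label), df in self.feature_tables.items():
            df.to_csv(out / f"features_{tag}_{label}.csv")


def _masks_for(
    cohort: Cohort, tag: str, strategy: RasterStrategy
) -> dict[str, BinaryMask]:
    out = {}
    for pat in cohort.patients:
        geom = pat.images[tag].geometry
        out[pat.patient_id] = rasterize(pat.contours[tag], geom, strategy)
    return out


def extract_table(
    cohort: Cohort,
    tag: str,
    masks: dict[str, BinaryMask],
    config: ExtractionConfig,
) -> pd.DataFrame:
    """Patients x features table for one modality and one mask set."""
    rows = {}
    for pat in cohort.patients:
        fv = extract_features(pat.images[tag], masks[pat.patient_id], config)
        rows[pat.patient_id] = fv.values
    return pd.DataFrame.from_dict(rows, orient="index")


def _pd_matrix(base: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Features x patients P_d values between two aligned feature tables."""
    pdm = pd.DataFrame(index=base.columns, columns=base.index, dtype=float)
    for pid in base.index:
        for feat in base.columns:
            pdm.loc[feat, pid] = percent_difference(
                float(other.loc[pid, feat]), float(base.loc[pid, feat])
            )
    return pdm


def _categorise_matrix(pdm: pd.DataFrame) -> pd.DataFrame:
    return pdm.map(categorise)


def _table_entanglement(base: pd.DataFrame, other: pd.DataFrame) -> float:
    d_base = hclust_complete(zscore_scale(base))
    d_other = hclust_complete(zscore_scale(other))
    return entanglement(d_base, d_other, L=1.0)


def run_experiment1(
    cohort: Cohort,
    strategies: list[RasterStrategy],
    baseline: RasterStrategy | None = None,
    configs: dict[str, ExtractionConfig] | None = None,
) -> ComparisonReport:
    """Compare rasterisation strategies against a designated baseline."""
    if not strategies:
        raise UsageError("need at least one strategy to compare")
    baseline = baseline or RasterStrategy(method="centre")
    configs = configs or default_configs(cohort)
    report = ComparisonReport()
    vd_rows, rho_rows, icc_rows, ent_rows, scatter_rows = [], [], [], [], []
    for tag in cohort.modalities:
        t0 = time.perf_counter()
        base_masks = _masks_for(cohort, tag, baseline)
        base_table = extract_table(cohort, tag, base_masks, configs[tag])
        report.feature_tables[(tag, "baseline")] = base_table
        rater_tables = [base_table]
        for strat in strategies:
            label = strat.label()
            masks = _masks_for(cohort, tag, strat)
            table = extract_table(cohort, tag, masks, configs[tag])
            report.feature_tables[(tag, label)] = table
            rater_tables.append(table)
            pdm = _pd_matrix(base_table, table)
            report.pd_categories[(tag, label)] = _categorise_matrix(pdm)
            for pat in cohort.patients:
                pid = pat.patient_id
                dmap = difference_map(masks[pid], base_masks[pid])
                vd = voxel_discrepancy(dmap)
                cls = classify_discrepancy(dmap, masks[pid], base_masks[pid])
                vd_rows.append(
                    {"patient_id": pid, "modality": tag, "strategy": label,
                     "V_d": vd, "n_discrepant": dmap.n_discrepant,
                     "slice_extension": cls["slice_extension"],
                     "edge": cls["edge"]}
                )
                n_above = int((pdm[pid].to_numpy(dtype=float) > 0.5).sum()
                              + np.isnan(pdm[pid].to_numpy(dtype=float)).sum())
                scatter_rows.append(
                    {"patient_id": pid, "modality": tag, "strategy": label,
                     "V_d": vd, "n_features_pd_gt_0.5": n_above}
                )
            for feat in base_table.columns:
                rho_rows.append(
                    {"modality": tag, "strategy": label, "feature": feat,
                     "rho": spearman_rho(base_table[feat], table[feat])}
                )
            ent_rows.append(
                {"modality": tag, "strategy": label, "family": "all",
                 "entanglement": _table_entanglement(base_table, table)}
            )
        for feat in base_table.columns:
            ratings = np.column_stack([t[feat].to_numpy(float) for t in rater_tables])
            icc_rows.append({"modality": tag, "feature": feat,
                             "icc2": icc2(ratings)})
        log.info("experiment1 %s done in %.1fs", tag, time.perf_counter() - t0)
    report.vd = pd.DataFrame(vd_rows)
    report.rho = pd.DataFrame(rho_rows)
    report.icc = pd.DataFrame(icc_rows)
    report.entanglement = pd.DataFrame(ent_rows)
    report.scatter = pd.DataFrame(scatter_rows)
    return report


def run_experiment2(
    cohort: Cohort,
    split: int = 1,
    thresholds: list[float] | None = None,
    baseline: RasterStrategy | None = None,
    configs: dict[str, ExtractionConfig] | None = None,
) -> ComparisonReport:
    """Sweep the super-sampling inclusion threshold at a fixed split."""
    thresholds = list(thresholds) if thresholds is not None else list(range(10, 100, 10))
    if any(not (0 < t <= 100) for t in thresholds):
        raise UsageError("thresholds must lie in (0, 100]")
    strategies = [
        RasterStrategy(method="supersampled", split=split, threshold_pct=float(t))
        for t in thresholds
    ]
    report = run_experiment1(cohort, strategies, baseline=baseline, configs=configs)
    mv_rows = []
    for tag in cohort.modalities:
        for strat in strategies:
            masks = _masks_for(cohort, tag, strat)
            for pid, mask in masks.items():
                mv_rows.append({"patient_id": pid, "modality": tag,
                                "strategy": strat.label(),
                                "threshold_pct": strat.threshold_pct,
                                "n_voxels": mask.n_voxels})
    report.mask_voxels = pd.DataFrame(mv_rows)
    fam_rows = []
    for (tag, label), cats in report.pd_categories.items():
        fams = [feature_family(f) for f in cats.index]
        for fam in FEATURE_FAMILIES:
            sub = cats.iloc[[i for i, f in enumerate(fams) if f == fam]]
            flat = sub.to_numpy().ravel()
            for grp in ("G1", "G2", "G3", "G4"):
                fam_rows.append({"modality": tag, "strategy": label,
                                 "family": fam, "category": grp,
                                 "count": int((flat == grp).sum())})
    report.family_counts = pd.DataFrame(fam_rows)
    return report


def run_experiment3(
    cohort: Cohort,
    partition: list[list[str]] | None = None,
    group_strategies: tuple[RasterStrategy, ...] = DEFAULT_MIXED_STRATEGIES,
    baseline: RasterStrategy | None = None,
    configs: dict[str, ExtractionConfig] | None = None,
) -> pd.DataFrame:
    """Mixed-import clustering comparison at the feature-family level.

    Returns a table with one row per (modality, family): the
    entanglement between complete-linkage dendrograms of the baseline
    and the mixed feature tables, each Z-scored separately.
    """
    baseline = baseline or RasterStrategy(method="centre")
    configs = configs or default_configs(cohort)
    ids = [p.patient_id for p in cohort.patients]
    if partition is None:
        k = 3
        partition = [ids[i::k] for i in range(k)]
    if len(partition) != len(group_strategies):
        raise UsageError("partition and group_strategies lengths differ")
    flat = [pid for grp in partition for pid in grp]
    if sorted(flat) != sorted(ids):
        raise UsageError("partition must cover the cohort exactly once")
    group_of = {pid: g for g, grp in enumerate(partition) for pid in grp}

    rows = []
    for tag in cohort.modalities:
        base_masks = _masks_for(cohort, tag, baseline)
        base_table = extract_table(cohort, tag, base_masks, configs[tag])
        mixed_masks = {}
        for pat in cohort.patients:
            strat = group_strategies[group_of[pat.patient_id]]
            geom = pat.images[tag].geometry
            mixed_masks[pat.patient_id] = rasterize(pat.contours[tag], geom, strat)
        mixed_table = extract_table(cohort, tag, mixed_masks, configs[tag])
        for fam in FEATURE_FAMILIES:
            cols = [c for c in base_table.columns if feature_family(c) == fam]
            ent = _table_entanglement(base_table[cols], mixed_table[cols])
            rows.append({"modality": tag, "family": fam, "entanglement": ent})
    return pd.DataFrame(rows)
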