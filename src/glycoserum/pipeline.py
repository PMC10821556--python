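"""End-to-end orchestration: peak lists -> profiles -> traits -> statistics
-> multivariate views -> three-class evaluation.

``run_pipeline`` validates its inputs up front (every metadata sample must
have at least one peak file; all groups non-empty), then emits, in order:
the normalized profile matrix, the trait matrix, a group-statistics report
(one row per trait: per-group mean/SD, the global test routed by the
normality check, and Bonferroni-adjusted pairwise contrasts), trait-wise
pairwise ROC AUCs, PCA and LDA coordinates, the random-forest three-class
report for an explicit discovery/validation split, and the feature
importance ranking.  All outputs are deterministic functions of the inputs
and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .classify import CVConfig, lda_project, pca_project, rf_multiclass_cv
from .glycan_core import MassConfig, theoretical_mz
from .library import load_library
from .spectra import (
    AnnotationConfig,
    GlycanProfile,
    annotate,
    average_replicates,
    normalize_profile,
    profiles_to_frame,
    read_peaklist_csv,
    recalibrate,
)
from .stats import anova_bonferroni, kruskal_dunn, ks_normality, roc_auc
from .traits import compute_traits, traits_to_frame

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_profiles", "stats_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    peaks_dir: Path
    metadata: Path
    library: Path
    output_dir: Path
    annotation: AnnotationConfig = AnnotationConfig()
    mass: MassConfig = MassConfig()
    cv: CVConfig = CVConfig()
    alpha: float = 0.05
    recalibrate: bool = True
    split_column: Optional[str] = "set"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    profiles: pd.DataFrame
    traits: pd.DataFrame
    stats: pd.DataFrame
    trait_aucs: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_variance: np.ndarray
    lda_scores: pd.DataFrame
    rf_reports: Dict[str, Dict[str, float]]
    importances: pd.DataFrame


def build_profiles(
    peaks_dir: Path,
    metadata: pd.DataFrame,
    library,
    mass_cfg: MassConfig,
    ann_cfg: AnnotationConfig,
    do_recalibrate: bool = True,
) -> pd.DataFrame:
    """Annotate and average every sample's replicate spots into one profile row."""
    peaks_dir = Path(peaks_dir)
    calibrants = [theoretical_mz(a.composition, mass_cfg) for a in library.values()]
    rows: List[GlycanProfile] = []
    for sid in metadata["sample_id"]:
        files = sorted(peaks_dir.glob(f"{sid}_*.csv"))
        if not files:
            raise FileNotFoundError(f"no peak files for sample {sid!r} in {peaks_dir}")
        reps = []
        for f in files:
            pl = read_peaklist_csv(f)
            if do_recalibrate:
                pl = recalibrate(pl, calibrants, ann_cfg)
            raw = annotate(pl, library.values(), mass_cfg, ann_cfg)
            reps.append(normalize_profile(raw, sid))
        rows.append(average_replicates(reps))
    return profiles_to_frame(rows)


def stats_report(traits: pd.DataFrame, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-trait three-group comparison in the layout of a summary table.

    Each trait is routed to ANOVA when the K-S test retains normality of the
    pooled within-group residuals at ``alpha``, otherwise to Kruskal-Wallis
    with Dunn's post-hoc test.
    """
    names = sorted(groups.unique())
    records = []
    for trait in traits.columns:
        samples = [traits.loc[(groups == g).to_numpy(), trait].to_numpy() for g in names]
        residuals = np.concatenate([s - s.mean() for s in samples])
        _, p_norm = ks_normality(residuals)
        gaussian = p_norm > alpha
        res = (anova_bonferroni if gaussian else kruskal_dunn)(samples, names, variable=trait)
        rec: Dict[str, object] = {"trait": trait, "test": res.test_name,
                                  "statistic": res.statistic, "p": res.p_value}
        for g, m, s in zip(res.group_names, res.group_means, res.group_sds):
            rec[f"mean_{g}"] = m
            rec[f"sd_{g}"] = s
        for con in res.contrasts:
            tag = f"{con.group_a}_vs_{con.group_b}"
            rec[f"ci_low_{tag}"] = con.ci_low
            rec[f"ci_high_{tag}"] = con.ci_high
            rec[f"padj_{tag}"] = con.p_adjusted
        records.append(rec)
    return pd.DataFrame(records).set_index("trait")


def _pairwise_trait_aucs(traits: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    names = sorted(groups.unique())
    records = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            mask = groups.isin([ga, gb]).to_numpy()
            labels = (groups[mask] == gb).astype(int).to_numpy()
            for trait in traits.columns:
                scores = traits.loc[mask, trait].to_numpy()
                auc = roc_auc(scores, labels)
                records.append({"contrast": f"{ga}_vs_{gb}", "trait": trait,
                                "auc": max(auc, 1 - auc)})
    return pd.DataFrame(records)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the whole workflow and write every table under ``output_dir``."""
    meta = pd.read_csv(cfg.metadata, sep="\t")
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata needs sample_id and group columns")
    groups = meta.set_index("sample_id")["group"]
    counts = groups.value_counts()
    for required in ("normal", "benign", "cancer"):
        if counts.get(required, 0) == 0:
            raise ValueError(f"metadata has no samples in group {required!r}")
    library = load_library(cfg.library)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", cfg)

    profiles = build_profiles(cfg.peaks_dir, meta, library, cfg.mass, cfg.annotation, cfg.recalibrate)
    profiles.to_csv(out / "profiles.tsv", sep="\t")

    trait_rows = [
        compute_traits(GlycanProfile(sid, profiles.loc[sid].to_dict()), library)
        for sid in profiles.index
    ]
    traits = traits_to_frame(trait_rows)
    traits.to_csv(out / "traits.tsv", sep="\t")

    groups = groups.reindex(traits.index)
    stats = stats_report(traits, groups, cfg.alpha)
    stats.to_csv(out / "stats_report.tsv", sep="\t")

    trait_aucs = _pairwise_trait_aucs(traits, groups)
    trait_aucs.to_csv(out / "trait_aucs.tsv", sep="\t", index=False)

    scores, _, evr = pca_project(traits.to_numpy(), n_components=min(3, traits.shape[1]))
    pca_scores = pd.DataFrame(scores, index=traits.index,
                              columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")

    bc_mask = groups.isin(["benign", "cancer"]).to_numpy()
    _, lda = lda_project(traits.to_numpy()[bc_mask], groups[bc_mask].to_numpy())
    lda_scores = pd.DataFrame({"lda_score": lda}, index=traits.index[bc_mask])
    lda_scores.to_csv(out / "lda_scores.tsv", sep="\t")

    rf_reports: Dict[str, Dict[str, float]] = {}
    importances = pd.DataFrame(index=traits.columns)
    cv = dataclasses.replace(cfg.cv, seed=cfg.seed)
    _, full_report, imp = rf_multiclass_cv(traits.to_numpy(), groups.to_numpy(), cv)
    rf_reports["all"] = full_report.as_dict()
    importances["all"] = imp
    if cfg.split_column and cfg.split_column in meta.columns:
        split = meta.set_index("sample_id")[cfg.split_column].reindex(traits.index)
        for subset in sorted(split.dropna().unique()):
            mask = (split == subset).to_numpy()
            try:
                _, rep, imp = rf_multiclass_cv(traits.to_numpy()[mask], groups[mask].to_numpy(), cv)
            except ValueError as exc:
                log.warning("skipping %s split %r: %s", cfg.split_column, subset, exc)
                continue
            rf_reports[str(subset)] = rep.as_dict()
            importances[str(subset)] = imp
    with open(out / "rf_reports.json", "w") as fh:
        json.dump(rf_reports, fh, indent=2, sort_keys=True)
    importances.sort_values("all", ascending=False).to_csv(out / "feature_importance.tsv", sep="\t")

    return PipelineResult(
        profiles=profiles, traits=traits, stats=stats, trait_aucs=trait_aucs,
        pca_scores=pca_scores, pca_variance=evr, lda_scores=lda_scores,
        rf_reports=rf_reports, importances=importances,
    )
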