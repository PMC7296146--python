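"""End-to-end orchestration: raw tables (real or simulated) to report bundle.

Stage order mirrors the analysis workflow: outlier removal and carrier
averaging -> replicate-correlation acceptance filter -> per-day bivariate
REML fits -> relative drought effects and significance counts -> profile
clustering (mean-RDE and genetic-correlation profiles) -> joint
classification -> post-harvest linkage, days-with-correlation and the
quartile selection rule -> PLS/PRESS prediction.  Every stage writes its
CSV intermediate plus a JSON manifest capturing parameters and seeds, so
a rerun with the same config is byte-identical and partial reruns can
reuse intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import choose_k, cluster_profiles, joint_classification, wss_curve
from .design import ExperimentDesign
from .effects import mean_effect_profiles, rde_table, significant_trait_counts
from .io import MAIN_SPIKE_TRAITS, write_table
from .linkage import (correlation_days_table, pca_contrast_lines,
                      rde_correlation_profiles, select_traits,
                      upper_quartile)
from .mixedmodel import analyze_postharvest, fit_surface
from .pls import press_profile
from .preprocess import average_within_carriers, filter_traits, remove_outliers

log = logging.getLogger("phenodrought")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published workflow where
    it states a value (acceptance threshold 0.2, Bonferroni at 0.05,
    day-count significance 0.001, up to 10 clusters)."""

    grubbs_alpha: float = 0.05
    grubbs_max_removals: int = 2
    replicate_threshold: float = 0.2
    bonferroni_alpha: float = 0.05
    daycount_alpha: float = 0.001
    k_max: int = 10
    cluster_restarts: int = 100
    cluster_seed: int = 0
    chosen_k_effects: int | None = None       # manual scree override
    chosen_k_gcorr: int | None = None
    control_floor: float = 1e-8
    ncomp: int = 2
    spike_targets: tuple[str, ...] = tuple(MAIN_SPIKE_TRAITS)
    tgw_target: str = "TGW"
    min_pls_rows: int = 8
    compute_se: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    acceptance: object
    fits: object
    rde: pd.DataFrame
    effect_profiles: pd.DataFrame
    effect_clusters: object
    gcorr_clusters: object
    joint: object
    day_counts: dict[str, pd.Series]
    q3: dict[str, float]
    selections: dict[str, object]
    overlap: list
    press: dict
    postharvest_summary: pd.DataFrame
    contrast_lines: object | None
    significant_counts: pd.Series
    stage_log: dict = field(default_factory=dict)


def run_pipeline(
    obs: pd.DataFrame,
    ph: pd.DataFrame,
    design: ExperimentDesign,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full workflow on a plant-observation and post-harvest table."""
    cfg = config or PipelineConfig()
    stage_log: dict = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- preprocess ------------------------------------------------------
    clean, removed = remove_outliers(obs, cfg.grubbs_alpha, cfg.grubbs_max_removals)
    cm = average_within_carriers(clean)
    report = filter_traits(cm, cfg.replicate_threshold,
                           treatments=design.treatments,
                           all_traits=sorted(obs["trait"].unique()))
    accepted = report.accepted_traits
    stage_log["preprocess"] = {
        "n_observations": int(len(obs)), "n_outliers_removed": int(len(removed)),
        "n_traits_in": int(obs["trait"].nunique()),
        "n_traits_empty": report.n_empty, "n_traits_rejected": report.n_rejected,
        "n_traits_accepted": len(accepted),
    }
    log.info("preprocess: %s", stage_log["preprocess"])
    if out is not None:
        write_table(report.table, out / "acceptance.csv")
    if not accepted:
        raise RuntimeError(
            "no trait passed the replicate-correlation filter "
            f"(threshold {cfg.replicate_threshold}); nothing to analyze"
        )
    cma = cm[cm["trait"].isin(accepted)]

    # --- per-day mixed models -------------------------------------------
    fits = fit_surface(cma, traits=accepted, compute_se=cfg.compute_se)
    pvals = fits.pvalue_table()
    sig_counts = significant_trait_counts(
        pvals[pvals["converged"]], cfg.bonferroni_alpha, m=len(accepted))
    stage_log["fit"] = {"n_fits": len(fits.fits),
                        "n_nonconverged": int((~pvals["converged"]).sum())}
    if out is not None:
        write_table(fits.to_long_frame(), out / "fits.csv")
        sig_counts.rename("n_significant").to_csv(out / "significant_counts.csv")

    # --- drought effects -------------------------------------------------
    rde = rde_table(cma, control_floor=cfg.control_floor)
    profiles = mean_effect_profiles(rde, design.n_days).loc[
        [t for t in accepted]]
    if out is not None:
        write_table(rde, out / "rde.csv")

    # --- clustering ------------------------------------------------------
    eff_wss = wss_curve(profiles, cfg.k_max, cfg.cluster_restarts, cfg.cluster_seed)
    k_eff = cfg.chosen_k_effects or choose_k(eff_wss).k
    eff_clu = cluster_profiles(profiles, k_eff, cfg.cluster_restarts,
                               cfg.cluster_seed)
    gcorr = fits.genetic_correlation_profiles().reindex(profiles.index)
    gc_wss = wss_curve(gcorr, cfg.k_max, cfg.cluster_restarts, cfg.cluster_seed)
    k_gc = cfg.chosen_k_gcorr or choose_k(gc_wss).k
    gc_clu = cluster_profiles(gcorr, k_gc, cfg.cluster_restarts, cfg.cluster_seed)
    joint = joint_classification(eff_clu.labels, gc_clu.labels)
    stage_log["cluster"] = {"k_effects": k_eff, "k_gcorr": k_gc,
                            "n_combined": joint.n_combined}
    if out is not None:
        pd.DataFrame({"effect_cluster": eff_clu.labels,
                      "gcorr_cluster": gc_clu.labels}).to_csv(out / "clusters.csv")
        joint.crosstab.to_csv(out / "joint_crosstab.csv")

    # --- post-harvest and linkage ---------------------------------------
    ph_summary = analyze_postharvest(ph, compute_se=cfg.compute_se)
    ph_rde = rde_table(ph, control_floor=cfg.control_floor, by_day=False)
    spike = [t for t in cfg.spike_targets if t in set(ph_rde["trait"])]
    targets = spike + ([cfg.tgw_target] if cfg.tgw_target in set(ph_rde["trait"]) else [])
    profiles_rt = rde_correlation_profiles(rde, ph_rde, targets=targets,
                                           traits=accepted)
    days_tab = correlation_days_table(profiles_rt, cfg.daycount_alpha)
    if out is not None:
        write_table(days_tab, out / "correlation_days.csv")
        write_table(ph_summary, out / "postharvest_summary.csv")

    # contrast lines: extremes of PC1 on the spike-complex RDE matrix
    contrast = None
    if len(spike) >= 2:
        try:
            mat = ph_rde[ph_rde["trait"].isin(spike)].pivot_table(
                index="genotype", columns="trait", values="rde",
                aggfunc="first")
            contrast = pca_contrast_lines(mat)
            stage_log["contrast_lines"] = {"low": contrast.extreme_low,
                                           "high": contrast.extreme_high}
        except ValueError:
            contrast = None

    # per-target day counts: the spike complex sums counts over its members
    day_counts: dict[str, pd.Series] = {}
    if spike:
        sp = (days_tab[days_tab["target"].isin(spike)]
              .groupby("trait")["n_total"].sum())
        day_counts["spike"] = sp.reindex(accepted, fill_value=0)
    if cfg.tgw_target in set(days_tab["target"]):
        tg = days_tab[days_tab["target"] == cfg.tgw_target].set_index("trait")[
            "n_total"]
        day_counts[cfg.tgw_target] = tg.reindex(accepted, fill_value=0)

    selections = {}
    q3s = {}
    for name, counts in day_counts.items():
        q3 = upper_quartile(counts.to_numpy())
        q3s[name] = q3
        selections[name] = select_traits(joint.pairs, counts, q3, target=name)
    sel_sets = [set(s.selected) for s in selections.values()]
    overlap = sorted(set.intersection(*sel_sets)) if sel_sets else []
    stage_log["select"] = {name: s.selected for name, s in selections.items()}
    stage_log["select"]["overlap"] = overlap
    if out is not None:
        rows = [(name, t) for name, s in selections.items() for t in s.selected]
        write_table(pd.DataFrame(rows, columns=["target", "trait"]),
                    out / "selected_traits.csv")

    # --- PLS / PRESS -----------------------------------------------------
    press = {}
    if spike:
        predictor_sets = {"all": accepted}
        sel = selections.get("spike")
        if sel and sel.selected:
            predictor_sets["selected"] = sel.selected
        press["spike"] = press_profile(rde, ph_rde, spike, predictor_sets,
                                       cfg.ncomp, min_rows=cfg.min_pls_rows)
    if cfg.tgw_target in set(ph_rde["trait"]):
        predictor_sets = {"all": accepted}
        sel = selections.get(cfg.tgw_target)
        if sel and sel.selected:
            predictor_sets["selected"] = sel.selected
        press[cfg.tgw_target] = press_profile(rde, ph_rde, [cfg.tgw_target],
                                              predictor_sets, cfg.ncomp,
                                              min_rows=cfg.min_pls_rows)
    if out is not None:
        rows = []
        for tgt, profs in press.items():
            for name, pp in profs.items():
                for day, val in pp.press.items():
                    rows.append((tgt, name, day, val))
        write_table(pd.DataFrame(rows, columns=["target", "predictor_set",
                                                "day", "press"]),
                    out / "press.csv")
        manifest = {
            "package_version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "design": asdict(design) | {"treatments": list(design.treatments)},
            "stages": _jsonable(stage_log),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))

    return PipelineResult(
        config=cfg, acceptance=report, fits=fits, rde=rde,
        effect_profiles=profiles, effect_clusters=eff_clu,
        gcorr_clusters=gc_clu, joint=joint, day_counts=day_counts, q3=q3s,
        selections=selections, overlap=overlap, press=press,
        postharvest_summary=ph_summary, contrast_lines=contrast,
        significant_counts=sig_counts,
        stage_log=stage_log,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
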