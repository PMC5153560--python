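"""End-to-end orchestration: cohort -> features -> statistics -> report.

The feature table has one row per subject x structure (caudate/putamen)
x side (more/less affected), holding conventional uptake, the laterality
index and the 13 texture statistics. Reports mirror the univariate /
multivariate layout of a per-measure association table.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import (
    PhantomParams,
    clinical_frame,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from .stats import CLINICAL_MEASURES, AssociationReport, analyze_measure, pearson_corr
from .texture import FEATURE_NAMES, texture_for_region
from .uptake import assign_affected_sides, laterality_index, mean_roi_uptake, normalize_to_reference
from .volume import RegionMaskSet, Volume

__all__ = [
    "PipelineConfig",
    "extract_features",
    "run_pipeline",
    "plot_scatter",
]

logger = logging.getLogger("striatex")

_DEFAULT_ANALYSES: List[Tuple[str, str, str]] = [
    ("caudate", "more", "PD"),
    ("putamen", "more", "PD"),
    ("putamen", "more", "PD+HC"),
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    mode: str = "simulate"
    manifest: Optional[str] = None
    params: PhantomParams = field(default_factory=PhantomParams)
    n_pd: int = 85
    n_hc: int = 56
    Q: int = 32
    distance: int = 1
    homogeneity_form: str = "inverse_difference"
    cluster_tendency_exponent: int = 4
    fdr_alpha: float = 0.05
    enter_p: float = 0.10
    remove_p: float = 0.05
    measures: Sequence[str] = CLINICAL_MEASURES
    analyses: Sequence[Tuple[str, str, str]] = field(
        default_factory=lambda: list(_DEFAULT_ANALYSES)
    )
    out_dir: str = "striatex_run"
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not self.manifest:
            raise ValueError("ingest mode needs a cohort manifest path")
        for name in ("fdr_alpha", "enter_p", "remove_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["measures"] = list(self.measures)
        d["analyses"] = [list(a) for a in self.analyses]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "params" in d:
            d["params"] = PhantomParams.from_dict(d["params"])
        if "analyses" in d:
            d["analyses"] = [tuple(a) for a in d["analyses"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def extract_features(
    volumes: Sequence[Volume],
    masks: RegionMaskSet,
    subject_ids: Sequence[str],
    Q: int = 32,
    distance: int = 1,
    homogeneity_form: str = "inverse_difference",
    cluster_tendency_exponent: int = 4,
) -> pd.DataFrame:
    """Uptake + laterality + texture for every subject and striatal ROI."""
    rows = []
    for vol, sid in zip(volumes, subject_ids):
        summary = normalize_to_reference(mean_roi_uptake(vol, masks))
        more = assign_affected_sides(summary)
        less = "R" if more == "L" else "L"
        norm = summary.mean_normalized
        for struct in ("caudate", "putamen"):
            lat = laterality_index(norm[f"{struct}_R"], norm[f"{struct}_L"])
            for rel, hemi in (("more", more), ("less", less)):
                region = f"{struct}_{hemi}"
                feats = texture_for_region(
                    vol, masks, region, Q=Q, distance=distance,
                    homogeneity_form=homogeneity_form,
                    cluster_tendency_exponent=cluster_tendency_exponent,
                )
                row = {
                    "subject_id": sid,
                    "region": struct,
                    "side": rel,
                    "hemisphere": hemi,
                    "mean_raw": summary.mean_raw[region],
                    "mean_normalized": norm[region],
                    "reference_mean": summary.reference_mean,
                    "laterality": lat,
                    "n_voxels": feats.n_voxels,
                    "Q": Q,
                    "distance": distance,
                    "degenerate": feats.degenerate,
                }
                row.update(feats.to_dict())
                rows.append(row)
    return pd.DataFrame(rows)


def _format_report_text(reports: List[AssociationReport]) -> str:
    lines = []
    for rep in reports:
        lines.append(
            f"== {rep.region} ({rep.side} affected side), subset {rep.subset}, "
            f"measure {rep.measure} =="
        )
        lines.append(
            f"{'metric':<18}{'n':>5}{'r':>9}{'p':>11}  {'FDR':<5}"
            f"{'M: coef':>12}{'M: p':>11}"
        )
        for _, row in rep.table.iterrows():
            fdr = "*" if row["fdr_significant"] else ""
            coef = f"{row['coef']:.4g}" if np.isfinite(row["coef"]) else "-"
            coef_p = f"{row['coef_p']:.3g}" if np.isfinite(row["coef_p"]) else "-"
            r = f"{row['r']:.3f}" if np.isfinite(row["r"]) else "-"
            p = f"{row['p']:.3g}" if np.isfinite(row["p"]) else "-"
            lines.append(
                f"{row['metric']:<18}{row['n']:>5}{r:>9}{p:>11}  {fdr:<5}"
                f"{coef:>12}{coef_p:>11}"
            )
        sel = ", ".join(rep.model.selected) or "(none)"
        lines.append(f"stepwise-selected: {sel}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate-or-ingest -> features -> statistics; returns the run dir.

    Writes features.csv, report.csv, report.txt, run.log and
    provenance.yaml. Identical config (and seed) gives identical
    outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if config.mode == "simulate":
            logger.info(
                "simulating cohort: %d PD + %d HC, seed %d",
                config.n_pd, config.n_hc, config.params.seed,
            )
            cohort = simulate_cohort(config.params, n_pd=config.n_pd, n_hc=config.n_hc)
            if config.save_volumes:
                write_cohort(cohort, out_dir / "cohort")
        else:
            logger.info("ingesting cohort from %s", config.manifest)
            cohort = read_cohort(config.manifest)

        clinical = clinical_frame(cohort.records)
        clinical.to_csv(out_dir / "clinical.csv", index=False)

        try:
            features = extract_features(
                cohort.volumes,
                cohort.masks,
                [r.subject_id for r in cohort.records],
                Q=config.Q,
                distance=config.distance,
                homogeneity_form=config.homogeneity_form,
                cluster_tendency_exponent=config.cluster_tendency_exponent,
            )
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"feature-extraction stage failed: {exc}") from exc
        features.to_csv(out_dir / "features.csv", index=False)
        logger.info("extracted %d feature rows", len(features))

        reports: List[AssociationReport] = []
        for region, side, subset in config.analyses:
            for measure in config.measures:
                try:
                    reports.append(
                        analyze_measure(
                            features, clinical, measure,
                            region=region, side=side, subset=subset,
                            alpha=config.fdr_alpha,
                            enter_p=config.enter_p, remove_p=config.remove_p,
                        )
                    )
                except Exception as exc:  # noqa: BLE001
                    raise RuntimeError(
                        f"analysis stage failed for {region}/{side}/{subset} "
                        f"vs {measure}: {exc}"
                    ) from exc
        report_df = pd.concat([r.table for r in reports], ignore_index=True)
        report_df.to_csv(out_dir / "report.csv", index=False)
        (out_dir / "report.txt").write_text(_format_report_text(reports))

        provenance = {
            "software": {"name": "striatex", "version": __version__},
            "config": config.to_dict(),
            "seed": config.params.seed,
            "spec_defaults": {
                "Q": 32, "distance": 1, "fdr_alpha": 0.05,
                "enter_p": 0.10, "remove_p": 0.05,
                "homogeneity_form": "inverse_difference",
                "cluster_tendency_exponent": 4,
            },
        }
        with open(out_dir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(provenance, fh, sort_keys=True)
        logger.info("run complete: %s", out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir


def plot_scatter(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    metric: str,
    measure: str,
    out,
    region: str = "caudate",
    side: str = "more",
):
    """Scatter of one metric against one clinical measure with the
    least-squares line and annotated Pearson r / p; PD and HC are drawn
    separately when both groups are present. Returns (path, result)."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    valid_metrics = ("mean_normalized", "laterality") + FEATURE_NAMES
    if metric not in valid_metrics:
        raise ValueError(
            f"unknown metric {metric!r}; available: {', '.join(valid_metrics)}"
        )
    if measure not in clinical.columns:
        raise ValueError(
            f"unknown measure {measure!r}; available: {', '.join(CLINICAL_MEASURES)}"
        )
    rows = features[(features["region"] == region) & (features["side"] == side)]
    data = rows.merge(clinical, on="subject_id", how="inner").dropna(
        subset=[metric, measure]
    )
    if len(data) == 0:
        raise ValueError("no joined data to plot")
    result = pearson_corr(data[metric], data[measure], metric=metric, measure=measure)

    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for group, color in (("PD", "tab:blue"), ("HC", "tab:orange")):
        sub = data[data["group"] == group]
        if len(sub):
            ax.scatter(sub[measure], sub[metric], s=18, alpha=0.8, label=group,
                       color=color)
    slope, intercept = np.polyfit(data[measure], data[metric], 1)
    xs = np.linspace(data[measure].min(), data[measure].max(), 50)
    ax.plot(xs, slope * xs + intercept, "k-", lw=1)
    ax.set_xlabel(measure)
    ax.set_ylabel(f"{region} ({side} affected) {metric}")
    ax.annotate(
        f"r = {result.r:.3f}, p = {result.p:.3g}",
        xy=(0.03, 0.95), xycoords="axes fraction", va="top",
    )
    if data["group"].nunique() > 1:
        ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    return out, result
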