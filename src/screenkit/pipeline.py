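"""End-to-end orchestration: simulate -> normalize -> QC -> hits -> dose -> enrich.

A run is fully described by a :class:`RunConfig` (flat YAML on disk); every
stage writes its table under the output directory and the run finishes with a
machine-readable ``summary.json`` plus a stage-granular log.  Re-running with
the same config and seed reproduces every output file byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plate_io
from .dose_response import fit_dose_table
from .enrichment import set_enrichment, trinarize
from .hit_calling import (
    HitThresholds,
    call_preliminary_hits,
    compound_activities,
    finalize_hits,
    flag_promiscuous,
    hit_rate,
    neutral_activity_stats,
)
from .normalization import correct_pattern, normalize_screen, qc_table, replicate_r2
from .synthetic import (
    DoseDesign,
    ScreenConfig,
    generate_annotations,
    generate_dose_series,
    generate_promiscuity,
    generate_screen,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "normalize", "qc", "hits", "dose", "enrich")


@dataclass
class RunConfig:
    """Single-file description of a reproducible pipeline run.

    All analysis thresholds default to the screen's canonical values
    (k_sd = 2, promiscuity 50 assays / 0.25 ratio, minimum enrichment set
    size 3, 8-dose 2-fold titration from 50 uM) and are overridable.
    """

    outdir: str = "screen_run"
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    dose_design: DoseDesign = field(default_factory=DoseDesign)
    k_sd: float = 2.0
    direction: str = "inhibition"
    min_set_size: int = 3
    dose_noise_cv: float = 0.05
    n_boot: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    wells_path: str | None = None  # analyze existing data instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "screen" in d:
            sc = d["screen"]
            if "inhibitor_effect_range" in sc:
                sc["inhibitor_effect_range"] = tuple(sc["inhibitor_effect_range"])
            d["screen"] = ScreenConfig(**sc)
        if "dose_design" in d:
            d["dose_design"] = DoseDesign(**d["dose_design"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["screen"]["inhibitor_effect_range"] = list(d["screen"]["inhibitor_effect_range"])
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages and return the machine-readable summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("screenkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    t0 = time.monotonic()
    try:
        screen_cfg = ScreenConfig(**{**asdict(cfg.screen), "seed": cfg.seed})
        truth = annotations = promiscuity = None
        if "simulate" in cfg.stages:
            logger.info("stage simulate: %d compounds x %d replicates",
                        screen_cfg.n_compounds, screen_cfg.n_replicates)
            wells, library, truth = generate_screen(screen_cfg)
            annotations = generate_annotations(truth, seed=cfg.seed + 1)
            promiscuity, truth = generate_promiscuity(truth, seed=cfg.seed + 2)
            plate_io.write_well_table(wells, outdir / "wells.csv")
            plate_io.write_library(library, outdir / "library.csv")
            plate_io.write_annotations(annotations, outdir / "annotations.csv")
            plate_io.write_promiscuity(promiscuity, outdir / "promiscuity.csv")
            _write(truth, outdir / "ground_truth.csv")
            summary["n_wells"] = int(len(wells))
        elif cfg.wells_path:
            wells = plate_io.read_well_table(cfg.wells_path)
        else:
            raise ValueError("no input: enable the simulate stage or set wells_path")
        summary["n_compounds"] = int(wells.loc[wells.well_type == "compound",
                                               "compound_id"].nunique())

        corrected = None
        if "normalize" in cfg.stages:
            logger.info("stage normalize: %d wells", len(wells))
            normalized = normalize_screen(wells)
            corrected = correct_pattern(normalized)
            _write(corrected, outdir / "normalized.csv")

        if "qc" in cfg.stages:
            qc = qc_table(wells)
            _write(qc, outdir / "qc.csv")
            summary["zprime_mean"] = float(qc["zprime"].mean())
            summary["zprime_min"] = float(qc["zprime"].min())
            summary["zprime_max"] = float(qc["zprime"].max())
            summary["n_plates"] = int(qc["plate_id"].nunique())
            logger.info("stage qc: Z' mean %.3f range [%.3f, %.3f]",
                        summary["zprime_mean"], summary["zprime_min"],
                        summary["zprime_max"])

        hits_df = None
        acts = None
        if "hits" in cfg.stages:
            if corrected is None:
                raise ValueError("hits stage requires the normalize stage")
            acts = compound_activities(corrected)
            mu, sd = neutral_activity_stats(corrected)
            thr = HitThresholds(neutral_mean=mu, neutral_sd=sd,
                                k_sd=cfg.k_sd, direction=cfg.direction)
            prelim = call_preliminary_hits(acts, thr)
            if promiscuity is None and (outdir / "promiscuity.csv").exists():
                promiscuity = plate_io.read_promiscuity(outdir / "promiscuity.csv")
            if promiscuity is not None:
                flags = flag_promiscuous(promiscuity)
            else:
                flags = pd.Series(dtype=bool)
            hits_df, hit_summary = finalize_hits(prelim, flags)
            _write(hits_df, outdir / "hits.csv")
            summary.update(hit_summary)
            summary["hit_rate_pct"] = round(
                hit_rate(hit_summary["n_final"], hit_summary["n_compounds"]), 1
            )
            r1 = acts["activity_rep1"].to_numpy(float)
            r2 = acts["activity_rep2"].to_numpy(float)
            ok = ~(np.isnan(r1) | np.isnan(r2))
            summary["replicate_r2"] = float(replicate_r2(r1[ok], r2[ok]))
            logger.info("stage hits: %d preliminary, %d final (%.1f%%), r2=%.3f",
                        hit_summary["n_preliminary"], hit_summary["n_final"],
                        summary["hit_rate_pct"], summary["replicate_r2"])

        if "dose" in cfg.stages:
            if hits_df is None or truth is None:
                logger.warning("stage dose skipped: needs hits and simulated truth")
            else:
                final_ids = hits_df.loc[hits_df["final_hit"], "compound_id"]
                t = truth.set_index("compound_id")
                series = []
                for i, cid in enumerate(final_ids):
                    row = t.loc[cid]
                    if row["is_inhibitor"]:
                        s = generate_dose_series(
                            L=100.0, h=float(row["true_span_pct"]),
                            alpha=float(row["true_ic50_uM"]),
                            beta=float(row["true_hill"]),
                            design=cfg.dose_design, noise_cv=cfg.dose_noise_cv,
                            seed=cfg.seed + 10 + i, compound_id=cid,
                        )
                    else:  # false positive: flat confirmatory series
                        s = generate_dose_series(
                            L=100.0, h=0.0, alpha=None, beta=1.0,
                            design=cfg.dose_design, noise_cv=cfg.dose_noise_cv,
                            seed=cfg.seed + 10 + i, compound_id=cid,
                        )
                    series.append(s)
                if series:
                    dose_df = pd.concat(series, ignore_index=True)
                    plate_io.write_dose_table(dose_df, outdir / "dose_series.csv")
                    metrics = fit_dose_table(dose_df, n_boot=cfg.n_boot, seed=cfg.seed)
                    _write(metrics, outdir / "dose_metrics.csv")
                    conv = metrics["converged"] & (metrics["method"] == "nls")
                    summary["n_dose_series"] = int(len(metrics))
                    summary["n_dose_converged"] = int(conv.sum())
                    with_ic50 = metrics["relative_ic50_uM"].dropna()
                    summary["median_ic50_uM"] = (
                        float(with_ic50.median()) if len(with_ic50) else None
                    )
                    logger.info("stage dose: %d series, %d converged",
                                len(metrics), int(conv.sum()))

        if "enrich" in cfg.stages:
            if acts is None or annotations is None:
                logger.warning("stage enrich skipped: needs hits stage and annotations")
            else:
                mean_act = acts.set_index("compound_id")[
                    ["activity_rep1", "activity_rep2"]
                ].mean(axis=1)
                enr = set_enrichment(mean_act, annotations, min_set_size=cfg.min_set_size)
                _write(enr, outdir / "enrichment.csv")
                mu, sd = neutral_activity_stats(corrected)
                tri = trinarize(mean_act - mu, sd)
                counts = tri["class"].value_counts().to_dict()
                summary["n_sets_tested"] = int(enr.attrs["n_sets_tested"])
                summary["n_sets_significant"] = int(enr["bonferroni_significant"].sum())
                summary["trinarized_counts"] = {
                    k: int(v) for k, v in sorted(counts.items())
                }
                logger.info("stage enrich: %d sets tested, %d significant",
                            summary["n_sets_tested"], summary["n_sets_significant"])

        summary["runtime_s"] = round(time.monotonic() - t0, 3)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
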