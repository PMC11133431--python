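"""End-to-end pipeline: cohort filter -> obesity map -> correspondence.

Binds the stages into one reproducible run: inclusion filtering,
per-parcel BMI regression, spin-test battery correlation and/or PLS
correspondence with bootstrap feature selection, and gene-set
overrepresentation — every artifact written with a JSON sidecar
recording settings, seed and package version so the run record alone
suffices to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correspondence import correlate_battery
from .enrichment import overrepresentation_test, read_gmt
from .parcellation import load_parcellation, read_parcel_map, write_parcel_map
from .pls import (apply_feature_selection, bootstrap_ratios,
                  component_significance, fit_pls, read_annotation_matrix)
from .regression import apply_inclusion_filters, build_obesity_map, \
    read_subject_table
from .spin import make_spin_ensemble

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    Defaults are the analysis defaults of this literature: 10,000 spin
    permutations, 20,000 bootstrap resamples, 5 latent components,
    bootstrap-ratio threshold 3, alpha 0.05.  ``paths`` names the
    inputs: ``centroids`` (TSV, required), ``subjects`` (CSV), and
    optionally ``battery`` (list of parcel-map TSVs), ``annotation``
    (TSV) and ``gene_sets`` (GMT).
    """

    seed: int
    outdir: str
    paths: dict = field(default_factory=dict)
    covariates: tuple = ("age", "sex", "site", "education", "ses")
    n_perm: int = 10_000
    n_boot: int = 20_000
    n_components: int = 5
    br_threshold: float = 3.0
    alpha: float = 0.05
    spun_side: str = "target"
    annotation_source: str = "gene"

    def __post_init__(self):
        for name in ("n_perm", "n_boot", "n_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def _sidecar(path: Path, config: RunConfig, stage: str, extra=None) -> None:
    record = {"stage": stage, "parcelcorr_version": __version__,
              "config": {k: v for k, v in asdict(config).items()
                         if k != "paths"},
              "paths": {k: str(v) for k, v in config.paths.items()}}
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage error aborts with the stage name and offending input in
    the exception message.  Reruns with an identical config and seed
    produce numerically byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("parcelcorr")
    root.addHandler(log_handler)
    try:
        return _run_stages(config, outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run_stages(config: RunConfig, outdir: Path) -> Path:
    paths = config.paths
    if "centroids" not in paths:
        raise ValueError("stage parcellation: no 'centroids' path configured")
    parc = load_parcellation(paths["centroids"])
    logger.info("parcellation: %d parcels (%s)", parc.n_parcels,
                "/".join(parc.present_hemispheres))

    tmap = None
    if "subjects" in paths:
        try:
            subjects = read_subject_table(paths["subjects"], parc)
            subjects = apply_inclusion_filters(subjects)
            result = build_obesity_map(subjects, config.covariates)
        except Exception as exc:
            raise RuntimeError(
                f"stage obesity_map failed on {paths['subjects']}: {exc}") from exc
        tmap = result.tmap
        write_parcel_map(tmap, outdir / "obesity_tmap.tsv", column="t")
        keep = ~tmap.missing
        pd.DataFrame({
            "parcel_id": np.asarray(parc.parcel_ids)[keep],
            "beta": result.beta[keep], "t": tmap.values[keep],
            "p": result.p[keep], "q": result.q[keep],
        }).to_csv(outdir / "obesity_map_stats.tsv", sep="\t", index=False,
                  float_format="%.12g")
        _sidecar(outdir / "obesity_tmap.json", config, "obesity_map",
                 {"n_subjects": result.n_subjects,
                  "covariates": list(result.covariates),
                  "failed_parcels": result.failed_parcels})
        logger.info("obesity map fitted on %d subjects", result.n_subjects)
    elif "target_map" in paths:
        tmap = read_parcel_map(paths["target_map"], parc, name="target")

    ensemble = None
    if tmap is not None and ("battery" in paths or "annotation" in paths):
        ensemble = make_spin_ensemble(parc, config.n_perm, config.seed)

    if "battery" in paths:
        try:
            battery = [read_parcel_map(p, parc, name=Path(p).stem)
                       for p in paths["battery"]]
            results = correlate_battery(tmap, battery, ensemble)
        except Exception as exc:
            raise RuntimeError(f"stage battery_correlation failed: {exc}") from exc
        pd.DataFrame([{
            "map_id": r.map_b_id, "r": r.r, "p_spin": r.p_spin, "q": r.q,
            "n_parcels_used": r.n_parcels_used} for r in results
        ]).to_csv(outdir / "battery_correlations.tsv", sep="\t", index=False,
                  float_format="%.12g")
        _sidecar(outdir / "battery_correlations.json", config,
                 "battery_correlation",
                 {"n_maps": len(results),
                  "n_significant_q": int(sum(r.q < config.alpha for r in results))})
        logger.info("battery: %d maps correlated", len(results))

    if "annotation" in paths:
        try:
            annot = read_annotation_matrix(paths["annotation"], parc,
                                           source=config.annotation_source)
            model = fit_pls(annot, tmap, config.n_components)
            component_significance(model, annot, tmap, ensemble)
            bootstrap_ratios(annot, tmap, model, config.n_boot, config.seed)
            apply_feature_selection(model, config.br_threshold)
        except Exception as exc:
            raise RuntimeError(f"stage pls failed on {paths['annotation']}: "
                               f"{exc}") from exc
        model_record = {"components": [{
            "index": c.index, "r_obs": c.r_obs, "p_perm": c.p_perm,
            "variance_explained_pct": c.variance_explained,
            "flipped": bool(c.flipped),
            "n_positive_features": len(c.positive_features),
            "n_negative_features": len(c.negative_features),
        } for c in model.components]}
        _sidecar(outdir / "pls_model.json", config, "pls", model_record)
        wide = pd.DataFrame({"feature_id": model.feature_ids})
        for c in model.components:
            wide[f"weight_c{c.index}"] = c.weights
            wide[f"br_c{c.index}"] = c.br
        wide.to_csv(outdir / "pls_features.tsv", sep="\t", index=False,
                    float_format="%.12g")
        for c in model.components:
            write_parcel_map(c.scores, outdir / f"pls_scores_c{c.index}.tsv",
                             column="score")
        logger.info("pls: %d components, p_perm=%s", model.n_components,
                    [round(c.p_perm, 4) for c in model.components])

        if "gene_sets" in paths:
            try:
                collection = read_gmt(paths["gene_sets"],
                                      universe=model.feature_ids)
                for direction in ("positive", "negative"):
                    features = getattr(model.components[0],
                                       f"{direction}_features")
                    if not features:
                        logger.info("ora: no %s features selected", direction)
                        continue
                    ora = overrepresentation_test(features, collection)
                    pd.DataFrame([{
                        "set_name": r.set_name, "overlap": r.overlap,
                        "set_size": r.set_size_in_universe, "hits": r.hits,
                        "universe": r.universe_size, "expected": r.expected,
                        "ratio": r.enrichment_ratio, "p": r.p, "q": r.q,
                    } for r in ora]).to_csv(
                        outdir / f"ora_{direction}.tsv", sep="\t",
                        index=False, float_format="%.12g")
            except Exception as exc:
                raise RuntimeError(
                    f"stage ora failed on {paths['gene_sets']}: {exc}") from exc
            _sidecar(outdir / "ora.json", config, "ora")

    _sidecar(outdir / "run_record.json", config, "run_complete")
    return outdir
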