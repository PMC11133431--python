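"""Synthetic data emulating the pipeline's study inputs.

Real inputs to this kind of analysis — consortium cohorts of cortical
thickness, post-mortem expression atlases, PET tracer maps — are
controlled-access or externally curated.  Every generator here is a
pure, seeded function producing desk-scale stand-ins with planted
ground truth so each pipeline stage can be tested end to end:

* spherical parcellations (hemisphere spiral layout, DKT-like sizes),
* spatially autocorrelated parcel maps (Gaussian-kernel smoothing over
  great-circle distance — the structure the spin test must respect),
* subject cohorts with BMI, covariates and per-parcel thickness with a
  planted regional BMI effect,
* annotation matrices with a planted latent component.

Ground truth (planted effect maps, planted loadings) is always returned
alongside the data so recovery tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import ParcelMap, SphericalParcellation, write_parcel_map
from .pls import AnnotationMatrix
from .regression import SubjectTable

_GOLDEN = (np.sqrt(5) - 1) / 2

#: default per-covariate slopes on thickness (mm per unit)
DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.005,      # mm per year: cortical thinning with age
    "sex": 0.02,        # mm offset for sex == 1
    "education": 0.001, # mm per year of education
    "ses": 0.001,       # mm per SD of socioeconomic status
}


@dataclass
class SynthConfig:
    """Knobs for the synthetic generators; ``seed`` is mandatory.

    Defaults emulate the study setting: a 62-parcel two-hemisphere
    parcellation, smoothing lengthscale 0.5 rad (clearly autocorrelated
    maps at 62 parcels), adult-like BMI, 0.1 mm residual thickness
    noise, and a 200-feature annotation matrix with 20 informative
    columns of unit loading spread.
    """

    seed: int
    n_parcels: int = 62
    lengthscale: float = 0.5          # radians on the unit sphere
    n_subjects: int = 500
    beta_map: np.ndarray = None       # planted mm-per-BMI-unit effect per parcel
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    noise_sd: float = 0.1             # mm
    n_sites: int = 3
    n_features: int = 200
    n_informative: int = 20
    loading_sd: float = 1.0
    loading_dist: str = "normal"      # or "fixed": |loading| = loading_sd
    feature_lengthscale: float = None # annotation null columns; default = lengthscale
    baseline_thickness: float = 2.5   # mm
    baseline_sd: float = 0.1          # mm spread of parcel baselines

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent nondeterminism)")
        for name in ("lengthscale", "noise_sd", "loading_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.loading_dist not in ("normal", "fixed"):
            raise ValueError("loading_dist must be 'normal' or 'fixed'")
        if self.feature_lengthscale is None:
            self.feature_lengthscale = self.lengthscale
        if self.feature_lengthscale < 0:
            raise ValueError("feature_lengthscale must be >= 0")


def make_sphere_parcellation(n_parcels: int, seed: int,
                             hemispheres: str = "both") -> SphericalParcellation:
    """Evenly spread parcel centroids per hemisphere, jittered by seed.

    Points follow a deterministic spiral (golden-ratio azimuths within
    one hemisphere's half-open azimuth range, uniform polar spacing)
    with small seeded angular jitter.  Hemispheres are separated by the
    sagittal plane x = 0 (+x right).
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    if hemispheres == "both" and n_parcels % 2:
        raise ValueError("two-hemisphere parcellation needs an even parcel count")
    rng = np.random.default_rng(seed)
    m = n_parcels // 2 if hemispheres == "both" else n_parcels

    def _hemi_points(rng):
        i = np.arange(m)
        cos_theta = 2 * (i + 0.5) / m - 1
        phi = ((i * _GOLDEN) % 1.0) * np.pi - np.pi / 2
        cos_theta = np.clip(cos_theta + rng.normal(0, 0.02, m), -0.999, 0.999)
        phi = np.clip(phi + rng.normal(0, 0.02, m),
                      -np.pi / 2 + 0.01, np.pi / 2 - 0.01)
        sin_theta = np.sqrt(1 - cos_theta ** 2)
        # cos(phi) > 0 keeps x > 0: the right hemisphere
        return np.column_stack([sin_theta * np.cos(phi),
                                sin_theta * np.sin(phi),
                                cos_theta])

    right = _hemi_points(rng)
    if hemispheres == "left":
        left = right * np.array([-1.0, 1.0, 1.0])
        ids = tuple(f"lh.parcel{i:02d}" for i in range(m))
        return SphericalParcellation(ids, ("left",) * m, left)
    left = _hemi_points(rng) * np.array([-1.0, 1.0, 1.0])
    ids = tuple(f"lh.parcel{i:02d}" for i in range(m)) + \
        tuple(f"rh.parcel{i:02d}" for i in range(m))
    hemis = ("left",) * m + ("right",) * m
    return SphericalParcellation(ids, hemis, np.vstack([left, right]))


def _smoothing_kernel(parcellation: SphericalParcellation,
                      lengthscale: float) -> np.ndarray:
    """Gaussian kernel over great-circle distances between centroids."""
    c = parcellation.centroids
    d = np.arccos(np.clip(c @ c.T, -1.0, 1.0))
    if lengthscale == 0:
        return np.eye(parcellation.n_parcels)
    return np.exp(-d ** 2 / (2 * lengthscale ** 2))


def _standardize(v: np.ndarray, axis: int = 0) -> np.ndarray:
    v = v - v.mean(axis=axis, keepdims=True)
    return v / v.std(axis=axis, keepdims=True)


def make_autocorrelated_map(parcellation: SphericalParcellation,
                            lengthscale: float, seed: int,
                            name: str = "synthetic_map") -> ParcelMap:
    """A spatially smooth random map: smoothed white noise, standardized.

    White standard-normal values per parcel are smoothed by a Gaussian
    kernel of the given lengthscale (radians) over great-circle
    distances, then re-standardized to mean 0, SD 1.  Lengthscale 0
    gives re-standardized white noise.
    """
    if lengthscale < 0:
        raise ValueError("lengthscale must be >= 0")
    rng = np.random.default_rng(seed)
    k = _smoothing_kernel(parcellation, lengthscale)
    values = _standardize(k @ rng.standard_normal(parcellation.n_parcels))
    return ParcelMap(parcellation, values, name=name)


def make_cohort(parcellation: SphericalParcellation, config: SynthConfig):
    """A subject cohort with planted per-parcel BMI effects.

    BMI is lognormal (median 26 kg/m^2, sigma 0.17 — an adult-like
    distribution) clipped to the [10, 50] inclusion range with clip
    events counted in the ground truth; age ~ N(55, 7.5) years, sex
    Bernoulli(0.5), site uniform over ``n_sites``, education ~ N(14, 3)
    years, SES ~ N(0, 1).  Thickness per parcel p and subject i is
    baseline_p + beta_map_p * BMI_i + covariate effects + N(0, noise_sd).

    Returns ``(SubjectTable, ground_truth_dict)``.
    """
    n = config.n_subjects
    n_terms = 2 + len(config.covariate_effects) + max(config.n_sites - 1, 0)
    if n < n_terms + 2:
        raise ValueError(f"n_subjects={n} too small for {n_terms} model terms")
    rng = np.random.default_rng(config.seed)
    n_parcels = parcellation.n_parcels
    beta_map = (np.zeros(n_parcels) if config.beta_map is None
                else np.asarray(config.beta_map, dtype=float))
    if beta_map.size != n_parcels:
        raise ValueError("beta_map length must equal parcel count")

    bmi_raw = np.exp(rng.normal(np.log(26.0), 0.17, n))
    n_clipped = int(np.sum((bmi_raw < 10) | (bmi_raw > 50)))
    bmi = np.clip(bmi_raw, 10.0, 50.0)
    age = rng.normal(55.0, 7.5, n)
    sex = rng.integers(0, 2, n)
    site = rng.integers(0, config.n_sites, n)
    education = rng.normal(14.0, 3.0, n)
    ses = rng.normal(0.0, 1.0, n)
    site_offsets = rng.normal(0.0, 0.02, config.n_sites)
    baseline = rng.normal(config.baseline_thickness, config.baseline_sd,
                          n_parcels)

    eff = config.covariate_effects
    subject_part = (eff.get("age", 0.0) * (age - age.mean())
                    + eff.get("sex", 0.0) * sex
                    + eff.get("education", 0.0) * (education - education.mean())
                    + eff.get("ses", 0.0) * ses
                    + site_offsets[site])
    thickness = (baseline[None, :]
                 + np.outer(bmi, beta_map)
                 + subject_part[:, None]
                 + rng.normal(0.0, config.noise_sd, (n, n_parcels)))

    df = pd.DataFrame({
        "subject_id": [f"sub-{i:05d}" for i in range(n)],
        "bmi": bmi, "age": age, "sex": sex, "site": site,
        "education": education, "ses": ses,
    })
    for j, pid in enumerate(parcellation.parcel_ids):
        df[pid] = thickness[:, j]
    truth = {
        "beta_map": beta_map, "baseline": baseline,
        "site_offsets": site_offsets, "n_bmi_clipped": n_clipped,
        "covariate_effects": dict(eff),
    }
    return SubjectTable(df, parcellation), truth


def make_annotation_matrix(parcellation: SphericalParcellation,
                           target_map: ParcelMap, config: SynthConfig,
                           source: str = "gene"):
    """An annotation matrix with a planted latent component.

    Informative columns are ``loading_f * target + N(0, 1)`` noise with
    loadings drawn N(0, loading_sd) (or, with ``loading_dist="fixed"``,
    set to +-loading_sd with random sign — the equal-SNR design used
    for recovery experiments); the remaining columns are independent
    autocorrelated null maps at ``feature_lengthscale`` (0 gives white
    columns).  Column order is shuffled by seed.  Returns
    ``(AnnotationMatrix, ground_truth_dict)`` where the ground truth
    carries the per-column planted loadings (0 for null columns) and
    the informative mask, aligned to the shuffled column order.
    """
    if target_map.parcellation.parcel_ids != parcellation.parcel_ids:
        raise ValueError("target map is on a different parcellation")
    rng = np.random.default_rng(config.seed)
    n_parcels = parcellation.n_parcels
    n_feat, n_info = config.n_features, config.n_informative
    if config.loading_dist == "fixed":
        loadings = config.loading_sd * rng.choice([-1.0, 1.0], n_info)
    else:
        loadings = rng.normal(0.0, config.loading_sd, n_info)
    target = _standardize(target_map.values)
    info_cols = (np.outer(target, loadings)
                 + rng.standard_normal((n_parcels, n_info)))
    k = _smoothing_kernel(parcellation, config.feature_lengthscale)
    null_cols = _standardize(
        k @ rng.standard_normal((n_parcels, n_feat - n_info)))
    values = np.hstack([info_cols, null_cols])
    full_loadings = np.concatenate([loadings, np.zeros(n_feat - n_info)])
    informative = np.concatenate(
        [np.ones(n_info, bool), np.zeros(n_feat - n_info, bool)])
    order = rng.permutation(n_feat)
    prefix = "gene" if source == "gene" else "term"
    ids = tuple(f"{prefix}{i:04d}" for i in range(n_feat))
    matrix = AnnotationMatrix(parcellation, ids, values[:, order],
                              source=source)
    truth = {"loadings": full_loadings[order], "informative": informative[order]}
    return matrix, truth


def write_centroid_table(parcellation: SphericalParcellation, path) -> None:
    df = pd.DataFrame({
        "parcel_id": parcellation.parcel_ids,
        "hemisphere": parcellation.hemispheres,
        "x": parcellation.centroids[:, 0],
        "y": parcellation.centroids[:, 1],
        "z": parcellation.centroids[:, 2],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_synthetic_dataset(outdir, config: SynthConfig,
                            n_battery: int = 5) -> dict:
    """Materialize a full synthetic study into ``outdir``.

    Writes the centroid TSV, subject CSV, a battery of annotation
    parcel-map TSVs, the annotation matrix TSV, and a ground-truth
    JSON.  Returns the file manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    parc = make_sphere_parcellation(config.n_parcels,
                                    int(rng.integers(2 ** 31)))
    # planted negative BMI effect in one contiguous patch of parcels
    anchor = parc.centroids[0]
    near = np.argsort(-parc.centroids @ anchor)[:max(4, parc.n_parcels // 8)]
    beta_map = np.zeros(parc.n_parcels)
    beta_map[near] = -0.01
    cfg = SynthConfig(**{**asdict_config(config), "beta_map": beta_map,
                         "seed": int(rng.integers(2 ** 31))})
    cohort, cohort_truth = make_cohort(parc, cfg)
    # the annotation's planted component follows the planted BMI-effect
    # pattern, so the fitted obesity map genuinely corresponds to it
    target = ParcelMap(parc, _standardize(beta_map), name="planted_pattern")
    annot, annot_truth = make_annotation_matrix(parc, target, cfg)

    manifest = {}
    write_centroid_table(parc, outdir / "centroids.tsv")
    manifest["centroids"] = "centroids.tsv"
    cohort.data.to_csv(outdir / "subjects.csv", index=False,
                       float_format="%.12g")
    manifest["subjects"] = "subjects.csv"
    battery_files = []
    for i in range(n_battery):
        m = make_autocorrelated_map(parc, config.lengthscale,
                                    int(rng.integers(2 ** 31)),
                                    name=f"annotation{i:02d}")
        fname = f"annotation{i:02d}.tsv"
        write_parcel_map(m, outdir / fname)
        battery_files.append(fname)
    manifest["battery"] = battery_files
    adf = pd.DataFrame(annot.values, columns=annot.feature_ids)
    adf.insert(0, "parcel_id", parc.parcel_ids)
    adf.to_csv(outdir / "annotation_matrix.tsv", sep="\t", index=False,
               float_format="%.12g")
    manifest["annotation_matrix"] = "annotation_matrix.tsv"
    truth = {
        "beta_map": cohort_truth["beta_map"].tolist(),
        "n_bmi_clipped": cohort_truth["n_bmi_clipped"],
        "planted_loadings": annot_truth["loadings"].tolist(),
        "informative": annot_truth["informative"].astype(int).tolist(),
        "seed": config.seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    manifest["ground_truth"] = "ground_truth.json"
    return manifest


def asdict_config(config: SynthConfig) -> dict:
    """Config as a plain dict (ndarray fields untouched)."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
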