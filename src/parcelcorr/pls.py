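"""Partial least squares correspondence between a brain map and an
annotation matrix.

The response y is a parcel map (e.g. an obesity t-map); the predictors
X are a parcels x features annotation matrix (gene expression or
cognitive-term activation likelihoods).  Single-response PLS with
X-deflation extracts latent components: the k-th weight vector is the
unit-norm direction maximizing covariance between the deflated-X
projection and y, which for one response is available in closed form as
the normalized cross-covariance vector X_k^T y.  Columns of X and y are
z-scored first, so weights are scale-free.

Inference follows the permutation/bootstrap recipe standard in imaging
transcriptomics: component significance from spin permutations of the
response (preserving its spatial autocorrelation, leaving X and its
feature covariance intact), and feature reliability as bootstrap ratios
(original weight / bootstrap SE over joint parcel resampling), with
|BR| > 3 marking robust features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import ParcelMap, SphericalParcellation
from .spin import SpinNullEnsemble

logger = logging.getLogger(__name__)

#: defaults matching common practice in this literature
DEFAULT_N_COMPONENTS = 5
DEFAULT_N_PERM = 10_000
DEFAULT_N_BOOT = 20_000
BR_THRESHOLD = 3.0


@dataclass
class AnnotationMatrix:
    """Parcels x features matrix (genes or cognitive terms).

    Columns that are constant across parcels carry no information after
    standardization and are dropped at construction with their names
    logged.  ``source`` tags the feature family (``"gene"`` /
    ``"term"`` / free-form).
    """

    parcellation: SphericalParcellation
    feature_ids: tuple
    values: np.ndarray = field(repr=False)
    source: str = "gene"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != self.parcellation.n_parcels:
            raise ValueError(
                f"values must be ({self.parcellation.n_parcels}, n_features)")
        if v.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length mismatch")
        keep = v.std(axis=0) > 0
        if not keep.all():
            dropped = [self.feature_ids[i] for i in np.flatnonzero(~keep)]
            logger.info("dropped %d constant feature column(s): %s",
                        len(dropped), dropped[:10])
            v = v[:, keep]
        self.values = v
        self.feature_ids = tuple(f for f, k in zip(self.feature_ids, keep) if k)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class PLSComponent:
    """One latent component: weights, scores, and inference results."""

    index: int                      # 1-based
    weights: np.ndarray             # unit-norm, per feature
    scores: ParcelMap               # per-parcel component scores
    r_obs: float                    # Pearson(scores, y), oriented >= 0
    covariance: float               # captured covariance (z-scored units)
    variance_explained: float       # percent, 100 * r_obs^2
    flipped: bool = False           # sign orientation applied at fit
    p_perm: float = None
    br: np.ndarray = None           # bootstrap ratio per feature
    br_infinite: np.ndarray = None  # True where bootstrap SD was exactly 0
    positive_features: tuple = ()
    negative_features: tuple = ()


@dataclass
class PLSModel:
    components: list
    feature_ids: tuple
    n_parcels_used: int
    n_perm: int = None
    n_boot: int = None
    seed: int = None
    preprocessing: str = "z-score X columns and y over used parcels (ddof=1)"

    @property
    def n_components(self) -> int:
        return len(self.components)


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mean) / sd


def _pls_core(Xz: np.ndarray, yz: np.ndarray, n_components: int):
    """Single-response PLS with X-deflation on pre-standardized data.

    Returns (weights (f, k), scores (n, k), cov (k,)).  The k-th weight
    vector is the normalized cross-covariance of the k-times-deflated X
    with y; scores are the deflated-X projections (NIPALS x-scores);
    cov is the captured covariance |X_k^T y| / (n - 1), the statistic
    compared against the permutation null.
    """
    n, f = Xz.shape
    W = np.empty((f, n_components))
    T = np.empty((n, n_components))
    cov = np.empty(n_components)
    Xd = Xz.copy()
    for k in range(n_components):
        c = Xd.T @ yz
        norm_c = np.linalg.norm(c)
        if norm_c == 0:
            raise ValueError(
                f"component {k + 1} exceeds the informative rank of X")
        w = c / norm_c
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            raise ValueError(f"degenerate scores at component {k + 1}")
        cov[k] = norm_c / (n - 1)
        W[:, k] = w
        T[:, k] = t
        Xd -= np.outer(t, (Xd.T @ t) / tt)
    return W, T, cov


def _null_cov_stats(Xz: np.ndarray, Y_null: np.ndarray,
                    n_components: int) -> np.ndarray:
    """Captured-covariance null distribution, shape (n_perm, k).

    ``Y_null`` holds one standardized null response per column.  The
    first component needs no deflation, so it is computed for all
    permutations in one matrix product; deeper components loop.
    """
    n = Xz.shape[0]
    n_perm = Y_null.shape[1]
    out = np.empty((n_perm, n_components))
    out[:, 0] = np.linalg.norm(Xz.T @ Y_null, axis=0) / (n - 1)
    if n_components == 1:
        return out
    for j in range(n_perm):
        yz = Y_null[:, j]
        Xd = Xz.copy()
        c = Xd.T @ yz
        for k in range(1, n_components):
            w = c / np.linalg.norm(c)
            t = Xd @ w
            Xd -= np.outer(t, (Xd.T @ t) / (t @ t))
            c = Xd.T @ yz
            out[j, k] = np.linalg.norm(c) / (n - 1)
    return out


def fit_pls(X: AnnotationMatrix, y: ParcelMap,
            n_components: int = DEFAULT_N_COMPONENTS) -> PLSModel:
    """Fit the PLS correspondence model.

    Rows where y is missing are dropped (the left-hemisphere-only and
    few-region annotation cases reduce the parcellation instead).  Each
    component is sign-oriented so that its score-response correlation
    r_obs is non-negative, with the flip recorded.
    """
    if X.parcellation.parcel_ids != y.parcellation.parcel_ids:
        raise ValueError("annotation matrix and map are on different parcellations")
    used = ~y.missing
    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("response map is entirely missing")
    if n_used < n_components + 2:
        raise ValueError(
            f"{n_used} usable parcels cannot support {n_components} components")
    max_k = min(n_used - 1, X.n_features)
    if n_components > max_k:
        raise ValueError(
            f"n_components={n_components} exceeds min(parcels-1, features)={max_k}")
    Xz = _zscore(X.values[used])
    yz = _zscore(y.values[used])
    W, T, cov = _pls_core(Xz, yz, n_components)
    components = []
    for k in range(n_components):
        t = T[:, k]
        r = float(np.corrcoef(t, yz)[0, 1])
        flipped = r < 0
        if flipped:
            W[:, k] = -W[:, k]
            t = -t
            r = -r
        scores = np.full(y.parcellation.n_parcels, np.nan)
        scores[used] = t
        smap = ParcelMap(y.parcellation, scores, missing=~used,
                         name=f"component{k + 1}_scores")
        components.append(PLSComponent(
            index=k + 1, weights=W[:, k].copy(), scores=smap, r_obs=r,
            covariance=float(cov[k]), variance_explained=100.0 * r * r,
            flipped=flipped,
        ))
    return PLSModel(components=components, feature_ids=X.feature_ids,
                    n_parcels_used=n_used)


def component_significance(model: PLSModel, X: AnnotationMatrix, y: ParcelMap,
                           ensemble: SpinNullEnsemble) -> np.ndarray:
    """Spin-permutation p-value per component.

    The response map is spun through every ensemble assignment (X held
    fixed), the spun response re-standardized, the model refit, and the
    k-th observed captured covariance compared with the null
    distribution of k-th-component covariances:
    p_k = (1 + #{null_k >= obs_k}) / (n_perm + 1).
    """
    if ensemble.parcellation.parcel_ids != y.parcellation.parcel_ids:
        raise ValueError("ensemble and map are on different parcellations")
    used = ~y.missing
    Xz = _zscore(X.values[used])
    obs = np.array([c.covariance for c in model.components])
    k = model.n_components
    y_perm = ensemble.permuted_values(y)[:, used]      # (n_perm, n_used)
    ok_rows = ~np.isnan(y_perm).any(axis=1)
    if not ok_rows.all():
        logger.info("%d permutations dropped rows with missing values",
                    int((~ok_rows).sum()))
    Y_null = _zscore(y_perm[ok_rows].T)                # (n_used, n_eff)
    null = _null_cov_stats(Xz, Y_null, k)
    n_eff = null.shape[0]
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_eff + 1)
    for comp, pk in zip(model.components, p):
        comp.p_perm = float(pk)
    model.n_perm = ensemble.n_perm
    return p


def bootstrap_ratios(X: AnnotationMatrix, y: ParcelMap, model: PLSModel,
                     n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> np.ndarray:
    """Bootstrap ratio per feature per component, shape (n_features, k).

    Parcel rows of (X, y) are resampled jointly with replacement; the
    model is refit per resample and each resampled weight vector is
    sign-aligned to the original (flipped when its dot product with the
    original weights is negative) before accumulating the spread —
    without this step the sign indeterminacy of PLS would inflate the
    bootstrap SE.  BR = original weight / bootstrap SD; a zero SD yields
    a flagged infinite ratio.  Resamples with fewer than 3 distinct
    parcels are redrawn (bounded retries).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    used = ~y.missing
    Xu = X.values[used]
    yu = y.values[used]
    n = Xu.shape[0]
    k = model.n_components
    W0 = np.column_stack([c.weights for c in model.components])
    s = np.zeros((X.n_features, k))
    ss = np.zeros((X.n_features, k))
    n_done = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tries = 0
        while len(np.unique(idx)) < 3:
            tries += 1
            if tries > 100:
                raise RuntimeError("could not draw a usable bootstrap resample")
            logger.info("bootstrap resample redrawn (<3 distinct parcels)")
            idx = rng.integers(0, n, size=n)
        Xb = _zscore(Xu[idx])
        yb = yu[idx]
        sd = yb.std(ddof=1)
        yb = (yb - yb.mean()) / (sd if sd > 0 else 1.0)
        try:
            Wb, _, _ = _pls_core(Xb, yb, k)
        except ValueError:
            # resample collapsed the informative rank; skip it
            continue
        signs = np.sign((Wb * W0).sum(axis=0))
        signs[signs == 0] = 1.0
        Wb = Wb * signs
        s += Wb
        ss += Wb ** 2
        n_done += 1
    if n_done < 2:
        raise RuntimeError("too few successful bootstrap resamples")
    mean = s / n_done
    var = (ss - n_done * mean ** 2) / (n_done - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        br = np.where(sd > 0, W0 / sd,
                      np.sign(W0) * np.inf)
    br = np.where((sd == 0) & (W0 == 0), 0.0, br)
    infinite = (sd == 0) & (W0 != 0)
    for j, comp in enumerate(model.components):
        comp.br = br[:, j]
        comp.br_infinite = infinite[:, j]
    model.n_boot = n_boot
    model.seed = seed
    return br


def select_features(br, feature_ids=None, threshold: float = BR_THRESHOLD):
    """Split features into reliable positive/negative sets by |BR| > threshold.

    The inequality is strict; flagged-infinite ratios are included with
    their sign; the two sets are disjoint by construction.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    br = np.asarray(br, dtype=float)
    if feature_ids is None:
        feature_ids = tuple(range(br.size))
    pos = tuple(f for f, b in zip(feature_ids, br) if b > threshold)
    neg = tuple(f for f, b in zip(feature_ids, br) if b < -threshold)
    return pos, neg


def apply_feature_selection(model: PLSModel,
                            threshold: float = BR_THRESHOLD) -> None:
    """Populate each component's positive/negative feature lists in place."""
    for comp in model.components:
        if comp.br is None:
            raise ValueError("run bootstrap_ratios before selecting features")
        comp.positive_features, comp.negative_features = select_features(
            comp.br, model.feature_ids, threshold)


def gene_score_map(component: PLSComponent) -> ParcelMap:
    """The component's per-parcel scores as a brain map.

    For a gene annotation matrix these are the "gene scores": the
    projection of regional expression onto the component's weights,
    summarizing the expression pattern tied to the response map.
    """
    return component.scores


def variance_explained(component, y: ParcelMap) -> float:
    """Percent of response-map variance captured by a component's scores.

    Defined as 100 * r^2 where r is the Pearson correlation between the
    component scores and the response over jointly non-missing parcels.
    Accepts a :class:`PLSComponent` or a :class:`ParcelMap` of scores.
    """
    smap = component.scores if isinstance(component, PLSComponent) else component
    keep = smap.usable_with(y)
    scores = smap.values[keep]
    if np.ptp(scores) == 0:
        raise ValueError("zero-variance component scores")
    r = np.corrcoef(scores, y.values[keep])[0, 1]
    return float(100.0 * r * r)


def read_annotation_matrix(path, parcellation: SphericalParcellation,
                           source: str = "gene") -> AnnotationMatrix:
    """Read an annotation TSV: first column ``parcel_id``, one column per
    feature.  Rows must cover exactly the parcellation's parcels (any
    order)."""
    df = pd.read_csv(path, sep="\t").set_index("parcel_id")
    missing = [p for p in parcellation.parcel_ids if p not in df.index]
    if missing:
        raise ValueError(f"annotation matrix missing parcels: {missing[:5]}")
    df = df.loc[list(parcellation.parcel_ids)]
    return AnnotationMatrix(parcellation, tuple(df.columns),
                            df.to_numpy(dtype=float), source=source)
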