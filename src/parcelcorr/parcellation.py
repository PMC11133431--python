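"""Spherical parcellations and per-parcel maps.

A parcellation is a fixed, ordered set of cortical parcels, each with a
hemisphere label and a unit-vector centroid on the sphere.  Coordinates
follow the RAS convention: +x is right, so the sagittal plane is x = 0
and hemisphere mirroring is a sign flip of x.  A :class:`ParcelMap`
carries one real value per parcel plus an explicit missing mask —
missing parcels are masked, never imputed.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_HEMI_ALIASES = {
    "left": "left", "l": "left", "lh": "left",
    "right": "right", "r": "right", "rh": "right",
}


@dataclass(frozen=True)
class SphericalParcellation:
    """Ordered parcels with hemisphere labels and unit-sphere centroids.

    Parameters
    ----------
    parcel_ids : tuple of str
        Unique parcel labels in file order (e.g. ``"lh.superiorfrontal"``).
    hemispheres : tuple of str
        ``"left"`` or ``"right"`` per parcel.
    centroids : ndarray, shape (n_parcels, 3)
        Unit-norm centroid directions.
    """

    parcel_ids: tuple
    hemispheres: tuple
    centroids: np.ndarray = field(repr=False)

    def __post_init__(self):
        ids = list(self.parcel_ids)
        if len(ids) < 2:
            raise ValueError("a parcellation needs at least 2 parcels")
        seen, dups = set(), []
        for p in ids:
            if p in seen:
                dups.append(p)
            seen.add(p)
        if dups:
            raise ValueError(f"duplicate parcel_id(s): {sorted(set(dups))}")
        bad = set(self.hemispheres) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere label(s): {sorted(bad)}")
        c = np.asarray(self.centroids, dtype=float)
        if c.shape != (len(ids), 3):
            raise ValueError("centroids must be (n_parcels, 3)")
        norms = np.linalg.norm(c, axis=1)
        if np.any(norms == 0):
            zero = [ids[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"zero-length centroid vector for {zero}")
        object.__setattr__(self, "centroids", c / norms[:, None])
        object.__setattr__(self, "parcel_ids", tuple(ids))
        object.__setattr__(self, "hemispheres", tuple(self.hemispheres))

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        """Indices of parcels in one hemisphere, in parcellation order."""
        return np.flatnonzero(np.asarray(self.hemispheres) == hemisphere)

    @property
    def present_hemispheres(self) -> tuple:
        return tuple(h for h in ("left", "right")
                     if len(self.hemisphere_indices(h)) > 0)

    def index_of(self, parcel_id: str) -> int:
        return self.parcel_ids.index(parcel_id)


@dataclass
class ParcelMap:
    """One real value per parcel with an explicit missing mask.

    Units depend on role: t-statistics for obesity maps, density
    z-scores for receptor maps, dimensionless scores for PLS maps.
    """

    parcellation: SphericalParcellation
    values: np.ndarray
    missing: np.ndarray = None
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.parcellation.n_parcels:
            raise ValueError(
                f"map has {v.size} values for {self.parcellation.n_parcels} parcels"
            )
        if self.missing is None:
            m = ~np.isfinite(v)
        else:
            m = np.asarray(self.missing, dtype=bool).ravel()
            if m.size != v.size:
                raise ValueError("missing mask length mismatch")
            m = m | ~np.isfinite(v)
        self.values = v
        self.missing = m

    @property
    def n_usable(self) -> int:
        return int((~self.missing).sum())

    def usable_with(self, other: "ParcelMap") -> np.ndarray:
        """Boolean mask of parcels non-missing in both maps."""
        if self.parcellation is not other.parcellation and \
                self.parcellation.parcel_ids != other.parcellation.parcel_ids:
            raise ValueError("maps are on different parcellations")
        return ~(self.missing | other.missing)


def load_parcellation(centroid_table) -> SphericalParcellation:
    """Read a parcellation from a centroid TSV.

    The table must have columns ``parcel_id, hemisphere, x, y, z``
    (tab-separated, header required).  Centroids are normalized to unit
    length; parcel order is file order; hemisphere labels are parsed
    case-insensitively (``lh``/``l``/``left`` etc.).
    """
    df = pd.read_csv(centroid_table, sep="\t")
    required = {"parcel_id", "hemisphere", "x", "y", "z"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"centroid table missing columns: {sorted(missing_cols)}")
    if len(df) < 2:
        raise ValueError("centroid table needs at least 2 rows")
    hemis = []
    for h in df["hemisphere"]:
        key = str(h).strip().lower()
        if key not in _HEMI_ALIASES:
            raise ValueError(f"unknown hemisphere label: {h!r}")
        hemis.append(_HEMI_ALIASES[key])
    return SphericalParcellation(
        parcel_ids=tuple(str(p) for p in df["parcel_id"]),
        hemispheres=tuple(hemis),
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def load_dkt62() -> SphericalParcellation:
    """The bundled 62-parcel DKT-style fixture (synthetic centroids).

    Parcel names follow the Desikan-Killiany-Tourville convention
    (31 per hemisphere); the centroid coordinates are synthetic
    stand-ins generated by the package's hemisphere-spiral construction,
    not FreeSurfer fsaverage coordinates.
    """
    ref = importlib.resources.files("parcelcorr.data") / "dkt62_centroids_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_parcellation(path)


def read_parcel_map(path, parcellation: SphericalParcellation,
                    column: str = "value", name: str = "") -> ParcelMap:
    """Read a parcel-map TSV (``parcel_id  value``) aligned to a parcellation.

    Parcels absent from the file are masked as missing.
    """
    df = pd.read_csv(path, sep="\t").set_index("parcel_id")
    values = np.full(parcellation.n_parcels, np.nan)
    for i, pid in enumerate(parcellation.parcel_ids):
        if pid in df.index:
            values[i] = df.loc[pid, column]
    return ParcelMap(parcellation, values, name=name or str(path))


def write_parcel_map(pmap: ParcelMap, path, column: str = "value") -> None:
    """Write a parcel-map TSV, omitting missing parcels."""
    keep = ~pmap.missing
    df = pd.DataFrame({
        "parcel_id": np.asarray(pmap.parcellation.parcel_ids)[keep],
        column: pmap.values[keep],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
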