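"""Spin permutations: spatially constrained nulls for parcellated maps.

Correlations between cortical maps cannot be tested with naive value
shuffles because nearby parcels are alike (spatial autocorrelation):
shuffling destroys that structure and inflates false positives.  The
spin test instead rotates one map on the sphere.  Each null sample is a
uniformly random 3x3 rotation; parcel values are reassigned by nearest
rotated centroid, which preserves the map's spatial smoothness while
breaking its alignment with the other map.

Hemispheres are handled symmetrically: the left hemisphere receives the
sampled rotation R and the right receives its sagittal mirror M R M
(M = diag(-1, 1, 1), x being the left-right axis), so contralateral
structure is preserved and assignments never cross hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parcellation import ParcelMap, SphericalParcellation

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class RotationSet:
    """A reproducible sample of uniform random rotations.

    ``rotations`` has shape (n_perm, 3, 3); every matrix is proper
    orthogonal (R^T R = I, det R = +1).
    """

    n_perm: int
    rotations: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self):
        if self.rotations.shape != (self.n_perm, 3, 3):
            raise ValueError("rotations must have shape (n_perm, 3, 3)")


@dataclass(frozen=True)
class SpinNullEnsemble:
    """Per-permutation parcel reassignments induced by a RotationSet.

    ``assignment[k, j]`` is the source parcel index whose rotated
    centroid lies nearest (great-circle) to target parcel j under
    permutation k.  Assignments are hemisphere-constrained and need not
    be bijections: a source parcel may serve several targets.
    """

    n_perm: int
    assignment: np.ndarray = field(repr=False)
    parcellation: SphericalParcellation = None
    seed: int = 0

    def permute(self, pmap: ParcelMap, k: int) -> ParcelMap:
        """Apply permutation ``k`` to a map (values and missing mask)."""
        idx = self.assignment[k]
        return ParcelMap(pmap.parcellation, pmap.values[idx],
                         missing=pmap.missing[idx], name=pmap.name)

    def permuted_values(self, pmap: ParcelMap) -> np.ndarray:
        """All permuted value vectors at once, shape (n_perm, n_parcels).

        Missing entries propagate as NaN.
        """
        vals = np.where(pmap.missing, np.nan, pmap.values)
        return vals[self.assignment]


def sample_rotations(n_perm: int, seed: int) -> RotationSet:
    """Draw ``n_perm`` rotations uniformly over SO(3).

    Construction: QR-orthonormalize a matrix of independent standard
    normals, fix the sign convention using the diagonal of R (making the
    draw Haar-uniform over O(3)), then flip one column wherever the
    determinant is -1.  Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    mats = np.empty((n_perm, 3, 3))
    for i in range(n_perm):
        a = rng.standard_normal((3, 3))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        mats[i] = q
    return RotationSet(n_perm=n_perm, rotations=mats, seed=seed)


def build_spin_ensemble(parcellation: SphericalParcellation,
                        rotations: RotationSet) -> SpinNullEnsemble:
    """Turn rotations into hemisphere-constrained parcel reassignments.

    For each rotation and each hemisphere, source centroids are rotated
    (the right hemisphere with the mirrored rotation) and every target
    parcel is assigned the source parcel whose rotated centroid is
    nearest by great-circle distance.  Ties break to the lowest source
    index; duplicates are allowed.  The identity rotation reproduces the
    identity assignment.
    """
    n_parcels = parcellation.n_parcels
    hemi_idx = {h: parcellation.hemisphere_indices(h)
                for h in parcellation.present_hemispheres}
    for h, idx in hemi_idx.items():
        if len(idx) < 1:
            raise ValueError(f"hemisphere {h} has no parcels")
    assignment = np.empty((rotations.n_perm, n_parcels), dtype=np.intp)
    for k in range(rotations.n_perm):
        rot = rotations.rotations[k]
        for h, idx in hemi_idx.items():
            r = rot if h == "left" else _MIRROR @ rot @ _MIRROR
            cen = parcellation.centroids[idx]           # (m, 3)
            rotated = cen @ r.T                          # rotated source centroids
            # great-circle distance is monotone in -dot; argmax dot = nearest,
            # and argmax returns the lowest index on exact ties
            dots = rotated @ cen.T                       # (source, target)
            nearest = np.argmax(dots, axis=0)
            assignment[k, idx] = idx[nearest]
    return SpinNullEnsemble(n_perm=rotations.n_perm, assignment=assignment,
                            parcellation=parcellation, seed=rotations.seed)


def make_spin_ensemble(parcellation: SphericalParcellation,
                       n_perm: int, seed: int) -> SpinNullEnsemble:
    """Convenience: sample rotations and build the ensemble in one call."""
    return build_spin_ensemble(parcellation, sample_rotations(n_perm, seed))
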