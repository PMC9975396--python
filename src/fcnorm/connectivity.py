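"""From network time series to connectivity features.

Motion quality control, the per-subject Pearson correlation matrix between
the 14 network time series, and the flattening of its strict lower triangle
into the 91-element feature vector fed to the normative model (plus the
inverse reshaping used to localize reconstruction error on network pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, FBNAtlas


class DegenerateSignalError(ValueError):
    """A network time series has zero variance; Pearson r is undefined."""


class MalformedMotionError(ValueError):
    """Motion parameter series have inconsistent lengths."""


# --------------------------------------------------------------------------
# motion quality control
# --------------------------------------------------------------------------

#: Radius (mm) of the sphere used to convert rotations to displacements
#: when framewise displacement has to be derived from the six realignment
#: parameters (Power-style FD).
FD_SPHERE_RADIUS_MM = 50.0


@dataclass(frozen=True)
class MotionParams:
    """Per-volume head-motion summary for one subject.

    translations_mm : (T, 3) array, signed displacements along x/y/z
    rotations_deg   : (T, 3) array, signed rotations about x/y/z
    fd_mm           : (T,) framewise displacement; derived Power-style from
                      the six parameters when not supplied.
    """

    translations_mm: np.ndarray
    rotations_deg: np.ndarray
    fd_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.translations_mm, dtype=float)
        r = np.asarray(self.rotations_deg, dtype=float)
        object.__setattr__(self, "translations_mm", t)
        object.__setattr__(self, "rotations_deg", r)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise MalformedMotionError(
                "translations and rotations must both be (T, 3) arrays"
            )
        if t.shape[0] < 1:
            raise MalformedMotionError("motion series must be non-empty")
        if self.fd_mm is not None:
            fd = np.asarray(self.fd_mm, dtype=float)
            if fd.shape != (t.shape[0],):
                raise MalformedMotionError("fd length must match volume count")
            if np.any(fd < 0):
                raise MalformedMotionError("framewise displacement must be >= 0")
            object.__setattr__(self, "fd_mm", fd)

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[0]

    def framewise_displacement(self) -> np.ndarray:
        """FD series: supplied values, or the sum of absolute backward
        differences of the six parameters with rotations mapped to arc
        length on a 50 mm sphere."""
        if self.fd_mm is not None:
            return self.fd_mm
        dt = np.abs(np.diff(self.translations_mm, axis=0))
        dr = np.abs(np.diff(np.deg2rad(self.rotations_deg), axis=0))
        fd = dt.sum(axis=1) + FD_SPHERE_RADIUS_MM * dr.sum(axis=1)
        return np.concatenate([[0.0], fd])


@dataclass(frozen=True)
class QCThresholds:
    """Motion-rejection limits; a scan is excluded when a limit is exceeded
    (strictly — a value exactly at the limit passes)."""

    max_fd_mm: float = 3.0
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 3.0

    def __post_init__(self) -> None:
        if min(self.max_fd_mm, self.max_translation_mm, self.max_rotation_deg) <= 0:
            raise ValueError("QC thresholds must be strictly positive")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    violated: tuple[str, ...]


def motion_qc(motion: MotionParams, thresholds: QCThresholds | None = None) -> QCResult:
    """Apply the head-motion rejection rule.

    A subject fails when maximum framewise displacement exceeds
    ``max_fd_mm``, any translation magnitude exceeds ``max_translation_mm``,
    or any rotation magnitude exceeds ``max_rotation_deg``. The violated
    criteria are named in the result.
    """
    thr = thresholds or QCThresholds()
    violated = []
    if np.max(motion.framewise_displacement()) > thr.max_fd_mm:
        violated.append("framewise_displacement")
    if np.max(np.abs(motion.translations_mm)) > thr.max_translation_mm:
        violated.append("translation")
    if np.max(np.abs(motion.rotations_deg)) > thr.max_rotation_deg:
        violated.append("rotation")
    return QCResult(passed=not violated, violated=tuple(violated))


# --------------------------------------------------------------------------
# connectivity matrix and feature vector
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric inter-network Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    atlas: FBNAtlas = field(default=DEFAULT_ATLAS)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = self.atlas.n_networks
        if v.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {v.shape}")
        object.__setattr__(self, "values", v)

    def at(self, a: str, b: str) -> float:
        return float(self.values[self.atlas.index(a), self.atlas.index(b)])


@dataclass(frozen=True)
class FeatureVector:
    """The lower-triangle connectivity features of one subject, with the
    feature-index -> network-pair map that makes the ordering explicit."""

    values: np.ndarray
    atlas: FBNAtlas = field(default=DEFAULT_ATLAS)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.atlas.n_pairs,):
            raise ValueError(
                f"expected {self.atlas.n_pairs} features, got shape {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def pair_index(self) -> dict[int, tuple[str, str]]:
        return self.atlas.pair_index_map()


def correlation_matrix(
    ts: pd.DataFrame | np.ndarray, atlas: FBNAtlas = DEFAULT_ATLAS
) -> ConnectivityMatrix:
    """Pearson correlation between all network pairs of one subject.

    ``ts`` is a T x n table (rows: timepoints, columns: networks in atlas
    order; a DataFrame is reordered by its column labels). Symmetry and a
    unit diagonal are enforced exactly.
    """
    if isinstance(ts, pd.DataFrame):
        missing = [c for c in atlas.labels if c not in ts.columns]
        if missing:
            raise ValueError(f"time-series table lacks columns {missing}")
        data = ts.loc[:, list(atlas.labels)].to_numpy(dtype=float)
    else:
        data = np.asarray(ts, dtype=float)
    if data.ndim != 2 or data.shape[1] != atlas.n_networks:
        raise ValueError(
            f"expected T x {atlas.n_networks} time series, got {data.shape}"
        )
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [atlas.labels[i] for i in dead]
        raise DegenerateSignalError(
            f"zero-variance time series for network(s) {names}"
        )
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, atlas=atlas)


def vectorize(conn: ConnectivityMatrix, subject_id: str | None = None) -> FeatureVector:
    """Flatten the strict lower triangle (row-major) to the feature vector."""
    rows, cols = conn.atlas.pair_rows_cols()
    return FeatureVector(
        values=conn.values[rows, cols], atlas=conn.atlas, subject_id=subject_id
    )


def devectorize(
    vec: FeatureVector | np.ndarray, atlas: FBNAtlas = DEFAULT_ATLAS
) -> np.ndarray:
    """Reshape a feature vector back to the lower-triangular matrix layout.

    Inverse of :func:`vectorize` on the strict lower triangle; the upper
    triangle and diagonal are zero.
    """
    if isinstance(vec, FeatureVector):
        atlas = vec.atlas
        values = vec.values
    else:
        values = np.asarray(vec, dtype=float)
    if values.shape != (atlas.n_pairs,):
        raise ValueError(f"expected {atlas.n_pairs} features, got {values.shape}")
    n = atlas.n_networks
    out = np.zeros((n, n))
    rows, cols = atlas.pair_rows_cols()
    out[rows, cols] = values
    return out


def vectorize_cohort(
    matrices: list[ConnectivityMatrix], subject_ids: list[str] | None = None
) -> pd.DataFrame:
    """Stack per-subject feature vectors into a subjects x pairs DataFrame
    whose columns are "A|B" pair labels."""
    if not matrices:
        raise ValueError("no connectivity matrices supplied")
    atlas = matrices[0].atlas
    rows, cols = atlas.pair_rows_cols()
    columns = [f"{atlas.labels[i]}|{atlas.labels[j]}" for i, j in zip(rows, cols)]
    data = np.stack([vectorize(m).values for m in matrices])
    index = subject_ids if subject_ids is not None else range(len(matrices))
    return pd.DataFrame(data, index=index, columns=columns)
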