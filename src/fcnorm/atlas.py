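"""Functional brain network (FBN) atlas and pair-index conventions.

The analysis operates on 14 canonical resting-state networks. Inter-network
connectivity lives in a symmetric correlation matrix whose strict lower
triangle is flattened to a fixed-order feature vector; the bijection between
feature index k and unordered network pair (i, j) is defined here and used
everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical ordered labels of the 14 functional brain networks:
#: anterior salience, auditory, basal ganglia, dorsal default mode,
#: higher visual, language, left executive control, posterior salience,
#: precuneus, primary visual, right executive control, sensorimotor,
#: ventral default mode, visuospatial.
DEFAULT_LABELS = (
    "ASN", "AN", "BGN", "DDMN", "HVN", "LN", "LECN",
    "PSN", "PN", "PVN", "RECN", "SN", "VDMN", "VN",
)


@dataclass(frozen=True)
class FBNAtlas:
    """Ordered list of network labels fixing matrix and vector index order.

    The strict lower triangle of an ``n x n`` symmetric matrix is flattened
    row-major: (1,0), (2,0), (2,1), (3,0), ... For the default 14 networks
    this yields 91 features.
    """

    labels: tuple[str, ...] = field(default=DEFAULT_LABELS)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("atlas needs at least two labels")

    @property
    def n_networks(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        n = self.n_networks
        return n * (n - 1) // 2

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown network label {label!r}") from None

    def pair_rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the strict lower triangle, row-major."""
        rows, cols = np.tril_indices(self.n_networks, k=-1)
        return rows, cols

    def pair_to_feature(self, a: str | int, b: str | int) -> int:
        """Feature index k of the unordered pair (a, b)."""
        i = a if isinstance(a, int) else self.index(a)
        j = b if isinstance(b, int) else self.index(b)
        if i == j:
            raise ValueError("self-pairs carry no connectivity feature")
        i, j = max(i, j), min(i, j)
        # row-major strict lower triangle: row i contributes i entries
        return i * (i - 1) // 2 + j

    def feature_to_pair(self, k: int) -> tuple[str, str]:
        """Network labels (row, col) of feature index k."""
        if not 0 <= k < self.n_pairs:
            raise IndexError(f"feature index {k} outside [0, {self.n_pairs})")
        rows, cols = self.pair_rows_cols()
        return self.labels[rows[k]], self.labels[cols[k]]

    def pair_index_map(self) -> dict[int, tuple[str, str]]:
        """Full k -> (label_i, label_j) map, persisted alongside outputs."""
        rows, cols = self.pair_rows_cols()
        return {
            int(k): (self.labels[i], self.labels[j])
            for k, (i, j) in enumerate(zip(rows, cols))
        }


DEFAULT_ATLAS = FBNAtlas()
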