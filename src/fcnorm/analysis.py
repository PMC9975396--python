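"""Deviation statistics on top of the normative model.

Group-level comparison of per-subject reconstruction errors (Shapiro-Wilk
normality report plus Mann-Whitney U), binarized deviation graphs with node
degrees, per-feature error maps

    MSE_f = (1/N) * sum_subjects (fhat - f)^2        (N = group size)

healthy-baseline subtraction, selection of the worst-reconstructed network
pairs, the rule-based characterization of each patient group, and the
individual-level deviation matrix. All absolute differences entering the
thresholding are in standardized (z-score) units, the units the model is
trained in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .atlas import DEFAULT_ATLAS, FBNAtlas
from .connectivity import devectorize

__all__ = [
    "GroupComparison",
    "GroupErrorMatrix",
    "BinarizedDeviationGraph",
    "CharacterizationResult",
    "compare_groups",
    "merged_threshold",
    "binarize_and_degree",
    "group_degree_summary",
    "mse_per_feature",
    "subtract_healthy",
    "top_fraction_pairs",
    "characterize_group",
    "individual_level_matrix",
]


# --------------------------------------------------------------------------
# group comparison of MSE_s
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of two groups' MSE_s distributions.

    Shapiro-Wilk p-values are reported per group but never gate the test:
    the rank test is the primary comparison throughout. No multiple-testing
    correction is applied across comparisons; p-values are raw.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    mannwhitney_u: float
    p_value: float
    method: str


def _mannwhitney(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float, str]:
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if min(a.size, b.size) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"  # normal approximation with tie correction
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), method


def compare_groups(
    mse_by_group: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    alternative: str = "two-sided",
) -> list[GroupComparison]:
    """Shapiro-Wilk per group plus Mann-Whitney U per requested pair.

    The exact null distribution is used when the smaller group has at most
    8 subjects and no ties are present; otherwise the tie-corrected normal
    approximation. Two degenerate identical-constant samples yield p = 1
    with a warning (the test is undefined).
    """
    shapiro: dict[str, float] = {}
    for g, v in mse_by_group.items():
        v = np.asarray(v, dtype=float)
        if v.size < 3:
            raise ValueError(f"group {g!r} needs >= 3 subjects")
        if np.ptp(v) == 0:
            shapiro[g] = float("nan")
        else:
            shapiro[g] = float(stats.shapiro(v).pvalue)
    out = []
    for ga, gb in pairs:
        a = np.asarray(mse_by_group[ga], dtype=float)
        b = np.asarray(mse_by_group[gb], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(
                f"all values identical in {ga} and {gb}; rank test undefined",
                stacklevel=2,
            )
            u, p, method = a.size * b.size / 2.0, 1.0, "degenerate"
        else:
            u, p, method = _mannwhitney(a, b, alternative)
        out.append(
            GroupComparison(
                group_a=ga, group_b=gb, n_a=a.size, n_b=b.size,
                median_a=float(np.median(a)), median_b=float(np.median(b)),
                shapiro_p_a=shapiro[ga], shapiro_p_b=shapiro[gb],
                mannwhitney_u=u, p_value=p, method=method,
            )
        )
    return out


# --------------------------------------------------------------------------
# binarized deviation graphs
# --------------------------------------------------------------------------


def merged_threshold(
    abs_diff_vectors: np.ndarray, top_fraction: float = 0.20
) -> float:
    """Deviation threshold retaining the top fraction of all test subjects'
    absolute differences, merged into one vector.

    The threshold is the empirical (1 - top_fraction) quantile (linear
    interpolation); values >= threshold are retained, so ties at the
    threshold are all kept and the realized retained fraction can exceed
    the nominal one slightly (warned when all values are equal).
    """
    merged = np.asarray(abs_diff_vectors, dtype=float).ravel()
    if merged.size == 0:
        raise ValueError("no values to threshold")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if np.ptp(merged) == 0:
        warnings.warn("all merged values equal; threshold retains everything",
                      stacklevel=2)
        return float(merged[0])
    return float(np.quantile(merged, 1.0 - top_fraction))


@dataclass(frozen=True)
class BinarizedDeviationGraph:
    """One subject's thresholded deviation pattern as a binary graph."""

    adjacency: np.ndarray  # n x n symmetric, zero diagonal
    threshold: float
    degrees: np.ndarray    # per-node degree, 0..n-1
    atlas: FBNAtlas = field(default=DEFAULT_ATLAS)


def binarize_and_degree(
    abs_diff_vector: np.ndarray,
    threshold: float,
    atlas: FBNAtlas = DEFAULT_ATLAS,
) -> BinarizedDeviationGraph:
    """Threshold one subject's absolute-difference vector and compute node
    degrees on the symmetrized binary graph. An edge marks a network pair
    whose reconstruction deviates at least as much as the threshold."""
    vals = np.asarray(abs_diff_vector, dtype=float)
    if vals.shape != (atlas.n_pairs,):
        raise ValueError(f"expected {atlas.n_pairs} features, got {vals.shape}")
    rows, cols = atlas.pair_rows_cols()
    adj = np.zeros((atlas.n_networks, atlas.n_networks), dtype=int)
    sel = vals >= threshold
    adj[rows[sel], cols[sel]] = 1
    adj = adj + adj.T
    graph = nx.from_numpy_array(adj)
    degrees = np.array([graph.degree[i] for i in range(atlas.n_networks)])
    return BinarizedDeviationGraph(
        adjacency=adj, threshold=float(threshold), degrees=degrees, atlas=atlas
    )


def group_degree_summary(
    graphs: list[BinarizedDeviationGraph],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-network median degree over a group, plus the histogram of
    networks by median degree (bins of width 1 over 0..n-1)."""
    if not graphs:
        raise ValueError("need at least one subject graph")
    atlas = graphs[0].atlas
    degs = np.stack([g.degrees for g in graphs])
    medians = np.median(degs, axis=0)
    hist, _ = np.histogram(
        medians, bins=np.arange(atlas.n_networks + 1) - 0.5
    )
    return medians, hist


# --------------------------------------------------------------------------
# per-feature error maps
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupErrorMatrix:
    """Lower-triangular map of per-pair mean squared reconstruction error
    for one group (optionally with the healthy baseline subtracted)."""

    group: str
    values: np.ndarray  # n x n, strict lower triangle populated
    n_subjects: int
    subtracted: bool = False
    atlas: FBNAtlas = field(default=DEFAULT_ATLAS)

    def feature_values(self) -> np.ndarray:
        rows, cols = self.atlas.pair_rows_cols()
        return self.values[rows, cols]

    def at(self, a: str, b: str) -> float:
        i, j = self.atlas.index(a), self.atlas.index(b)
        i, j = max(i, j), min(i, j)
        return float(self.values[i, j])


def mse_per_feature(
    residuals: np.ndarray,
    group: str,
    atlas: FBNAtlas = DEFAULT_ATLAS,
) -> GroupErrorMatrix:
    """MSE_f: mean over the group's subjects of the squared residual, per
    feature, reshaped to the lower-triangular pair layout. ``residuals``
    may be signed or absolute — they are squared either way."""
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.shape[1] != atlas.n_pairs:
        raise ValueError(f"expected {atlas.n_pairs} features, got {r.shape[1]}")
    msef = np.mean(r ** 2, axis=0)
    return GroupErrorMatrix(
        group=group, values=devectorize(msef, atlas), n_subjects=r.shape[0]
    )


def subtract_healthy(
    patient: GroupErrorMatrix, healthy: GroupErrorMatrix
) -> GroupErrorMatrix:
    """Remove the healthy test group's error map from a patient group's,
    isolating error specific to the patients (entries may go negative)."""
    if patient.atlas.labels != healthy.atlas.labels:
        raise ValueError("error matrices use different atlases")
    if healthy.subtracted:
        raise ValueError("healthy baseline is already a subtracted matrix")
    return GroupErrorMatrix(
        group=patient.group,
        values=patient.values - healthy.values,
        n_subjects=patient.n_subjects,
        subtracted=True,
        atlas=patient.atlas,
    )


def top_fraction_pairs(
    matrix: GroupErrorMatrix, fraction: float = 0.10
) -> list[tuple[tuple[str, str], float]]:
    """The worst-reconstructed pairs: floor(fraction * n_pairs) entries with
    the largest values (for fraction 0.10 of 91 pairs, exactly 9).

    Deterministic ordering: descending value, then ascending feature index.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    atlas = matrix.atlas
    vals = matrix.feature_values()
    k = max(1, int(np.floor(fraction * atlas.n_pairs)))
    order = np.lexsort((np.arange(vals.size), -vals))
    return [
        (atlas.feature_to_pair(int(i)), float(vals[i])) for i in order[:k]
    ]


# --------------------------------------------------------------------------
# group characterization
# --------------------------------------------------------------------------


Pair = tuple[str, str]


@dataclass(frozen=True)
class CharacterizationResult:
    """Network pairs that characterize a patient group.

    rule_1: in the top fraction both before and after healthy subtraction,
    under both healthy-test-set conditions (a) and (b) — robustly abnormal.
    rule_3: absent before subtraction but present after, both conditions —
    stable in health, abnormal in patients. rule_2 (before only) pairs are
    reported but not characteristic. characteristic = rule_1 | rule_3.
    """

    group: str
    rule_1: frozenset[Pair]
    rule_3: frozenset[Pair]
    rule_2: frozenset[Pair]

    @property
    def characteristic(self) -> frozenset[Pair]:
        return self.rule_1 | self.rule_3


def _canon(pairs, atlas: FBNAtlas) -> frozenset[Pair]:
    out = set()
    for p in pairs:
        (a, b) = p[0] if isinstance(p[0], tuple) else p
        i, j = atlas.index(a), atlas.index(b)
        i, j = min(i, j), max(i, j)
        out.add((atlas.labels[i], atlas.labels[j]))
    return frozenset(out)


def characterize_group(
    group: str,
    condition_sets: dict[str, dict[str, list]],
    atlas: FBNAtlas = DEFAULT_ATLAS,
) -> CharacterizationResult:
    """Apply the characterization rules over the two analysis conditions.

    ``condition_sets`` maps condition name ("a", "b") to
    ``{"before": pairs, "after": pairs}`` — the top-fraction pair sets
    without and with healthy subtraction (as returned by
    :func:`top_fraction_pairs`, or as plain label pairs).
    """
    for cond in ("a", "b"):
        if cond not in condition_sets:
            raise ValueError(f"missing condition {cond!r}")
        for phase in ("before", "after"):
            if phase not in condition_sets[cond]:
                raise ValueError(f"missing {phase!r} set for condition {cond!r}")
    sets = {
        (cond, phase): _canon(condition_sets[cond][phase], atlas)
        for cond in ("a", "b")
        for phase in ("before", "after")
    }
    rule1 = (
        sets[("a", "before")] & sets[("a", "after")]
        & sets[("b", "before")] & sets[("b", "after")]
    )
    rule3 = (
        (sets[("a", "after")] - sets[("a", "before")])
        & (sets[("b", "after")] - sets[("b", "before")])
    )
    rule2 = (
        (sets[("a", "before")] - sets[("a", "after")])
        | (sets[("b", "before")] - sets[("b", "after")])
    )
    return CharacterizationResult(
        group=group,
        rule_1=frozenset(rule1),
        rule_3=frozenset(rule3),
        rule_2=frozenset(rule2 - rule1 - rule3),
    )


# --------------------------------------------------------------------------
# individual level
# --------------------------------------------------------------------------


def individual_level_matrix(
    characteristic_pairs: list[Pair],
    abs_diff_by_subject: dict[str, np.ndarray],
    healthy_subjects: list[str] | None = None,
    atlas: FBNAtlas = DEFAULT_ATLAS,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-subject absolute deviations restricted to the characteristic
    pairs.

    Returns (matrix, subject_ids, flags): matrix rows follow the order of
    ``abs_diff_by_subject``; ``flags[s]`` is True when subject s exceeds
    the healthy median deviation on at least half of the pairs (a crude
    per-subject heterogeneity summary). When ``healthy_subjects`` is None
    the median over all supplied subjects is used as the reference.
    """
    if not characteristic_pairs:
        raise ValueError("characteristic pair list is empty")
    cols = [atlas.pair_to_feature(a, b) for a, b in characteristic_pairs]
    ids = list(abs_diff_by_subject)
    mat = np.stack([np.asarray(abs_diff_by_subject[s], dtype=float)[cols] for s in ids])
    ref_rows = (
        [ids.index(s) for s in healthy_subjects] if healthy_subjects else range(len(ids))
    )
    healthy_median = np.median(mat[list(ref_rows)], axis=0)
    flags = (mat > healthy_median).sum(axis=1) >= (len(cols) + 1) // 2
    return mat, ids, flags
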