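"""Synthetic multi-subject cohorts with known connectivity structure.

Generates network time series whose population correlation structure is
controlled: healthy subjects are drawn around a block-structured template,
patient groups around the same template with a few edges offset by a known
delta. Because the injected abnormalities are recorded in a truth manifest,
every downstream stage (feature extraction, normative model, deviation
localization) can be tested for recovery of a known answer.

Time series are multivariate Gaussian: the analysis consumes nothing beyond
second-order structure (Pearson correlation), so Gaussianity is a sufficient
generative law. Subject-level variability is additive Gaussian jitter on the
off-diagonal correlations followed by projection back onto the valid
(positive-definite, unit-diagonal) correlation manifold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, FBNAtlas
from .connectivity import MotionParams

__all__ = [
    "CohortConfig",
    "Cohort",
    "TruthManifest",
    "InvalidPerturbationError",
    "ConfigError",
    "nearest_correlation",
    "make_base_correlation",
    "perturb_correlation",
    "sample_subject_timeseries",
    "generate_cohort",
    "generate_motion_table",
    "default_config",
    "DEFAULT_BLOCKS",
]


class InvalidPerturbationError(ValueError):
    """An edge offset pushes a correlation outside (-1, 1)."""


class ConfigError(ValueError):
    """Cohort configuration is internally inconsistent."""


# --------------------------------------------------------------------------
# correlation templates
# --------------------------------------------------------------------------

_EIG_FLOOR = 1e-6
_MIN_EIG = 1e-8


def nearest_correlation(mat: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix.

    Eigenvalues are clipped from below and the result rescaled to a unit
    diagonal, iterating until the smallest eigenvalue clears ``_MIN_EIG``.
    For matrices that are already positive definite this is the identity map
    up to the symmetrization.
    """
    a = np.asarray(mat, dtype=float)
    a = (a + a.T) / 2.0
    for _ in range(100):
        w, v = np.linalg.eigh(a)
        if w.min() > _MIN_EIG:
            break
        w = np.clip(w, eig_floor, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


#: Default grouping of the 14 networks into correlated modules: visual,
#: default-mode, executive-control, salience, sensory-motor/auditory, and
#: two singleton networks.
DEFAULT_BLOCKS: tuple[tuple[str, ...], ...] = (
    ("HVN", "PVN"),
    ("DDMN", "VDMN", "PN", "LN"),
    ("LECN", "RECN"),
    ("ASN", "PSN"),
    ("SN", "AN"),
    ("BGN",),
    ("VN",),
)


def make_base_correlation(
    atlas: FBNAtlas = DEFAULT_ATLAS,
    block_structure: tuple[tuple[str, ...], ...] | None = DEFAULT_BLOCKS,
    seed: int = 0,
    within: float = 0.45,
    between: float = 0.10,
    noise_sd: float = 0.03,
) -> np.ndarray:
    """Population-level correlation template with modular block structure.

    Entries within a block are centred on ``within``, entries between blocks
    on ``between``, with small seeded heterogeneity of scale ``noise_sd``;
    the matrix is then projected to the nearest valid correlation matrix.
    """
    n = atlas.n_networks
    if block_structure is None:
        block_structure = (atlas.labels,)
    members = [lbl for blk in block_structure for lbl in blk]
    if sorted(members) != sorted(atlas.labels):
        raise ConfigError("block structure must partition the atlas labels")
    block_of = {lbl: b for b, blk in enumerate(block_structure) for lbl in blk}
    base = np.full((n, n), between)
    for i, li in enumerate(atlas.labels):
        for j, lj in enumerate(atlas.labels):
            if block_of[li] == block_of[lj]:
                base[i, j] = within
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        base = base + (noise + noise.T) / 2.0
    np.fill_diagonal(base, 1.0)
    return nearest_correlation(base)


def perturb_correlation(
    base: np.ndarray,
    perturbations: list[tuple[tuple[str, str], float]],
    atlas: FBNAtlas = DEFAULT_ATLAS,
) -> np.ndarray:
    """Offset chosen edges of a correlation template by known deltas.

    Each perturbation is ``((label_a, label_b), delta)``; the resulting
    entry must stay inside (-1, 1). The matrix is re-projected only if the
    offsets break positive definiteness, so unperturbed entries are
    preserved up to the projection tolerance.
    """
    out = np.array(base, dtype=float, copy=True)
    if not perturbations:
        return out
    for (la, lb), delta in perturbations:
        i, j = atlas.index(la), atlas.index(lb)
        if i == j:
            raise InvalidPerturbationError("cannot perturb a diagonal entry")
        val = out[i, j] + delta
        if not -1.0 < val < 1.0:
            raise InvalidPerturbationError(
                f"perturbed correlation {la}-{lb} = {val:.3f} outside (-1, 1)"
            )
        out[i, j] = out[j, i] = val
    if np.linalg.eigvalsh(out).min() <= _MIN_EIG:
        out = nearest_correlation(out)
    return out


# --------------------------------------------------------------------------
# subject sampling
# --------------------------------------------------------------------------


def _jitter_template(
    template: np.ndarray, subject_sd: float, rng: np.random.Generator
) -> np.ndarray:
    if subject_sd == 0:
        return nearest_correlation(template)
    n = template.shape[0]
    noise = rng.normal(0.0, subject_sd, size=(n, n))
    jittered = template + (noise + noise.T) / 2.0
    iu = np.triu_indices(n, 1)
    jittered[iu] = np.clip(jittered[iu], -0.99, 0.99)
    jittered.T[iu] = jittered[iu]
    np.fill_diagonal(jittered, 1.0)
    return nearest_correlation(jittered)


def sample_subject_timeseries(
    template: np.ndarray,
    subject_sd: float,
    n_timepoints: int,
    seed: int | np.random.SeedSequence,
    atlas: FBNAtlas = DEFAULT_ATLAS,
) -> pd.DataFrame:
    """Draw one subject's T x n network time series.

    The subject's own correlation matrix is a jittered, re-projected copy of
    ``template``; the series are i.i.d. multivariate normal draws from it,
    with columns standardized to zero mean and unit variance (cosmetic:
    Pearson correlation is scale-invariant).
    """
    if n_timepoints < 30:
        raise ValueError("n_timepoints must be >= 30")
    rng = np.random.default_rng(seed)
    subj_corr = _jitter_template(np.asarray(template, dtype=float), subject_sd, rng)
    chol = np.linalg.cholesky(subj_corr)
    data = rng.standard_normal((n_timepoints, atlas.n_networks)) @ chol.T
    data = (data - data.mean(axis=0)) / data.std(axis=0)
    return pd.DataFrame(data, columns=list(atlas.labels))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort deterministically.

    n_per_group maps named sets (e.g. H-Train, SCZ-Test-U) to subject
    counts; groups whose name starts with "H-" are healthy and sampled from
    the unperturbed template. perturbations maps patient-group names to
    lists of ((label_a, label_b), delta) edge offsets.
    """

    n_per_group: dict[str, int]
    n_timepoints: int = 150
    base_correlation: np.ndarray | None = None
    subject_sd: float = 0.06
    perturbations: dict[str, list[tuple[tuple[str, str], float]]] = field(
        default_factory=dict
    )
    seed: int = 0
    atlas: FBNAtlas = field(default=DEFAULT_ATLAS)
    include_motion: bool = False

    def validate(self) -> None:
        healthy = [g for g in self.n_per_group if g.startswith("H-")]
        if not any("Train" in g for g in healthy):
            raise ConfigError("need a healthy training group (H-*Train*)")
        if not any("Test" in g for g in healthy):
            raise ConfigError("need a healthy test group (H-*Test*)")
        unknown = set(self.perturbations) - set(self.n_per_group)
        if unknown:
            raise ConfigError(f"perturbations reference unknown group(s) {sorted(unknown)}")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ConfigError("all group sizes must be >= 1")
        if not 0 < self.n_timepoints:
            raise ConfigError("n_timepoints must be positive")


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth of a generated cohort: which edges were perturbed."""

    perturbed: dict[str, list[dict]]
    # group -> [{"pair": [a, b], "delta": d, "feature": k}, ...]

    def pairs(self, group: str) -> set[int]:
        return {rec["feature"] for rec in self.perturbed.get(group, [])}

    def to_json(self) -> str:
        return json.dumps(self.perturbed, indent=2)


@dataclass(frozen=True)
class Cohort:
    """In-memory generated cohort: manifest plus per-subject time series."""

    manifest: pd.DataFrame  # subject_id, group, seed_counter
    timeseries: dict[str, pd.DataFrame]
    truth: TruthManifest
    config: CohortConfig
    motion: dict[str, MotionParams] | None = None

    def subjects(self, group: str) -> list[str]:
        return list(self.manifest.loc[self.manifest["group"] == group, "subject_id"])

    def group_timeseries(self, group: str) -> list[pd.DataFrame]:
        return [self.timeseries[s] for s in self.subjects(group)]


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full cohort (deterministic given the config seed).

    Per-subject seeds are spawned from the master seed by a stable counter
    scheme — subject i (in manifest order) always receives child seed i — so
    enlarging a group appends subjects without reshuffling existing ones.
    With ``out_dir`` the cohort is also written to disk: one TSV per
    subject, a manifest TSV and a truth-manifest JSON.
    """
    config.validate()
    atlas = config.atlas
    base = (
        np.asarray(config.base_correlation, dtype=float)
        if config.base_correlation is not None
        else make_base_correlation(atlas, seed=config.seed)
    )
    templates: dict[str, np.ndarray] = {}
    truth: dict[str, list[dict]] = {}
    for group in config.n_per_group:
        perts = config.perturbations.get(group, [])
        templates[group] = perturb_correlation(base, perts, atlas)
        if perts:
            truth[group] = [
                {
                    "pair": [a, b],
                    "delta": float(d),
                    "feature": atlas.pair_to_feature(a, b),
                }
                for (a, b), d in perts
            ]

    rows = []
    timeseries: dict[str, pd.DataFrame] = {}
    motion: dict[str, MotionParams] = {}
    counter = 0
    master = np.random.SeedSequence(config.seed)
    for group, n_subj in config.n_per_group.items():
        for i in range(n_subj):
            subject_id = f"{group}_{i:03d}"
            child = np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(counter,)
            )
            timeseries[subject_id] = sample_subject_timeseries(
                templates[group],
                config.subject_sd,
                config.n_timepoints,
                child,
                atlas,
            )
            if config.include_motion:
                motion[subject_id] = generate_motion_table(
                    config.n_timepoints, contaminate=False, seed=child.spawn(1)[0]
                )
            rows.append({"subject_id": subject_id, "group": group, "seed_counter": counter})
            counter += 1
    manifest = pd.DataFrame(rows)
    cohort = Cohort(
        manifest=manifest,
        timeseries=timeseries,
        truth=TruthManifest(perturbed=truth),
        config=config,
        motion=motion if config.include_motion else None,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    paths = []
    for sid in cohort.manifest["subject_id"]:
        path = ts_dir / f"{sid}.tsv"
        cohort.timeseries[sid].to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths.append(str(path.relative_to(out_dir)))
    manifest = cohort.manifest.copy()
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    (out_dir / "truth_manifest.json").write_text(cohort.truth.to_json())


def load_cohort(out_dir: str | Path) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], TruthManifest]:
    """Read back a cohort written by :func:`generate_cohort`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.tsv", sep="\t")
    timeseries = {
        row.subject_id: pd.read_csv(out_dir / row.path, sep="\t")
        for row in manifest.itertuples()
    }
    truth = TruthManifest(
        perturbed=json.loads((out_dir / "truth_manifest.json").read_text())
    )
    return manifest, timeseries, truth


# --------------------------------------------------------------------------
# motion fixtures
# --------------------------------------------------------------------------


def generate_motion_table(
    n_volumes: int, contaminate: bool, seed: int | np.random.SeedSequence
) -> MotionParams:
    """Plausible realignment-parameter table for one scan.

    Translations and rotations follow small-amplitude random walks kept well
    inside the rejection limits; with ``contaminate=True`` a single large
    translation spike is injected, guaranteeing the motion-rejection rule
    fires (it exceeds both the translation and the framewise-displacement
    limits).
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    rng = np.random.default_rng(seed)
    trans = np.cumsum(rng.normal(0.0, 0.02, size=(n_volumes, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 0.01, size=(n_volumes, 3)), axis=0)
    # rescale so the clean table passes QC with margin
    trans *= min(1.0, 1.0 / max(1e-9, np.abs(trans).max()))
    rot *= min(1.0, 1.0 / max(1e-9, np.abs(rot).max()))
    if contaminate:
        spike = int(rng.integers(1, n_volumes))
        trans[spike, 0] += 4.0
    return MotionParams(translations_mm=trans, rotations_deg=rot)


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

#: Edge offsets injected per patient group (the known "abnormal" pairs).
DEFAULT_PERTURBATIONS: dict[str, list[tuple[tuple[str, str], float]]] = {
    "SCZ-Test-U": [(("ASN", "BGN"), 0.4), (("BGN", "HVN"), 0.4), (("HVN", "RECN"), 0.4)],
    "BD-Test-U": [(("BGN", "DDMN"), 0.4), (("BGN", "LN"), 0.4), (("HVN", "PVN"), 0.4)],
    "ADHD-Test-U": [(("ASN", "LN"), 0.4), (("ASN", "PN"), 0.4), (("LN", "RECN"), 0.4)],
    # independent replication cohort shares SCZ's injected pairs
    "SCZ-Test-C": [(("ASN", "BGN"), 0.4), (("BGN", "HVN"), 0.4), (("HVN", "RECN"), 0.4)],
}


def default_config(seed: int = 0, include_replication: bool = True) -> CohortConfig:
    """The package's reference synthetic study: 200 healthy training
    subjects, 30 subjects per test group, 150 timepoints, three edges offset
    by 0.4 per patient group."""
    n_per_group = {
        "H-Train": 200,
        "H-Test-U": 30,
        "SCZ-Test-U": 30,
        "BD-Test-U": 30,
        "ADHD-Test-U": 30,
    }
    perts = {k: v for k, v in DEFAULT_PERTURBATIONS.items() if k != "SCZ-Test-C"}
    if include_replication:
        n_per_group["H-Test-C"] = 30
        n_per_group["SCZ-Test-C"] = 30
        perts["SCZ-Test-C"] = DEFAULT_PERTURBATIONS["SCZ-Test-C"]
    return CohortConfig(n_per_group=n_per_group, perturbations=perts, seed=seed)
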