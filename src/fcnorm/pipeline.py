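"""End-to-end orchestration: simulate, extract features, train, analyze.

`run_pipeline` ties the stages together under one master seed and writes
every result as a machine-readable file (delimited tables and JSON) in a
run directory; nothing is reported only as a figure. The same entry points
are exposed through a thin command-line interface (`fcnorm simulate`,
`fcnorm run-all`).

Stage seeds are fanned out from the master seed through named spawn keys,
so the cohort, the model and any condition-(b) retraining each get an
independent, reproducible stream.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from . import model as md
from . import simulate as sim
from .atlas import DEFAULT_ATLAS
from .connectivity import correlation_matrix, motion_qc, vectorize_cohort

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline", "main"]


def _stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort: sim.CohortConfig
    model: md.AutoencoderSpec = field(default_factory=md.AutoencoderSpec)
    top_fraction_degree: float = 0.20
    top_fraction_pairs: float = 0.10
    alpha: float = 0.05
    baseline_healthy_test: str = "H-Test-U"
    replication_suffix: str = "-C"
    run_condition_b: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        cohort_raw = raw.pop("cohort", None)
        if cohort_raw is None:
            cohort = sim.default_config(seed=seed)
        else:
            cohort_raw = dict(cohort_raw)
            perts = {
                g: [((a, b), float(d)) for (a, b), d in
                    (((p["pair"][0], p["pair"][1]), p["delta"]) for p in plist)]
                for g, plist in cohort_raw.pop("perturbations", {}).items()
            }
            cohort = sim.CohortConfig(
                n_per_group=dict(cohort_raw.pop("n_per_group")),
                perturbations=perts,
                seed=int(cohort_raw.pop("seed", seed)),
                **cohort_raw,
            )
        model = md.AutoencoderSpec(**raw.pop("model", {}))
        return cls(cohort=cohort, model=model, seed=seed, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def validate_config(config: RunConfig) -> list[str]:
    """Structured diagnostics; an empty list means the config is runnable."""
    diags: list[str] = []
    try:
        config.cohort.validate()
    except sim.ConfigError as exc:
        diags.append(str(exc))
    for name in ("top_fraction_degree", "top_fraction_pairs"):
        val = getattr(config, name)
        if not 0 < val < 1:
            diags.append(f"{name} = {val} outside (0, 1)")
    if not 0 < config.alpha < 1:
        diags.append(f"alpha = {config.alpha} outside (0, 1)")
    groups = set(config.cohort.n_per_group)
    if config.baseline_healthy_test not in groups:
        diags.append(
            f"baseline healthy test group {config.baseline_healthy_test!r} "
            "not in cohort"
        )
    train = [g for g in groups if g.startswith("H-") and "Train" in g]
    if train and config.cohort.n_per_group.get(train[0], 0) == 0:
        diags.append("healthy training group is empty")
    return diags


@dataclass
class RunReport:
    """Everything one run computed, plus where it was written."""

    config: RunConfig
    qc_excluded: list[str]
    comparisons: list[an.GroupComparison]
    threshold: float
    degree_medians: dict[str, np.ndarray]
    degree_histograms: dict[str, np.ndarray]
    msef: dict[str, an.GroupErrorMatrix]
    msef_subtracted: dict[str, an.GroupErrorMatrix]
    top_pairs: dict[str, dict[str, list]]  # group -> {"before": .., "after": ..}
    characterizations: dict[str, an.CharacterizationResult]
    individual: dict[str, tuple[np.ndarray, list[str], np.ndarray]]
    mse_s: dict[str, np.ndarray]
    invariant_checks: dict[str, bool]
    warnings: list[str]
    timings: dict[str, float]
    out_dir: Path | None = None

    @property
    def ok(self) -> bool:
        return all(self.invariant_checks.values())


def _features_by_group(cohort: sim.Cohort, groups: list[str]) -> dict[str, pd.DataFrame]:
    out = {}
    for g in groups:
        ids = cohort.subjects(g)
        mats = [correlation_matrix(cohort.timeseries[s], cohort.config.atlas) for s in ids]
        out[g] = vectorize_cohort(mats, ids)
    return out


def _evaluate_condition(
    train_X: np.ndarray,
    test_features: dict[str, pd.DataFrame],
    spec: md.AutoencoderSpec,
) -> tuple[md.TrainedModel, dict[str, md.ReconstructionResult], dict[str, np.ndarray]]:
    """Standardize on the training rows, train, and score every test set."""
    std = md.fit_standardizer(train_X)
    model = md.train_autoencoder(spec, md.apply_standardizer(std, train_X), std)
    recon, z = {}, {}
    for g, feats in test_features.items():
        zg = md.apply_standardizer(std, feats.to_numpy())
        z[g] = zg
        recon[g] = md.reconstruct(model, zg)
    return model, recon, z


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full analysis under one master seed.

    Stages: cohort simulation (with motion QC when motion tables exist) ->
    connectivity features -> normative-model training on the healthy
    training group -> deviation statistics, including the condition-(b)
    re-split (healthy test set doubled, model retrained from scratch) and
    the rule-based characterization of each patient group.
    """
    diags = validate_config(config)
    if diags:
        raise sim.ConfigError("; ".join(diags))
    caught: list[str] = []
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    cohort_cfg = dataclasses.replace(config.cohort, seed=_stage_seed(config.seed, 0))
    cohort = sim.generate_cohort(cohort_cfg)
    timings["simulate"] = time.perf_counter() - t0

    # motion QC (only when motion tables were generated)
    qc_excluded: list[str] = []
    if cohort.motion:
        for sid, motion in cohort.motion.items():
            if not motion_qc(motion).passed:
                qc_excluded.append(sid)

    t0 = time.perf_counter()
    groups = [g for g in cohort_cfg.n_per_group]
    train_group = next(g for g in groups if g.startswith("H-") and "Train" in g)
    test_groups = [g for g in groups if g != train_group]
    feats = _features_by_group(cohort, groups)
    for g in feats:  # drop QC-excluded subjects
        keep = [s for s in feats[g].index if s not in qc_excluded]
        feats[g] = feats[g].loc[keep]
    timings["connectivity"] = time.perf_counter() - t0

    # condition (a): the configured split
    t0 = time.perf_counter()
    spec_a = config.model.with_(seed=_stage_seed(config.seed, 1))
    test_feats = {g: feats[g] for g in test_groups}
    _, recon_a, _ = _evaluate_condition(
        feats[train_group].to_numpy(), test_feats, spec_a
    )
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    h_test = config.baseline_healthy_test
    repl = [g for g in test_groups if g.endswith(config.replication_suffix)]
    core_tests = [g for g in test_groups if g not in repl]
    patient_groups = [g for g in core_tests if not g.startswith("H-")]

    mse_s = {g: recon_a[g].mse_s for g in test_groups}

    # group comparisons: healthy vs each patient, patients pairwise, and the
    # replication set against its own healthy baseline when present
    pairs = [(h_test, g) for g in patient_groups]
    pairs += [
        (a, b) for i, a in enumerate(patient_groups) for b in patient_groups[i + 1:]
    ]
    h_repl = [g for g in repl if g.startswith("H-")]
    if h_repl:
        pairs.append((h_test, h_repl[0]))
        pairs += [(h_repl[0], g) for g in repl if not g.startswith("H-")]
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        comparisons = an.compare_groups(mse_s, pairs)
        caught += [str(w.message) for w in wlist]

    # merged threshold over the core test sets; replication sets reuse it
    merged = np.vstack([recon_a[g].abs_diff for g in core_tests])
    threshold = an.merged_threshold(merged, config.top_fraction_degree)
    degree_medians, degree_histograms = {}, {}
    for g in test_groups:
        graphs = [
            an.binarize_and_degree(v, threshold, cohort_cfg.atlas)
            for v in recon_a[g].abs_diff
        ]
        degree_medians[g], degree_histograms[g] = an.group_degree_summary(graphs)

    # per-feature error maps and healthy subtraction
    msef = {
        g: an.mse_per_feature(recon_a[g].abs_diff, g, cohort_cfg.atlas)
        for g in test_groups
    }
    msef_subtracted = {
        g: an.subtract_healthy(msef[g], msef[h_test])
        for g in patient_groups
    }
    for g in repl:
        if not g.startswith("H-") and h_repl:
            msef_subtracted[g] = an.subtract_healthy(msef[g], msef[h_repl[0]])

    top_pairs: dict[str, dict[str, list]] = {}
    for g, mat in msef.items():
        top_pairs[g] = {"before": an.top_fraction_pairs(mat, config.top_fraction_pairs)}
        if g in msef_subtracted:
            top_pairs[g]["after"] = an.top_fraction_pairs(
                msef_subtracted[g], config.top_fraction_pairs
            )

    # condition (b): double the healthy test set from the training pool and
    # retrain from scratch on the reduced training set
    characterizations: dict[str, an.CharacterizationResult] = {}
    if config.run_condition_b and patient_groups:
        n_extra = feats[h_test].shape[0]
        train_ids = list(feats[train_group].index)
        moved, reduced = train_ids[-n_extra:], train_ids[:-n_extra]
        feats_b = dict(test_feats)
        feats_b[h_test] = pd.concat(
            [feats[h_test], feats[train_group].loc[moved]]
        )
        spec_b = config.model.with_(seed=_stage_seed(config.seed, 2))
        _, recon_b, _ = _evaluate_condition(
            feats[train_group].loc[reduced].to_numpy(), feats_b, spec_b
        )
        msef_b = {
            g: an.mse_per_feature(recon_b[g].abs_diff, g, cohort_cfg.atlas)
            for g in [h_test, *patient_groups]
        }
        for g in patient_groups:
            sub_b = an.subtract_healthy(msef_b[g], msef_b[h_test])
            characterizations[g] = an.characterize_group(
                g,
                {
                    "a": {
                        "before": top_pairs[g]["before"],
                        "after": top_pairs[g]["after"],
                    },
                    "b": {
                        "before": an.top_fraction_pairs(
                            msef_b[g], config.top_fraction_pairs
                        ),
                        "after": an.top_fraction_pairs(
                            sub_b, config.top_fraction_pairs
                        ),
                    },
                },
                cohort_cfg.atlas,
            )

    # individual-level deviation maps on the characteristic pairs
    individual = {}
    for g, char in characterizations.items():
        if not char.characteristic:
            continue
        subjects = {}
        for tg in (h_test, g):
            for sid, row in zip(feats[tg].index, recon_a[tg].abs_diff):
                subjects[sid] = row
        individual[g] = an.individual_level_matrix(
            sorted(char.characteristic),
            subjects,
            healthy_subjects=list(feats[h_test].index),
            atlas=cohort_cfg.atlas,
        )
    timings["analysis"] = time.perf_counter() - t0

    # invariant: mean-over-subjects MSE_s == mean-over-features MSE_f
    checks = {}
    for g in test_groups:
        lhs = float(np.mean(mse_s[g]))
        rhs = float(np.mean(msef[g].feature_values()))
        checks[f"conservation[{g}]"] = abs(lhs - rhs) < 1e-10

    report = RunReport(
        config=config,
        qc_excluded=qc_excluded,
        comparisons=comparisons,
        threshold=threshold,
        degree_medians=degree_medians,
        degree_histograms=degree_histograms,
        msef=msef,
        msef_subtracted=msef_subtracted,
        top_pairs=top_pairs,
        characterizations=characterizations,
        individual=individual,
        mse_s=mse_s,
        invariant_checks=checks,
        warnings=caught,
        timings=timings,
    )
    if out_dir is not None:
        report.out_dir = Path(out_dir)
        _write_report(report, cohort, Path(out_dir))
    return report


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------


def _matrix_frame(mat: an.GroupErrorMatrix) -> pd.DataFrame:
    labels = list(mat.atlas.labels)
    return pd.DataFrame(mat.values, index=labels, columns=labels)


def _edge_list(pairs: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(a, b, v) for (a, b), v in pairs], columns=["node_i", "node_j", "weight"]
    )


def _write_report(report: RunReport, cohort: sim.Cohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim._write_cohort(cohort, out / "cohort")

    pd.DataFrame([dataclasses.asdict(c) for c in report.comparisons]).to_csv(
        out / "group_comparisons.tsv", sep="\t", index=False
    )
    box = []
    for g, v in report.mse_s.items():
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        box.append({"group": g, "n": v.size, "q1": q1, "median": q2, "q3": q3,
                    "min": v.min(), "max": v.max()})
    pd.DataFrame(box).to_csv(out / "mse_s_boxplot_summary.tsv", sep="\t", index=False)
    pd.DataFrame(report.mse_s).to_csv(out / "mse_s_by_group.tsv", sep="\t", index=False)

    labels = list(report.config.cohort.atlas.labels)
    pd.DataFrame(report.degree_medians, index=labels).to_csv(
        out / "degree_medians.tsv", sep="\t"
    )
    pd.DataFrame(report.degree_histograms).to_csv(
        out / "degree_histograms.tsv", sep="\t", index_label="median_degree"
    )
    for g, mat in report.msef.items():
        _matrix_frame(mat).to_csv(out / f"msef_{g}.tsv", sep="\t")
    for g, mat in report.msef_subtracted.items():
        _matrix_frame(mat).to_csv(out / f"msef_subtracted_{g}.tsv", sep="\t")
    for g, phases in report.top_pairs.items():
        for phase, pairs in phases.items():
            _edge_list(pairs).to_csv(
                out / f"connectogram_{g}_{phase}.tsv", sep="\t", index=False
            )
    char_json = {
        g: {
            "rule_1": sorted(map(list, c.rule_1)),
            "rule_3": sorted(map(list, c.rule_3)),
            "rule_2_non_characteristic": sorted(map(list, c.rule_2)),
            "characteristic": sorted(map(list, c.characteristic)),
        }
        for g, c in report.characterizations.items()
    }
    (out / "characterization.json").write_text(json.dumps(char_json, indent=2))
    for g, (mat, ids, flags) in report.individual.items():
        char = sorted(report.characterizations[g].characteristic)
        df = pd.DataFrame(mat, index=ids, columns=[f"{a}|{b}" for a, b in char])
        df["above_healthy_median"] = flags
        df.to_csv(out / f"individual_{g}.tsv", sep="\t", index_label="subject_id")

    meta = {
        "seed": report.config.seed,
        "realized_threshold": report.threshold,
        "top_fraction_degree": report.config.top_fraction_degree,
        "top_fraction_pairs": report.config.top_fraction_pairs,
        "qc_excluded": report.qc_excluded,
        "invariant_checks": report.invariant_checks,
        "warnings": report.warnings,
        "timings_s": report.timings,
        "note": "raw p-values; no multiple-testing correction applied",
    }
    (out / "run_report.json").write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="fcnorm",
        description="Normative modeling of inter-network functional connectivity",
    )
    sub = parser.add_subparsers(dest="command", required=True)
    p_sim = sub.add_parser("simulate", help="generate a synthetic cohort")
    p_sim.add_argument("--config", help="YAML run config", default=None)
    p_sim.add_argument("--seed", type=int, default=0)
    p_sim.add_argument("--out", required=True)
    p_run = sub.add_parser("run-all", help="run the full pipeline")
    p_run.add_argument("--config", help="YAML run config", default=None)
    p_run.add_argument("--seed", type=int, default=None)
    p_run.add_argument("--out", required=True)
    args = parser.parse_args(argv)

    if args.config:
        config = RunConfig.from_yaml(args.config)
    else:
        config = RunConfig(cohort=sim.default_config(), seed=0)
    if getattr(args, "seed", None) is not None:
        config = dataclasses.replace(
            config,
            seed=args.seed,
            cohort=dataclasses.replace(config.cohort, seed=args.seed),
        )

    if args.command == "simulate":
        sim.generate_cohort(config.cohort, out_dir=args.out)
        print(f"cohort written to {args.out}")
        return 0
    report = run_pipeline(config, out_dir=args.out)
    print(f"run written to {args.out}; realized threshold {report.threshold:.4f}")
    for c in report.comparisons:
        print(f"  {c.group_a} vs {c.group_b}: U={c.mannwhitney_u:.1f} p={c.p_value:.4g}")
    return 0 if report.ok else 1


if __name__ == "__main__":
    sys.exit(main())
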