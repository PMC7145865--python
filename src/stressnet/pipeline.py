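"""End-to-end orchestration: simulate or load a cohort, then run
connectivity profiling, the FDR screen, SVR prediction, mediation, and
dot-probe scoring, with reproducible seeding and a written manifest.

A master seed deterministically spawns one sub-seed per stochastic stage
(simulation, fold assignment/permutations, bootstrap), so any stage can be
rerun in isolation and a rerun of the whole analysis with the same config
is identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    NetworkPartition,
    TimeSeriesMatrix,
    ConnectivityProfiler,
    profiles_to_tidy,
    profile_cohort,
    profiles_to_frame,
)
from .dotprobe import DotProbeScorer
from .mediation import render_path_diagram, run_cohort_models
from .prediction import cv_predict, permutation_pvalue
from .screening import COVARIATES_BASIC, COVARIATES_EXTENDED, screen
from .synthetic import CohortSpec, DotProbeSpec, simulate_behavior, simulate_dotprobe, simulate_timeseries

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "dotprobe", "prediction", "mediation")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully serializable description of one analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    dotprobe: DotProbeSpec | None = field(default_factory=DotProbeSpec)
    data_dir: str | None = None  # load user data instead of simulating
    diagonal_policy: str = "literal"
    screen_target: str = "els"
    screen_covariates: tuple[str, ...] = COVARIATES_BASIC
    q: float = 0.05
    cv_k: int = 4
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    n_perm: int = 199
    prediction_covariates: tuple[str, ...] = COVARIATES_EXTENDED
    n_boot: int = 2000
    ci_level: float = 0.95
    mediation_method: str = "bias_corrected"
    mediation_covariates: tuple[str, ...] = ("age", "sex")
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage sub-seeds spawned deterministically from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
            for name, child in zip(_STAGES, children)
        }

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "dotprobe": self.dotprobe.to_dict() if self.dotprobe else None,
            "data_dir": self.data_dir,
            "diagonal_policy": self.diagonal_policy,
            "screen_target": self.screen_target,
            "screen_covariates": list(self.screen_covariates),
            "q": self.q,
            "cv_k": self.cv_k,
            "svr_C": self.svr_C,
            "svr_epsilon": self.svr_epsilon,
            "n_perm": self.n_perm,
            "prediction_covariates": list(self.prediction_covariates),
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "mediation_method": self.mediation_method,
            "mediation_covariates": list(self.mediation_covariates),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        data = dict(data)
        cohort = data.pop("cohort", {})
        if isinstance(cohort, Mapping):
            cohort = dict(cohort)
            if "partition_sizes" in cohort:
                cohort["partition_sizes"] = tuple(
                    (str(n), int(c)) for n, c in cohort["partition_sizes"]
                )
            if "mediation_coeffs" in cohort:
                cohort["mediation_coeffs"] = tuple(cohort["mediation_coeffs"])
            cohort = CohortSpec(**cohort)
        probe = data.pop("dotprobe", None)
        if isinstance(probe, Mapping):
            probe = DotProbeSpec(**probe)
        for key in ("screen_covariates", "prediction_covariates", "mediation_covariates"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(cohort=cohort, dotprobe=probe, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_cohort(data_dir: Path, diagonal_policy: str):
    partition = NetworkPartition.from_csv(data_dir / "partition.csv")
    ts_dir = data_dir / "timeseries"
    files = sorted(ts_dir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no time-series TSVs under {ts_dir}")
    profiles = profile_cohort(files, partition, diagonal_policy)
    features = profiles_to_frame(profiles)
    behavior = pd.read_csv(data_dir / "behavior.csv")
    trials_path = data_dir / "dotprobe_trials.csv"
    trials = pd.read_csv(trials_path) if trials_path.exists() else None
    return partition, features, behavior, trials


def _simulate_cohort(config: AnalysisConfig, seeds: dict[str, int]):
    spec = dataclasses.replace(config.cohort, seed=seeds["simulate"])
    partition = spec.partition()
    profiler = ConnectivityProfiler(
        partition=partition, diagonal_policy=config.diagonal_policy
    ).fit([])
    features = profiler.transform(
        simulate_timeseries(spec, i) for i in range(spec.n_subjects)
    )
    behavior = simulate_behavior(spec, m_values=features[spec.mediator_measure].to_numpy())
    trials = None
    if config.dotprobe is not None:
        probe_spec = dataclasses.replace(config.dotprobe, seed=seeds["dotprobe"])
        trials = simulate_dotprobe(probe_spec)
    return partition, features, behavior, trials


def analyze_cohort(config: AnalysisConfig) -> dict[str, Any]:
    """Run every analysis stage in memory and return the result bundle.

    Keys of the returned dict: ``features`` (subject-by-measure frame),
    ``behavior``, ``bias_scores`` (wide frame or None), ``screen``
    (measure/r/p/p_adj/significant frame), ``prediction`` (r, permutation p,
    params), ``mediation`` (name -> MediationResult), ``seeds``.
    """
    seeds = config.stage_seeds()
    stage = "input"
    try:
        if config.data_dir is not None:
            partition, features, behavior, trials = _load_cohort(
                Path(config.data_dir), config.diagonal_policy
            )
        else:
            partition, features, behavior, trials = _simulate_cohort(config, seeds)

        stage = "dotprobe"
        bias_scores = None
        if trials is not None:
            scorer = DotProbeScorer()
            bias_scores = scorer.transform(trials)

        stage = "screen"
        screen_results = screen(
            features, behavior,
            target=config.screen_target,
            covariates=config.screen_covariates,
            q=config.q,
        )

        stage = "prediction"
        beh = behavior.set_index("subject_id").loc[features.index]
        y = beh[config.screen_target].to_numpy(dtype=float)
        cov = (
            beh[list(config.prediction_covariates)].to_numpy(dtype=float)
            if config.prediction_covariates
            else None
        )
        p_perm, r_pred = permutation_pvalue(
            features.to_numpy(dtype=float), y, cov,
            k=config.cv_k, n_perm=config.n_perm, seed=seeds["prediction"],
            C=config.svr_C, epsilon=config.svr_epsilon,
        )
        prediction = cv_predict(
            features.to_numpy(dtype=float), y, cov,
            k=config.cv_k, C=config.svr_C, epsilon=config.svr_epsilon,
            seed=seeds["prediction"],
        )

        stage = "mediation"
        mediator = (
            config.cohort.mediator_measure
            if config.data_dir is None
            else "within:VAN"
        )
        mediation = run_cohort_models(
            features, behavior, bias_scores,
            connectivity_mediator=mediator,
            covariates=config.mediation_covariates,
            n_boot=config.n_boot, ci_level=config.ci_level,
            method=config.mediation_method, seed=seeds["mediation"],
        )
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    return {
        "partition": partition,
        "features": features,
        "behavior": behavior,
        "bias_scores": bias_scores,
        "screen": screen_results,
        "prediction": prediction,
        "prediction_p": p_perm,
        "mediation": mediation,
        "seeds": seeds,
    }


def _render_report(config: AnalysisConfig, bundle: dict[str, Any]) -> str:
    lines = ["# Analysis report", ""]
    scr = bundle["screen"]
    hits = scr[scr["significant"]]
    lines.append(
        f"Screen: {len(scr)} connectivity measures vs {config.screen_target} "
        f"(partial r controlling for {', '.join(config.screen_covariates)}; "
        f"BH-FDR q = {config.q})"
    )
    if len(hits):
        for _, row in hits.iterrows():
            lines.append(
                f"  {row['measure']}: r = {row['r']:.3f}, p = {row['p']:.2e}, "
                f"p_adj = {row['p_adj']:.2e}"
            )
    else:
        lines.append("  no measure survived FDR correction")
    lines.append("")
    pred = bundle["prediction"]
    lines.append(
        f"Prediction: balanced {pred.k}-fold linear SVR, "
        f"r(predicted, observed) = {pred.r_pred_obs:.3f}, "
        f"permutation p = {bundle['prediction_p']:.4f} ({config.n_perm} permutations)"
    )
    lines.append("")
    for name, res in bundle["mediation"].items():
        mediator_label = {
            "van_connectivity": "VAN within-network connectivity",
            "sad_bias": "attention bias to sad face",
        }.get(name, name)
        lines.append(f"Mediation model ({mediator_label}):")
        lines.append(render_path_diagram(res, m=mediator_label))
        lines.append("")
    return "\n".join(lines)


def run_full(config: AnalysisConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write every intermediate table.

    Writes the tidy connectivity profiles, behavioral table, screen results,
    out-of-fold predictions, mediation results, optional bias scores, a
    human-readable report, and a manifest JSON recording config, seeds and
    artifact names.  Partial outputs are retained if a later stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = analyze_cohort(config)

    artifacts: dict[str, str] = {}

    def _write(name: str, fn) -> None:
        fn(outdir / name)
        artifacts[name.split(".")[0]] = name

    features = bundle["features"]
    tidy = features.rename_axis("subject_id").reset_index().melt(
        id_vars="subject_id", var_name="measure", value_name="value"
    )
    tidy[["measure_type", "network_or_pair"]] = tidy["measure"].str.split(":", expand=True)
    _write(
        "profiles.csv",
        lambda p: tidy[["subject_id", "measure_type", "network_or_pair", "value"]].to_csv(p, index=False),
    )
    _write("behavior.csv", lambda p: bundle["behavior"].to_csv(p, index=False))
    _write("screen.csv", lambda p: bundle["screen"].to_csv(p, index=False))
    pred = bundle["prediction"]
    pred_frame = pd.DataFrame(
        {
            "subject_id": features.index,
            "fold": pred.fold_of,
            "observed": pred.observed,
            "predicted": pred.predictions,
        }
    )
    _write("predictions.csv", lambda p: pred_frame.to_csv(p, index=False))
    summary = {
        **pred.to_dict(),
        "permutation_p": bundle["prediction_p"],
        "n_perm": config.n_perm,
    }
    _write("prediction.json", lambda p: p.write_text(json.dumps(summary, indent=2)))
    _write(
        "mediation.json",
        lambda p: p.write_text(
            json.dumps({k: v.to_dict() for k, v in bundle["mediation"].items()}, indent=2)
        ),
    )
    if bundle["bias_scores"] is not None:
        _write("bias_scores.csv", lambda p: bundle["bias_scores"].to_csv(p))
    _write("report.txt", lambda p: p.write_text(_render_report(config, bundle)))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": bundle["seeds"],
        "n_subjects": int(len(features)),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %d artifacts under %s", len(artifacts), outdir)
    return manifest


def replicate(
    config_a: AnalysisConfig, config_b: AnalysisConfig
) -> dict[str, pd.DataFrame]:
    """Run the screen on two cohorts and report which associations replicate.

    An association replicates when it is significant in both cohorts with
    the same sign.  Raises if the cohorts share no measures.
    """
    bundles = [analyze_cohort(c) for c in (config_a, config_b)]
    screen_a, screen_b = (b["screen"].set_index("measure") for b in bundles)
    common = screen_a.index.intersection(screen_b.index)
    if common.empty:
        raise ValueError("cohorts have disjoint measure sets; nothing to compare")
    verdicts = pd.DataFrame(
        {
            "r_cohort1": screen_a.loc[common, "r"],
            "r_cohort2": screen_b.loc[common, "r"],
            "significant_cohort1": screen_a.loc[common, "significant"],
            "significant_cohort2": screen_b.loc[common, "significant"],
        }
    )
    verdicts["same_sign"] = np.sign(verdicts["r_cohort1"]) == np.sign(verdicts["r_cohort2"])
    verdicts["replicates"] = (
        verdicts["significant_cohort1"]
        & verdicts["significant_cohort2"]
        & verdicts["same_sign"]
    )
    return {
        "screen_cohort1": bundles[0]["screen"],
        "screen_cohort2": bundles[1]["screen"],
        "verdicts": verdicts.reset_index(),
    }
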