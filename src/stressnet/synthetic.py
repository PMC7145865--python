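"""Synthetic cohort generator for the full analysis chain.

Generates every input the pipeline consumes: block-structured Gaussian ROI
time series with controllable within/between-network correlation targets, a
behavioral table with a planted X -> M -> Y mediation structure (X a
standardized early-life-stress score, M a connectivity or attention-bias
mediator, Y depression), and trial-level dot-probe reaction times with
per-emotion bias shifts.

Time-series model
-----------------
Each subject's covariance is compound-symmetric within each network block:
unit variances, a common correlation ``w_a`` inside network ``a`` and a
common correlation ``b_ab`` between networks ``a`` and ``b``.  Writing
``F`` for the small ``K x K`` matrix with ``F_aa = w_a`` and ``F_ab = b_ab``,
the node covariance is

    C = blockdiag((1 - w_a) I_a) + E F E^T

with ``E`` the node-to-network indicator matrix, so ``C`` is positive
definite whenever every ``w_a < 1`` and ``F`` is positive semidefinite.
Sampling uses this factor form directly (a node-level noise plus ``K``
shared network factors), so no large Cholesky factorization is needed.

Per-subject heterogeneity: each subject's targets are drawn around the spec
targets with a perturbation SD and truncated to a valid range; the latent
deviation of selected measures is tilted by the subject's standardized
stress score, which plants the X -> M path that downstream stages estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import NetworkPartition

#: Node counts of the ten canonical resting-state systems (227 nodes total),
#: the community sizes of the 264-ROI parcellation the field commonly uses.
DEFAULT_PARTITION_SIZES: tuple[tuple[str, int], ...] = (
    ("DMN", 58),
    ("SN", 18),
    ("FPN", 25),
    ("CON", 14),
    ("SMN", 35),
    ("VN", 31),
    ("VAN", 9),
    ("DAN", 11),
    ("AN", 13),
    ("SUB", 13),
)

#: Cohort demographics used for cosmetic realism of the behavioral table.
MALE_PROPORTION = 157 / 528
AGE_MEAN, AGE_SD, AGE_RANGE = 19.42, 1.40, (16.0, 26.0)
ELS_MEAN, ELS_SD = 37.35, 8.34
DEPRESSION_MEAN, DEPRESSION_SD = 7.05, 6.45
STRESS_MEAN, STRESS_SD = 46.70, 20.88

_PD_TOL = 1e-10
# truncation range for per-subject targets; keeps the implied covariance
# comfortably inside the positive-definite region
_WITHIN_RANGE = (0.02, 0.85)
_BETWEEN_RANGE = (-0.20, 0.45)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic resting-state cohort.

    Parameters
    ----------
    n_subjects, t_points : int
        Cohort size and time points per subject (default 230, an 8-minute
        scan at TR = 2 s minus discarded initial volumes).
    partition_sizes : sequence of (network name, node count)
        Defaults to the ten-system, 227-node split.
    within_targets : float or mapping
        Target within-network correlation per network, in ``[0, 1)``.
    between_targets : float or mapping
        Target between-network correlation per unordered pair, in ``(-1, 1)``.
    mediation_coeffs : (a, b, c_prime)
        Standardized planted paths: ``a`` couples the focal mediator target
        to the stress score X, ``b`` and ``c_prime`` generate
        ``Y = c_prime * X + b * M + noise``.
    mediator_measure : str
        Connectivity measure acting as M, e.g. ``"within:VAN"``.
    els_loadings : mapping measure -> loading or None
        Correlation between each measure's latent per-subject target and X.
        ``None`` plants the focal mediator at loading ``a`` plus a halo of
        secondary measures (DAN/SN/SMN within; VAN-DAN/VAN-SMN/VAN-VN
        between) at ``0.6 * a``, mimicking a correlated effect pattern.
    target_sd : float
        SD of per-subject target perturbations (inter-subject variance of
        true connectivity).
    noise_sd : float
        SD of the residual of Y given X and M.
    stress_loading : float
        Correlation of the current-stress nuisance score with X.
    """

    n_subjects: int = 300
    t_points: int = 230
    partition_sizes: tuple[tuple[str, int], ...] = DEFAULT_PARTITION_SIZES
    within_targets: float | Mapping[str, float] = 0.30
    between_targets: float | Mapping[tuple[str, str], float] = 0.10
    mediation_coeffs: tuple[float, float, float] = (0.35, 0.30, 0.20)
    mediator_measure: str = "within:VAN"
    els_loadings: Mapping[str, float] | None = None
    target_sd: float = 0.05
    noise_sd: float = 0.90
    stress_loading: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.t_points <= 0:
            raise ValueError("n_subjects and t_points must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.target_sd < 0:
            raise ValueError("target_sd must be nonnegative")
        names = [n for n, _ in self.partition_sizes]
        if len(set(names)) != len(names):
            raise ValueError("network names must be unique")
        if any(c <= 0 for _, c in self.partition_sizes):
            raise ValueError("node counts must be positive")
        for name, w in self.within_map().items():
            if not 0.0 <= w < 1.0:
                raise ValueError(f"within target for {name} must be in [0, 1), got {w}")
        for pair, b in self.between_map().items():
            if not -1.0 < b < 1.0:
                raise ValueError(f"between target for {pair} must be in (-1, 1), got {b}")
        a, b, c_prime = self.mediation_coeffs
        if not -1.0 < a < 1.0:
            raise ValueError("path a must lie in (-1, 1)")
        r2 = c_prime**2 + b**2 + 2 * a * b * c_prime
        if abs(r2) >= 1.0:
            raise ValueError(
                f"implied R^2 of Y on (X, M) is {r2:.3f}; paths (b, c_prime) too large"
            )
        # base covariance must be positive definite: K x K network-target
        # matrix PSD and every within target < 1
        F = self.base_target_matrix()
        eigmin = float(np.linalg.eigvalsh(F).min())
        if eigmin < -_PD_TOL:
            order = np.argsort(np.linalg.eigh(F)[1][:, 0] ** 2)[::-1]
            blocks = [names[i] for i in order[:3]]
            raise ValueError(
                f"implied block covariance is not positive definite "
                f"(network-target matrix eigenvalue {eigmin:.2e}); "
                f"most involved blocks: {blocks}"
            )

    # -- derived structure -------------------------------------------------

    @property
    def network_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.partition_sizes)

    @property
    def n_nodes(self) -> int:
        return sum(c for _, c in self.partition_sizes)

    def partition(self) -> NetworkPartition:
        return NetworkPartition.from_sizes(self.partition_sizes)

    def within_map(self) -> dict[str, float]:
        if isinstance(self.within_targets, Mapping):
            return {n: float(self.within_targets[n]) for n in self.network_names}
        return {n: float(self.within_targets) for n in self.network_names}

    def between_map(self) -> dict[tuple[str, str], float]:
        names = self.network_names
        pairs = [_pair_key(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        if isinstance(self.between_targets, Mapping):
            return {p: float(self.between_targets[p]) for p in pairs}
        return {p: float(self.between_targets) for p in pairs}

    def base_target_matrix(self) -> np.ndarray:
        """K x K matrix with within targets on the diagonal, between off it."""
        names = self.network_names
        K = len(names)
        F = np.empty((K, K))
        wmap, bmap = self.within_map(), self.between_map()
        for i, a in enumerate(names):
            F[i, i] = wmap[a]
            for j in range(i + 1, K):
                F[i, j] = F[j, i] = bmap[_pair_key(a, names[j])]
        return F

    def loading_map(self) -> dict[str, float]:
        """Measure -> correlation of its latent target with the stress score X."""
        if self.els_loadings is not None:
            return dict(self.els_loadings)
        a = self.mediation_coeffs[0]
        loadings = {self.mediator_measure: a}
        halo = 0.6 * a
        for net in ("DAN", "SN", "SMN"):
            if net in self.network_names:
                loadings.setdefault(f"within:{net}", halo)
        for other in ("DAN", "SMN", "VN"):
            if "VAN" in self.network_names and other in self.network_names:
                p = _pair_key("VAN", other)
                loadings.setdefault(f"between:{p[0]}-{p[1]}", halo)
        return loadings

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "t_points": self.t_points,
            "partition_sizes": [list(p) for p in self.partition_sizes],
            "within_targets": self.within_targets
            if not isinstance(self.within_targets, Mapping)
            else dict(self.within_targets),
            "between_targets": self.between_targets
            if not isinstance(self.between_targets, Mapping)
            else {f"{a}-{b}": v for (a, b), v in self.between_targets.items()},
            "mediation_coeffs": list(self.mediation_coeffs),
            "mediator_measure": self.mediator_measure,
            "target_sd": self.target_sd,
            "noise_sd": self.noise_sd,
            "stress_loading": self.stress_loading,
            "seed": self.seed,
        }


# -- deterministic random streams -----------------------------------------
# Streams are keyed on (seed, stage tag[, subject]) so each stage can be
# regenerated in isolation and simulate_timeseries / simulate_behavior agree
# on the same latent stress scores.

_STAGE_LATENT, _STAGE_TS, _STAGE_BEHAVIOR, _STAGE_DOTPROBE = 0, 1, 2, 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def latent_stress_scores(spec: CohortSpec) -> np.ndarray:
    """Standardized per-subject stress scores X driving every planted effect."""
    return _rng(spec.seed, _STAGE_LATENT).standard_normal(spec.n_subjects)


def _subject_target_matrix(spec: CohortSpec, subject_index: int) -> np.ndarray:
    """Per-subject K x K target matrix: spec targets + tilt + perturbation.

    The latent deviation of measure targets from spec values is
    ``target_sd * (loading * X_s + sqrt(1 - loading^2) * eta)`` so the
    target correlates with X at ``loading``.  Truncation to the valid range
    and, if needed, deterministic shrinkage toward the (validated) base
    matrix keep the implied covariance positive definite.
    """
    x = latent_stress_scores(spec)[subject_index]
    rng = _rng(spec.seed, _STAGE_LATENT, 1, subject_index)
    names = spec.network_names
    K = len(names)
    loadings = spec.loading_map()
    F_base = spec.base_target_matrix()
    F = F_base.copy()
    for i, a in enumerate(names):
        lam = loadings.get(f"within:{a}", 0.0)
        dev = lam * x + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal()
        F[i, i] = np.clip(F[i, i] + spec.target_sd * dev, *_WITHIN_RANGE)
    for i in range(K):
        for j in range(i + 1, K):
            p = _pair_key(names[i], names[j])
            lam = loadings.get(f"between:{p[0]}-{p[1]}", 0.0)
            dev = lam * x + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal()
            F[i, j] = F[j, i] = np.clip(F[i, j] + spec.target_sd * dev, *_BETWEEN_RANGE)
    # shrink the perturbation toward the base matrix until PSD (base is PD)
    gamma = 1.0
    for _ in range(60):
        Fg = F_base + gamma * (F - F_base)
        if np.linalg.eigvalsh(Fg).min() >= _PD_TOL:
            return Fg
        gamma *= 0.5
    return F_base


def simulate_timeseries(spec: CohortSpec, subject_index: int):
    """Simulate one subject's T x N time-series matrix.

    Draws from a zero-mean multivariate normal whose correlation has the
    subject's within-block value on each block and the between-block value
    across blocks.  Deterministic given ``(spec.seed, subject_index)``.
    """
    from .connectivity import TimeSeriesMatrix

    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    F = _subject_target_matrix(spec, subject_index)
    names = spec.network_names
    w = np.diag(F)
    # factor form: node noise sqrt(1 - w_a) + shared network factors L z
    eigval, eigvec = np.linalg.eigh(F)
    eigval = np.clip(eigval, 0.0, None)
    L = eigvec * np.sqrt(eigval)
    net_of_node = np.repeat(np.arange(len(names)), [c for _, c in spec.partition_sizes])
    rng = _rng(spec.seed, _STAGE_TS, subject_index)
    T, N = spec.t_points, spec.n_nodes
    noise = rng.standard_normal((T, N)) * np.sqrt(1.0 - w)[net_of_node]
    factors = rng.standard_normal((T, len(names))) @ L.T
    values = noise + factors[:, net_of_node]
    partition = spec.partition()
    return TimeSeriesMatrix(
        values=values,
        node_ids=partition.node_ids,
        subject_id=f"sub{subject_index:04d}",
    )


def simulate_cohort_timeseries(spec: CohortSpec):
    """All subjects' time-series matrices, in subject order."""
    return [simulate_timeseries(spec, i) for i in range(spec.n_subjects)]


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def simulate_behavior(
    spec: CohortSpec, m_values: Sequence[float] | np.ndarray | None = None
) -> pd.DataFrame:
    """Generate the behavioral table with the planted mediation structure.

    ``m_values`` is the realized mediator (e.g. each subject's VAN
    within-network connectivity computed from the simulated time series); it
    is standardized across subjects and the outcome is generated as
    ``Y = c_prime * X + b * M + Normal(0, noise_sd)``.  When ``m_values`` is
    omitted, a behavioral mediator is drawn directly with
    ``M = a * X + sqrt(1 - a^2) * eps``.  The realized X -> M correlation is
    recorded in ``frame.attrs["realized_a"]``.

    Scores are mapped onto the instruments' mean/SD scales (ELS on the
    childhood-trauma questionnaire scale, depression on the BDI scale,
    current stress on the life-events checklist scale) without truncation at
    nominal instrument bounds, so all planted correlations survive exactly.
    """
    a, b, c_prime = spec.mediation_coeffs
    x = latent_stress_scores(spec)
    rng = _rng(spec.seed, _STAGE_BEHAVIOR)
    n = spec.n_subjects
    if m_values is None:
        m = a * x + np.sqrt(max(0.0, 1 - a**2)) * rng.standard_normal(n)
    else:
        m = np.asarray(m_values, dtype=float)
        if m.shape != (n,):
            raise ValueError(f"m_values must have length {n}, got {m.shape}")
        rng.standard_normal(n)  # keep the stream aligned across both branches
    m_sd = m.std()
    if m_sd == 0:
        raise ValueError("mediator has zero variance")
    m_z = (m - m.mean()) / m_sd
    y = c_prime * x + b * m_z + spec.noise_sd * rng.standard_normal(n)

    lam = spec.stress_loading
    stress_z = lam * x + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal(n)
    sex = (rng.random(n) < MALE_PROPORTION).astype(int)
    age = _truncated_normal(rng, AGE_MEAN, AGE_SD, *AGE_RANGE, size=n)

    frame = pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(n)],
            "els": ELS_MEAN + ELS_SD * x,
            "depression": DEPRESSION_MEAN + DEPRESSION_SD * y,
            "current_stress": STRESS_MEAN + STRESS_SD * stress_z,
            "age": age,
            "sex": sex,
            "mediator_z": m_z,  # the standardized mediator the outcome was generated from
        }
    )
    frame.attrs["realized_a"] = float(np.corrcoef(x, m_z)[0, 1])
    frame.attrs["planted_paths"] = {"a": a, "b": b, "c_prime": c_prime}
    return frame


# -- dot-probe trials ------------------------------------------------------

#: Per-block trial counts of the four emotion-pair conditions
#: (neutral-happy, neutral-sad, neutral-anger, neutral-fear).
DEFAULT_TRIALS_PER_CONDITION = {"NH": 40, "NS": 37, "NA": 37, "NF": 37}


@dataclass(frozen=True)
class DotProbeSpec:
    """Parameters of a synthetic dot-probe session.

    ``bias_shift_ms`` maps each emotion condition to the
    incongruent-minus-congruent RT shift it plants (positive shift means
    probes opposite the emotional face are answered more slowly, i.e.
    attention is captured by the emotional face).
    """

    n_subjects: int = 100
    trials_per_condition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS_PER_CONDITION)
    )
    n_blocks: int = 2
    base_rt_ms: float = 500.0
    bias_shift_ms: Mapping[str, float] = field(default_factory=dict)
    rt_noise_sd_ms: float = 60.0
    error_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_blocks <= 0:
            raise ValueError("n_subjects and n_blocks must be positive")
        if self.base_rt_ms <= 0:
            raise ValueError("base_rt_ms must be positive")
        if self.rt_noise_sd_ms < 0:
            raise ValueError("rt_noise_sd_ms must be nonnegative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if any(c <= 0 for c in self.trials_per_condition.values()):
            raise ValueError("trial counts must be positive")
        unknown = set(self.bias_shift_ms) - set(self.trials_per_condition)
        if unknown:
            raise ValueError(f"bias shifts for unknown conditions: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "trials_per_condition": dict(self.trials_per_condition),
            "n_blocks": self.n_blocks,
            "base_rt_ms": self.base_rt_ms,
            "bias_shift_ms": dict(self.bias_shift_ms),
            "rt_noise_sd_ms": self.rt_noise_sd_ms,
            "error_rate": self.error_rate,
            "seed": self.seed,
        }


def simulate_dotprobe(spec: DotProbeSpec) -> pd.DataFrame:
    """Simulate trial-level dot-probe data for a cohort.

    Each trial draws the emotional-face side and probe side uniformly; on
    incongruent trials (probe opposite the emotional face) the condition's
    bias shift is added to the base RT.  Negative RTs are resampled.
    Deterministic given ``spec.seed``.
    """
    rng = _rng(spec.seed, _STAGE_DOTPROBE)
    rows: list[tuple] = []
    sides = np.array(["L", "R"])
    for s in range(spec.n_subjects):
        for block in range(spec.n_blocks):
            for cond, count in spec.trials_per_condition.items():
                shift = float(spec.bias_shift_ms.get(cond, 0.0))
                face = sides[rng.integers(0, 2, count)]
                probe = sides[rng.integers(0, 2, count)]
                incongruent = face != probe
                rt = (
                    spec.base_rt_ms
                    + shift * incongruent
                    + spec.rt_noise_sd_ms * rng.standard_normal(count)
                )
                for _ in range(100):
                    neg = rt <= 0
                    if not neg.any():
                        break
                    rt[neg] = (
                        spec.base_rt_ms
                        + shift * incongruent[neg]
                        + spec.rt_noise_sd_ms * rng.standard_normal(int(neg.sum()))
                    )
                correct = rng.random(count) >= spec.error_rate
                for t in range(count):
                    rows.append(
                        (
                            f"sub{s:04d}",
                            block,
                            cond,
                            face[t],
                            probe[t],
                            float(rt[t]),
                            bool(correct[t]),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "block", "condition", "face_side", "probe_side", "rt_ms", "correct"],
    )


# -- on-disk layout --------------------------------------------------------


def write_cohort(
    spec: CohortSpec,
    outdir: str | Path,
    dotprobe_spec: DotProbeSpec | None = None,
) -> dict:
    """Write a full synthetic dataset and return its manifest.

    Layout: per-subject time-series TSVs under ``timeseries/``, the node
    partition as two-column CSV, the behavioral table as CSV (mediator taken
    from the spec's focal connectivity measure), optional dot-probe trials
    as CSV, and a ``manifest.json`` recording spec and seed.
    """
    from .connectivity import connectivity_profile

    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    partition = spec.partition()
    partition.to_csv(outdir / "partition.csv")

    m_values = []
    mtype, _, mname = spec.mediator_measure.partition(":")
    for i in range(spec.n_subjects):
        ts = simulate_timeseries(spec, i)
        ts.to_tsv(outdir / "timeseries" / f"{ts.subject_id}.tsv")
        prof = connectivity_profile(ts, partition)
        if mtype == "within":
            m_values.append(prof.within[mname])
        else:
            a, b = mname.split("-")
            m_values.append(prof.between[_pair_key(a, b)])
    behavior = simulate_behavior(spec, m_values=np.asarray(m_values))
    behavior.to_csv(outdir / "behavior.csv", index=False)

    manifest = {
        "cohort_spec": spec.to_dict(),
        "realized_a": behavior.attrs["realized_a"],
        "files": {
            "partition": "partition.csv",
            "behavior": "behavior.csv",
            "timeseries_dir": "timeseries",
        },
    }
    if dotprobe_spec is not None:
        trials = simulate_dotprobe(dotprobe_spec)
        trials.to_csv(outdir / "dotprobe_trials.csv", index=False)
        manifest["dotprobe_spec"] = dotprobe_spec.to_dict()
        manifest["files"]["dotprobe_trials"] = "dotprobe_trials.csv"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
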