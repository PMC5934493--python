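"""End-to-end orchestration: simulate/load, calibrate, estimate, evaluate.

The five pipeline stages mirror a complete laboratory study:

1. acquire motion (synthetic generator or TRC files): static trial
   without the exoskeleton, static trial wearing it, treadmill walk
   wearing it;
2. scale the generic human model from the static marker pairs;
3. adjust the exoskeleton links and assemble the coupled model at the
   static posture (this also calibrates the fixation constraint
   anchors);
4. compute ground-truth human and exoskeleton joint angles by marker
   IK on the walking trial (base pose frozen at its static value — the
   treadmill keeps the pelvis quasi-stationary, and joint angles are
   invariant to common rigid motion);
5. estimate the human angles from the exoskeleton angles with the
   rigid baseline and the constraint-closure estimator, and evaluate
   both against the ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import __version__
from .body_models import (
    adjust_exo_links,
    apply_scaling,
    assemble_coupled,
    build_exo_model,
    build_generic_human,
    compute_scale_factors,
)
from .coupling_constraints import make_default_constraint_set
from .errors import ExokinError, ValidationError
from .evaluation import EvalReport, build_report
from .fileio import read_trc, write_angles_csv
from .ik_engine import (
    IKSettings,
    add_virtual_midpoint_marker,
    eikpe_estimate,
    exo_ankle_from_foot_markers,
    marker_ik,
    rigid_estimate,
)
from .synthetic_gait import (
    GaitProfileParams,
    SoftTissueParams,
    SyntheticSubject,
    generate_subject,
    soft_tissue_preset,
)
from .trajectories import JointTrajectory, MarkerTrajectory, SAGITTAL_CHANNELS

log = logging.getLogger("exokin")


@dataclass
class PipelineConfig:
    """Configuration of one full study run.

    ``preset`` selects the soft-tissue surrogate (``none`` or
    ``paper-like``); per-subject parameters are jittered around the
    preset so the cohort is heterogeneous, like a real subject pool.
    """

    n_subjects: int = 7
    seed: int = 0
    preset: str = "paper-like"
    duration: float = 10.0
    rate: float = 100.0
    vary_subjects: bool = True
    out_dir: Optional[str] = None
    settings: IKSettings = field(default_factory=IKSettings)
    #: subject overrides: generic segment lengths (m) and manual scale factors
    segment_lengths: Optional[Dict[str, float]] = None
    manual_scale_overrides: Dict[str, float] = field(default_factory=dict)
    #: constraint anchor/weight overrides (see make_default_constraint_set)
    constraint_config: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Top-level keys mirror :class:`PipelineConfig` fields; a ``solver``
    mapping is forwarded to :class:`IKSettings`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"pipeline config {path} must be a mapping")
    solver = raw.pop("solver", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
    config = PipelineConfig(**raw)
    if solver:
        config.settings = IKSettings(**solver)
    return config


def subject_soft_params(preset: str, rng: np.random.Generator, vary: bool = True) -> SoftTissueParams:
    """Draw one subject's soft-tissue parameters around a named preset."""
    base = soft_tissue_preset(preset)
    seed = int(rng.integers(0, 2**31 - 1))
    if preset == "none" or not vary:
        base.seed = seed
        return base
    offsets = {k: v * rng.uniform(0.7, 1.3) for k, v in base.offsets.items()}
    gains = {k: min(v + rng.uniform(-0.02, 0.02), 0.999) for k, v in base.gains.items()}
    lags = {k: v * rng.uniform(0.8, 1.25) for k, v in base.lags.items()}
    return SoftTissueParams(
        offsets=offsets,
        gains=gains,
        lags=lags,
        attachment_jitter=base.attachment_jitter,
        marker_noise=base.marker_noise,
        seed=seed,
    )


@dataclass
class SubjectResult:
    """All per-subject pipeline outputs."""

    gt: JointTrajectory
    v_R: JointTrajectory
    rigid: JointTrajectory
    eikpe: JointTrajectory
    coupled: object
    constraint_set: object
    gt_residual_rms: np.ndarray
    eikpe_residual_rms: np.ndarray


def process_subject(
    static_no_exo: MarkerTrajectory,
    static_with_exo: MarkerTrajectory,
    walk_markers: MarkerTrajectory,
    settings: Optional[IKSettings] = None,
    segment_lengths: Optional[Dict[str, float]] = None,
    manual_scale_overrides: Optional[Dict[str, float]] = None,
    constraint_config: Optional[dict] = None,
) -> SubjectResult:
    """Stages 2-5 for one subject, from the three captures."""
    settings = settings or IKSettings()
    generic = build_generic_human(lengths=segment_lengths)
    scale = compute_scale_factors(static_no_exo, generic)
    if manual_scale_overrides:
        scale.manual_overrides.update(manual_scale_overrides)
    human = apply_scaling(generic, scale)
    exo = adjust_exo_links(build_exo_model(), static_with_exo)
    coupled = assemble_coupled(human, exo, static_with_exo, settings)
    cs = make_default_constraint_set(coupled, constraint_config)

    walk = add_virtual_midpoint_marker(walk_markers, "Mk0", "Mk1", "Mk14")
    frozen = {c: coupled.static_posture[c] for c in coupled.base_coords}
    # the base stays frozen at its static pose (treadmill walking); the
    # exoskeleton ankle is not marker-observable and is recovered below
    # through the strapped foot instead
    free = list(coupled.human_coords) + [coupled.exo_coords[0], coupled.exo_coords[1]]
    x0 = np.array([coupled.static_posture[c] for c in free])
    ik_settings = dataclasses.replace(
        settings, marker_weights={**settings.marker_weights, "Mk14": 0.0, "SoleHeel": 0.0}
    )
    gt_result = marker_ik(
        coupled.model, walk, ik_settings, free_coords=free, frozen_values=frozen, x0=x0
    )
    traj = gt_result.trajectory
    gt = JointTrajectory(traj.time.copy(), {c: traj.channel(c).copy() for c in SAGITTAL_CHANNELS})
    v_R_partial = JointTrajectory(
        traj.time.copy(), {c: traj.channel(c).copy() for c in coupled.exo_coords[:2]}
    )
    ankle = exo_ankle_from_foot_markers(coupled, walk, v_R_partial, frozen)
    v_R = v_R_partial.with_channels({coupled.exo_coords[2]: ankle})
    rigid = rigid_estimate(v_R)
    eikpe_result = eikpe_estimate(coupled, cs, v_R, settings)
    return SubjectResult(
        gt=gt,
        v_R=v_R,
        rigid=rigid,
        eikpe=eikpe_result.trajectory,
        coupled=coupled,
        constraint_set=cs,
        gt_residual_rms=gt_result.per_frame_residual_rms,
        eikpe_residual_rms=eikpe_result.per_frame_residual_rms,
    )


def process_subject_files(
    static_no_exo_trc, static_with_exo_trc, walk_trc, settings: Optional[IKSettings] = None
) -> SubjectResult:
    """File-based entry: the three captures as TRC paths."""
    for path in (static_no_exo_trc, static_with_exo_trc, walk_trc):
        if not Path(path).exists():
            raise ExokinError(f"missing input capture: {path}")
    return process_subject(
        read_trc(static_no_exo_trc),
        read_trc(static_with_exo_trc),
        read_trc(walk_trc),
        settings,
    )


def run_pipeline(config: PipelineConfig) -> Tuple[EvalReport, Dict[str, SubjectResult]]:
    """Full synthetic study: generate the cohort, process, evaluate.

    The report compares the rigid baseline and the coupled estimator
    against the marker-IK ground truth per subject and joint.  All
    randomness flows from ``config.seed``; repeated runs are identical.
    """
    rng = np.random.default_rng(config.seed)
    gait = GaitProfileParams(duration=config.duration, rate=config.rate)
    results: Dict[str, SubjectResult] = {}
    gt: Dict[str, JointTrajectory] = {}
    rigid: Dict[str, JointTrajectory] = {}
    eikpe: Dict[str, JointTrajectory] = {}
    for i in range(config.n_subjects):
        key = f"S{i + 1}"
        soft = subject_soft_params(config.preset, rng, vary=config.vary_subjects)
        subject = generate_subject(
            seed=int(rng.integers(0, 2**31 - 1)), gait=gait, soft=soft
        )
        log.info("subject %s: scale=%s", key, subject.scale)
        res = process_subject(
            subject.static_no_exo,
            subject.static_with_exo,
            subject.walk_markers,
            config.settings,
            segment_lengths=config.segment_lengths,
            manual_scale_overrides=config.manual_scale_overrides,
            constraint_config=config.constraint_config,
        )
        results[key] = res
        gt[key] = res.gt
        rigid[key] = res.rigid
        eikpe[key] = res.eikpe
        log.info(
            "subject %s: GT residual %.2f mm, closure residual %.2f mm",
            key,
            1e3 * float(np.mean(res.gt_residual_rms)),
            1e3 * float(np.mean(res.eikpe_residual_rms)),
        )
    report = build_report(gt, rigid, eikpe)
    if config.out_dir is not None:
        _write_artifacts(config, report, results)
    return report, results


def _config_hash(config: PipelineConfig) -> str:
    payload = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_artifacts(config: PipelineConfig, report: EvalReport, results: Dict[str, SubjectResult]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "report.csv")
    report.to_json(out / "report.json")
    try:
        report.boxplot(out / "boxplot.png")
    except Exception as exc:  # plotting is best-effort
        log.warning("box plot rendering failed: %s", exc)
    for key, res in results.items():
        write_angles_csv(res.gt, out / f"{key}_gt.csv")
        write_angles_csv(res.rigid, out / f"{key}_rigid.csv")
        write_angles_csv(res.eikpe, out / f"{key}_eikpe.csv")
        with open(out / f"{key}_diagnostics.json", "w") as fh:
            json.dump(
                {
                    "gt_residual_rms_m_mean": float(np.mean(res.gt_residual_rms)),
                    "gt_residual_rms_m_max": float(np.max(res.gt_residual_rms)),
                    "closure_residual_rms_m_mean": float(np.mean(res.eikpe_residual_rms)),
                    "closure_residual_rms_m_max": float(np.max(res.eikpe_residual_rms)),
                    "static_residual_rms_m": float(res.coupled.static_residual_rms),
                    "static_ok": bool(res.coupled.static_ok),
                },
                fh,
                indent=2,
            )
    sidecar = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_subjects": config.n_subjects,
        "preset": config.preset,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
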