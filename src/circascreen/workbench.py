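"""End-to-end screening pipeline, fixture generation and run configuration.

`make_fixture` writes a synthetic IC table that emulates a screening cohort
(wild-type mice plus mutant lines, some with engineered onset shifts — a
positive-control design).  `run_pipeline` ties the four computational
stages together: QC -> phase prediction -> primary screen -> secondary
screen, writing plain TSV reports and a JSON summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ic_data, network, screen, simulate
from .errors import CircascreenError, PipelineError


@dataclass
class FixtureSpec:
    """Design of a synthetic screening cohort.

    `shifts` maps line id -> injected onset shift in hours (positive =
    delayed onset); lines absent from the map carry no shift.  Within a
    genotype, mice share the line's transition phase up to
    `within_line_sd` hours of biological scatter; amplitude and shape
    parameters vary mouse-to-mouse like the training generator.
    """

    n_wildtype: int = 20
    n_lines: int = 12
    mice_per_line: int = 8
    shifts: dict[str, float] = field(default_factory=dict)
    centre: str = "SIM"
    modality: str = "activity"
    seed: int = 0
    base_t2: float = 11.0        # wild-type hour-before-onset (ZT)
    base_delta_t: float = 2.0    # wild-type onset-to-peak interval (h)
    within_line_sd: float = 0.3  # mouse-to-mouse phase scatter (h)
    noise_scale: float = 0.05

    def __post_init__(self):
        if self.n_wildtype < 2 or self.n_lines < 2 or self.mice_per_line < 1:
            raise ValueError("fixture needs >= 2 WT mice, >= 2 lines, >= 1 mouse/line")
        unknown = set(self.shifts) - {self.line_id(i) for i in range(self.n_lines)}
        if unknown:
            raise ValueError(f"shifts reference unknown lines: {sorted(unknown)}")

    def line_id(self, i: int) -> str:
        return f"line{i:03d}"


def _cohort_mouse(template, rng, spec: FixtureSpec, shift: float):
    """One mouse: line phase + scatter, shape parameters freely sampled."""
    t2 = spec.base_t2 + shift + rng.normal(0.0, spec.within_line_sd)
    t2 = float(np.clip(t2, template.t1 + 0.5, ic_data.CANONICAL_ZT[-1] - 3.0))
    delta = max(1.0, spec.base_delta_t + rng.normal(0.0, 0.2))
    params = simulate.sample_sim_params(
        template, rng, noise_scale=spec.noise_scale, t2=t2, delta_t=delta
    )
    return simulate.synthesize_curve(params, rng)


def make_fixture(
    spec: FixtureSpec,
    out_path,
    template: simulate.TemplateParams | None = None,
) -> Path:
    """Write a synthetic IC TSV plus a `<name>.truth.tsv` label sidecar.

    Deterministic under `spec.seed`; returns the table path.
    """
    out_path = Path(out_path)
    if template is None:
        template = simulate.canonical_template(spec.modality, centre=spec.centre)
    rng = np.random.default_rng(spec.seed)

    rows = []
    truth = []

    def emit(subject: str, genotype: str, curve, shift: float):
        for z, v in zip(ic_data.CANONICAL_ZT, curve.values):
            rows.append((subject, genotype, spec.centre, spec.modality,
                         float(z), float(max(v, 0.0))))
        truth.append((subject, genotype, curve.onset_label, curve.peak_label, shift))

    for i in range(spec.n_wildtype):
        curve = _cohort_mouse(template, rng, spec, shift=0.0)
        emit(f"WT_m{i:03d}", "WT", curve, 0.0)
    for li in range(spec.n_lines):
        line = spec.line_id(li)
        shift = float(spec.shifts.get(line, 0.0))
        for mi in range(spec.mice_per_line):
            curve = _cohort_mouse(template, rng, spec, shift=shift)
            emit(f"{line}_m{mi:02d}", line, curve, shift)

    pd.DataFrame(rows, columns=list(ic_data.REQUIRED_COLUMNS)).to_csv(
        out_path, sep="\t", index=False
    )
    pd.DataFrame(
        truth,
        columns=["subject_id", "genotype", "true_onset", "true_peak", "injected_shift"],
    ).to_csv(out_path.with_suffix(".truth.tsv"), sep="\t", index=False)
    return out_path


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; loadable from YAML."""

    input_path: str
    output_dir: str
    model_path: str | None = None
    train: bool = False
    n_train: int = 20000
    epochs: int = 30
    modality: str = "activity"
    centre: str | None = None
    wildtype_label: str = "WT"
    time_format: str = "zt"
    seed: int = 0
    k_sd: float = 2.0
    d_min: float = 1.2
    p_max: float = 0.001
    concordance_min: float = 0.5
    noise_scale: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _prepare_profiles(profiles, thr, qc_rows):
    """Canonical grid + QC + normalization for each profile.

    Returns {subject_id: (profile, normalized_curve)} keyed per modality
    entry; profiles failing coverage are dropped (and counted).
    """
    kept = {}
    dropped = 0
    for prof in profiles:
        try:
            canon = ic_data.to_canonical_grid(prof)
            clean, report = ic_data.apply_qc(canon, thr)
            curve = ic_data.impute_and_normalize(clean)
        except (ic_data.InsufficientCoverageError, ic_data.DegenerateCurveError):
            dropped += 1
            continue
        for zt, rule, val in report.removals:
            qc_rows.append((prof.subject_id, prof.modality, zt, rule, val))
        kept[prof.subject_id] = (clean, curve)
    return kept, dropped


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute qc -> predict -> primary -> secondary and write all reports.

    Returns the JSON-serializable run summary.  Raises PipelineError with
    a stage tag on any stage failure.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thr = ic_data.QCThresholds()
    counts: dict[str, int] = {}

    # --- stage: read -------------------------------------------------------
    try:
        profiles = ic_data.read_ic_table(cfg.input_path, time_format=cfg.time_format)
    except CircascreenError as exc:
        raise PipelineError("read", str(exc)) from exc
    profiles = [p for p in profiles if p.modality == cfg.modality]
    if cfg.centre is not None:
        profiles = [p for p in profiles if p.centre == cfg.centre]
    if not profiles:
        raise PipelineError("read", "no profiles for the requested modality/centre")
    counts["subjects_in"] = len(profiles)

    # --- stage: qc ---------------------------------------------------------
    qc_rows: list[tuple] = []
    try:
        kept, dropped = _prepare_profiles(profiles, thr, qc_rows)
    except CircascreenError as exc:
        raise PipelineError("qc", str(exc)) from exc
    counts["subjects_qc_passed"] = len(kept)
    counts["subjects_qc_failed"] = dropped
    pd.DataFrame(
        qc_rows, columns=["subject_id", "modality", "zt_hour", "rule_id", "original_value"]
    ).to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    if not kept:
        raise PipelineError("qc", "no profile survived QC")

    # --- stage: model ------------------------------------------------------
    try:
        if cfg.model_path is not None and Path(cfg.model_path).exists():
            model = network.load_model(cfg.model_path)
        elif cfg.train:
            template = simulate.canonical_template(cfg.modality)
            curves = simulate.generate_training_set(
                template, cfg.n_train, seed=cfg.seed, noise_scale=cfg.noise_scale
            )
            X, y = simulate.curves_to_arrays(curves)
            tc = network.TrainingConfig(max_epochs=cfg.epochs, seed=cfg.seed)
            model, _ = network.train_model(X, y, tc)
            network.save_model(model, out_dir / "model.npz", tc,
                               seed=cfg.seed, n_train=cfg.n_train)
        else:
            raise PipelineError(
                "model", f"model file {cfg.model_path!r} not found and training disabled"
            )
    except PipelineError:
        raise
    except (CircascreenError, OSError) as exc:
        raise PipelineError("model", str(exc)) from exc

    # --- stage: predict ----------------------------------------------------
    try:
        subjects = sorted(kept)
        X = np.vstack([kept[s][1] for s in subjects])
        preds = model.predict(X.astype(np.float32))
    except (CircascreenError, ValueError) as exc:
        raise PipelineError("predict", str(exc)) from exc
    genotype_of = {p.subject_id: p.genotype for p in profiles}
    centre_of = {p.subject_id: p.centre for p in profiles}
    pred_df = pd.DataFrame({
        "subject_id": subjects,
        "genotype": [genotype_of[s] for s in subjects],
        "centre": [centre_of[s] for s in subjects],
        "modality": cfg.modality,
        "onset_zt": preds[:, 0],
        "peak_zt": preds[:, 1],
    })
    pred_df.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)

    # --- stage: screen -----------------------------------------------------
    try:
        results, hits = _screen_cohort(cfg, kept, pred_df, model)
    except CircascreenError as exc:
        raise PipelineError("screen", str(exc)) from exc
    report = screen.results_to_frame(results)
    report.to_csv(out_dir / "screen_report.tsv", sep="\t", index=False)
    counts["lines_screened"] = report["line_id"].nunique()
    counts["primary_outliers"] = int(
        report.groupby("line_id")["primary_outlier"].any().sum()
    )
    counts["secondary_hits"] = int(
        report.groupby("line_id")["secondary_hit"].any().sum()
    )

    summary = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "counts": counts,
        "secondary_hit_lines": sorted(
            {r.line_id for r in hits}
        ),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _screen_cohort(cfg: RunConfig, kept, pred_df: pd.DataFrame, model):
    """Build genotype groups (mean-curve prediction per line) and screen."""
    wt_mask = pred_df["genotype"] == cfg.wildtype_label
    wt = pred_df[wt_mask]
    if len(wt) < 2:
        raise CircascreenError(
            f"need >= 2 wild-type mice labelled {cfg.wildtype_label!r}"
        )
    wt_values = {
        "onset": wt["onset_zt"].to_numpy(),
        "peak": wt["peak_zt"].to_numpy(),
    }

    groups = []
    for line, grp in pred_df[~wt_mask].groupby("genotype", sort=True):
        cleaned = [kept[s][0] for s in grp["subject_id"]]
        mean_curve = simulate.average_profile([c.values for c in cleaned])
        mean_profile = ic_data.TimeSeriesProfile(
            subject_id=f"{line}:mean", genotype=str(line),
            centre=str(grp["centre"].iloc[0]), modality=cfg.modality,
            zt=ic_data.CANONICAL_ZT.copy(),
            values=np.maximum(mean_curve, 0.0),
        )
        norm = ic_data.impute_and_normalize(mean_profile)
        mean_pred = model.predict(norm[None, :].astype(np.float32))[0]
        groups.append(
            screen.GenotypeGroup(
                line_id=str(line), centre=str(grp["centre"].iloc[0]),
                modality=cfg.modality,
                mouse_onsets=grp["onset_zt"].to_numpy(),
                mouse_peaks=grp["peak_zt"].to_numpy(),
                mean_onset=float(mean_pred[0]),
                mean_peak=float(mean_pred[1]),
            )
        )
    results = screen.primary_screen(groups, wt_values, k=cfg.k_sd)
    hits = screen.secondary_screen(
        results,
        screen.SecondaryThresholds(
            d_min=cfg.d_min, p_max=cfg.p_max, concordance_min=cfg.concordance_min
        ),
    )
    return results, hits
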