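"""End-to-end orchestration: simulate → select → learn → predict → assign →
segment → measure → efficacy, from a single seeded config.

Every stage consumes the previous stage's artifact, all randomness derives
from one seed, and rerunning a config reproduces byte-identical tabular
outputs.  The stage order mirrors the clinical workflow: a training cohort
builds the prognosis network; a validation cohort is split into a
model-guided (research) arm and a control arm by the predicted survival
posterior; per-arm phantoms are segmented and measured; response categories
and follow-up times with arm-specific effect sizes yield ORR/DCR, a
chi-square group comparison and Kaplan–Meier PFS curves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayesnet, efficacy, features, imaging, synthetic
from .synthetic import OUTCOME

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Single config driving every stage.

    Effect sizes are the per-arm response-category probabilities and the
    per-arm median PFS (months); setting both arms equal gives a
    zero-treatment-effect run.
    """

    seed: int = 0
    training_n: int = 2000
    validate_n: int = 40
    screen_alpha: float = 0.05
    filter_alpha: float = 0.05
    default_r: int = 4
    mmhc_alpha: float = 0.05
    mmhc_maxk: int = 3
    score: str = "bic"
    recist_dialect: str = "strict"
    response_probs: dict = field(default_factory=lambda: {
        "research": (0.0, 0.20, 0.70, 0.10),
        "control": (0.0, 0.20, 0.55, 0.25),
    })
    median_pfs_months: dict = field(default_factory=lambda: {
        "research": 7.1, "control": 4.8})
    censor_months: float = 18.0
    segment_phantoms: bool = True
    classifier_epochs: int = 30
    classifier_samples: int = 1200
    phantom_noise_sd: float = 5.0
    # per-arm (pre, post) lesion semi-axes in mm on a (32, 64, 64) 1 mm grid
    phantom_semi_axes: dict = field(default_factory=lambda: {
        "research": ((10.0, 12.0, 12.0), (7.0, 8.5, 8.5)),
        "control": ((10.0, 12.0, 12.0), (9.5, 11.5, 11.5)),
    })
    outdir: str | None = None

    def __post_init__(self) -> None:
        for arm, probs in self.response_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"response probabilities of {arm!r} invalid")
        if set(self.response_probs) != set(self.median_pfs_months):
            raise ValueError("arms of response_probs and median_pfs differ")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _md5(text: str) -> str:
    return hashlib.md5(text.encode()).hexdigest()[:12]


def _write(path: Path | None, name: str, text: str) -> str:
    if path is not None:
        (path / name).write_text(text)
    return _md5(text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run report.

    The report maps stage names to their key outputs; with ``config.outdir``
    set, all intermediate artifacts (cohort, screen/filter tables, learned
    network, predictions, measurements, efficacy summary, KM curves) are
    written there as delimited text, plus a ``report.json``.
    """
    out = Path(config.outdir) if config.outdir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(8)]
    report: dict = {"seed": config.seed, "stages": {}}
    stage = "init"

    def log_stage(name: str, seed: int | None, digest: str, t0: float) -> None:
        report["stages"][name] = {"seed": seed, "output_hash": digest,
                                  "runtime_s": round(time.perf_counter() - t0, 3)}
        logger.info("stage=%s seed=%s hash=%s", name, seed, digest)

    try:
        # ---------------- simulate training cohort ----------------------
        stage = "simulate"
        t0 = time.perf_counter()
        truth = synthetic.make_ground_truth({"include_nuisance": True})
        cohort = synthetic.sample_cohort(truth, config.training_n, seeds[0])
        digest = _write(out, "cohort.csv", cohort.to_csv(index=False))
        _write(out, "ground_truth_network.txt", truth.network.to_text())
        log_stage(stage, seeds[0], digest, t0)

        # ---------------- feature selection ------------------------------
        stage = "feature_selection"
        t0 = time.perf_counter()
        specs = dict(truth.interval_specs)
        kept, screen_table = features.chi_square_screen(
            cohort, OUTCOME, alpha=config.screen_alpha, specs=specs)
        catalog = features.default_catalog()
        multilevel = [v for v in catalog.discrete
                      if v in cohort.columns and cohort[v].nunique() > 2]
        filt = features.logistic_filter(
            cohort, kept, OUTCOME, alpha=config.filter_alpha,
            categorical=multilevel)
        selected = filt.retained or kept
        digest = _write(out, "logistic_filter.csv", filt.table.to_csv(index=False))
        _write(out, "chi_square_screen.csv", screen_table.to_csv(index=False))
        report["selected_variables"] = selected
        log_stage(stage, None, digest, t0)

        # ---------------- discretize + learn network ---------------------
        stage = "learn_network"
        t0 = time.perf_counter()
        model_table = cohort[selected + [OUTCOME]].copy()
        for v in selected:
            spec = specs.get(v)
            if spec is None and v in catalog.continuous:
                col = cohort[v]
                spec = features.DiscretizationSpec(col.min(), col.max(),
                                                   config.default_r)
            if spec is not None:
                model_table[v] = features.equidistant_discretize(cohort[v], spec)
        net, hc = bayesnet.mmhc(model_table, alpha=config.mmhc_alpha,
                                maxk=config.mmhc_maxk, score=config.score,
                                outcome=OUTCOME)
        net_text = net.to_text()
        digest = _write(out, "learned_network.txt", net_text)
        report["learned_edges"] = sorted(net.edges)
        report["network_score"] = hc.score
        log_stage(stage, None, digest, t0)

        # ---------------- predict prognosis, assign arms -----------------
        stage = "assign_arms"
        t0 = time.perf_counter()
        validate = synthetic.sample_cohort(truth, config.validate_n, seeds[1])
        evid_table = validate.copy()
        for v, spec in specs.items():
            if v in evid_table.columns:
                evid_table[v] = features.equidistant_discretize(validate[v], spec)
        evidence_vars = [v for v in net.nodes if v != OUTCOME]
        rows = []
        for _, row in evid_table.iterrows():
            evidence = {v: int(row[v]) for v in evidence_vars}
            pred = bayesnet.predict_outcome(net, evidence)
            p_death = float(pred["posterior"][1])
            rows.append({"p_death": p_death,
                         "arm": "research" if p_death < 0.5 else "control"})
        predictions = pd.concat([evid_table.reset_index(drop=True),
                                 pd.DataFrame(rows)], axis=1)
        arm_sizes = predictions["arm"].value_counts().to_dict()
        for arm in config.response_probs:
            arm_sizes.setdefault(arm, 0)
        digest = _write(out, "predictions.csv", predictions.to_csv(index=False))
        report["arm_sizes"] = arm_sizes
        acc = float((predictions["arm"].eq("research")
                     == predictions[OUTCOME].eq(0)).mean())
        report["prediction_accuracy"] = acc
        log_stage(stage, seeds[1], digest, t0)

        # ---------------- phantoms: segment + measure --------------------
        if config.segment_phantoms:
            stage = "segment_phantoms"
            t0 = time.perf_counter()
            train_spec = synthetic.PhantomSpec(noise_sd=config.phantom_noise_sd,
                                               seed=seeds[2])
            timg, tmask, _ = synthetic.make_phantom(train_spec)
            clf = _train_on_phantom(timg, tmask, config, seeds[3])
            meas_rows = []
            for arm, (pre_ax, post_ax) in sorted(config.phantom_semi_axes.items()):
                vols = {}
                for phase, axes in (("pre", pre_ax), ("post", post_ax)):
                    spec = synthetic.PhantomSpec(
                        semi_axes=axes, noise_sd=config.phantom_noise_sd,
                        seed=seeds[4])
                    img, mask, true_meas = synthetic.make_phantom(spec)
                    seg = imaging.segment(img, clf)
                    meas = imaging.measure_lesion(seg, spec.spacing)
                    dice = _dice(seg, mask)
                    vols[phase] = meas.volume_cm3
                    meas_rows.append({
                        "arm": arm, "phase": phase,
                        "diameter_mm": meas.diameter_mm,
                        "volume_cm3": meas.volume_cm3,
                        "true_diameter_mm": true_meas.diameter_mm,
                        "true_volume_cm3": true_meas.volume_cm3,
                        "dice": dice})
                meas_rows.append({
                    "arm": arm, "phase": "change",
                    "volume_cm3": imaging.volume_change(vols["pre"], vols["post"])})
            measurements = pd.DataFrame(meas_rows)
            digest = _write(out, "measurements.csv",
                            measurements.to_csv(index=False))
            report["measurements"] = meas_rows
            log_stage(stage, seeds[3], digest, t0)

        # ---------------- response classification + efficacy -------------
        stage = "efficacy"
        t0 = time.perf_counter()
        rng = np.random.default_rng(seeds[5])
        assess_rows = []
        for i, arm in enumerate(predictions["arm"]):
            cat = CATEGORIES_BY_INDEX[
                rng.choice(4, p=config.response_probs[arm])]
            baseline = rng.uniform(40.0, 120.0)
            a = _assessment_for(cat, baseline, i, rng)
            observed = efficacy.classify_response(
                a, recist_dialect=config.recist_dialect)
            assess_rows.append({"patient_id": a.patient_id, "arm": arm,
                                "baseline_mm": a.baseline_sum_mm,
                                "followup_mm": a.followup_sum_mm,
                                "new_lesion": a.new_lesion,
                                "category": observed})
        assessments = pd.DataFrame(assess_rows)
        summaries = {}
        for arm in sorted(config.response_probs):
            sub = assessments[assessments["arm"] == arm]
            if len(sub) == 0:
                logger.warning("arm %s is empty; no efficacy summary", arm)
                continue
            counts = {c: int((sub["category"] == c).sum()) for c in
                      ("CR", "PR", "SD", "PD")}
            summaries[arm] = efficacy.efficacy_rates(
                counts["CR"], counts["PR"], counts["SD"], counts["PD"],
                group=arm)
        table2 = pd.DataFrame([{
            "group": s.group, "n": s.n, "CR": s.cr, "PR": s.pr, "SD": s.sd,
            "PD": s.pd, "ORR_pct": s.orr_pct, "DCR_pct": s.dcr_pct}
            for s in summaries.values()])
        digest = _write(out, "efficacy_summary.csv", table2.to_csv(index=False))
        _write(out, "assessments.csv", assessments.to_csv(index=False))
        report["efficacy"] = {arm: asdict(s) for arm, s in summaries.items()}
        if len(summaries) == 2:
            arms = sorted(summaries)
            succ = tuple(summaries[a].cr + summaries[a].pr + summaries[a].sd
                         for a in arms)
            tot = tuple(summaries[a].n for a in arms)
            try:
                stat, p = efficacy.chi2_compare(succ, tot)
                report["dcr_chi2"] = {"statistic": stat, "p": p}
            except ValueError as exc:
                logger.warning("DCR comparison skipped: %s", exc)
        log_stage(stage, seeds[5], digest, t0)

        # ---------------- follow-up + Kaplan–Meier -----------------------
        stage = "pfs"
        t0 = time.perf_counter()
        active = {a for a, n in arm_sizes.items() if n > 0}
        fspec = synthetic.FollowupSpec(
            hazards={a: np.log(2) / config.median_pfs_months[a] for a in active},
            arm_sizes={a: arm_sizes[a] for a in active},
            censor_months=config.censor_months, seed=seeds[6])
        follow = synthetic.simulate_followup(fspec)
        km = {}
        km_text = []
        for arm in sorted(active):
            sub = follow[follow["arm"] == arm]
            est = efficacy.km_curve(sub["time_months"], sub["event"])
            km[arm] = est
            for t, s, r in zip(est.times, est.survival, est.at_risk):
                km_text.append(f"{arm},{t:.6g},{s:.6g},{int(r)}")
        digest = _write(out, "km_curves.csv",
                        "arm,time_months,survival,at_risk\n"
                        + "\n".join(km_text) + "\n")
        _write(out, "followup.csv", follow.to_csv(index=False))
        report["median_pfs"] = {
            arm: (est.median if est.median_defined else None)
            for arm, est in km.items()}
        log_stage(stage, seeds[6], digest, t0)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise PipelineStageError(stage, exc) from exc

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
    return report


CATEGORIES_BY_INDEX = ("CR", "PR", "SD", "PD")


def _assessment_for(category: str, baseline: float, idx: int,
                    rng: np.random.Generator) -> efficacy.LesionAssessment:
    """Draw a diameter pair consistent with a response category."""
    pid = f"P{idx:03d}"
    if category == "CR":
        return efficacy.LesionAssessment(pid, baseline, 0.0, undetectable=True)
    if category == "PR":
        ratio = rng.uniform(0.30, 0.695)
    elif category == "SD":
        ratio = rng.uniform(0.705, 1.195)
    else:  # PD
        ratio = rng.uniform(1.205, 1.6)
    return efficacy.LesionAssessment(pid, baseline, ratio * baseline)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


def _train_on_phantom(img: np.ndarray, mask: np.ndarray,
                      config: PipelineConfig, seed: int) -> imaging.PixelClassifier:
    """Balanced pixel sample from one phantom stack → trained classifier."""
    rng = np.random.default_rng(seed)
    feats = np.concatenate([imaging.pixel_features(sl).reshape(-1, 5)
                            for sl in img])
    labels = mask.ravel().astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    half = config.classifier_samples // 2
    idx = np.concatenate([rng.choice(pos, size=min(half, len(pos)), replace=False),
                          rng.choice(neg, size=min(half, len(neg)), replace=False)])
    return imaging.train_pixel_classifier(
        feats[idx], labels[idx], epochs=config.classifier_epochs, seed=seed)
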