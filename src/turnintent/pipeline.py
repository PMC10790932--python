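"""End-to-end orchestration: simulate -> preprocess -> features -> models ->
attribution -> effect maps, for single subjects and synthetic cohorts.

Subject seeds are derived from one master seed via a counter scheme
(``SeedSequence(master, spawn_key=(i,))``) so a cohort is reproducible as a
whole and any one subject can be re-run in isolation. A run manifest lists
every written output with a checksum; re-running with the same manifest
settings reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .attribution import ShapReport, global_importance, shap_dataset
from .effectmap import EffectMap, group_average, paired_effect
from .features import EpochSet, extract_epochs
from .intent_model import CVResult, NetConfig, run_cv
from .preprocess import PreprocessConfig, preprocess
from .simdata import (
    DecisionModel,
    EventLog,
    NoiseModel,
    ScenarioConfig,
    simulate_behavior,
    simulate_recording,
)

__all__ = [
    "SubjectResult",
    "CohortResult",
    "subject_seed",
    "build_configs",
    "run_subject",
    "run_cohort",
]

VARIANTS = ("context", "fnirs", "combined")


def subject_seed(master_seed: int, index: int) -> int:
    """Counter-based per-subject seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_configs(cfg: dict | None = None, seed: int | None = None):
    """Validate a nested config dict into the four stage configs.

    Recognized sections: ``scenario``, ``decision``, ``noise``,
    ``preprocess``, ``net``, plus top-level ``amplitude``, ``n_active``,
    ``atypical_gain``, ``shap_m``, ``shap_instances``. Invalid physical
    settings raise before any computation.
    """
    cfg = dict(cfg or {})
    scen_kw = dict(cfg.get("scenario", {}))
    if seed is not None:
        scen_kw["rng_seed"] = int(seed)
    scenario = ScenarioConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in scen_kw.items()})
    decision = DecisionModel(**cfg.get("decision", {}))
    noise = NoiseModel(**cfg.get("noise", {}))
    prep = PreprocessConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in cfg.get("preprocess", {}).items()})
    if prep.band[1] >= scenario.sampling_rate / 2:
        raise ValueError(
            f"band high {prep.band[1]} Hz is not below the Nyquist frequency "
            f"{scenario.sampling_rate / 2} Hz")
    net_kw = dict(cfg.get("net", {}))
    net_kw.setdefault("rng_seed", scenario.rng_seed)
    net = NetConfig(**net_kw)
    extras = {
        "amplitude": float(cfg.get("amplitude", 1.0e-3)),
        "n_active": int(cfg.get("n_active", 10)),
        "atypical_gain": float(cfg.get("atypical_gain", 2.0)),
        "shap_m": int(cfg.get("shap_m", 2000)),
        "shap_instances": int(cfg.get("shap_instances", 100)),
        "grouped_cv": bool(cfg.get("grouped_cv", True)),
    }
    return scenario, decision, noise, prep, net, extras


@dataclass
class SubjectResult:
    seed: int
    log: EventLog
    epochs: EpochSet
    cv: dict[str, CVResult]
    effect_map: EffectMap
    shap: ShapReport | None = None
    n_rejected_channels: int = 0
    active_channels: np.ndarray | None = None

    def summary_row(self) -> dict:
        row = {"seed": self.seed, "n_intersections": len(self.log),
               "n_rejected_channels": self.n_rejected_channels}
        for v, res in self.cv.items():
            row[f"{v}_median_acc"] = res.median_accuracy
            row[f"{v}_pooled_acc"] = res.pooled_accuracy
            row[f"{v}_mean_auc"] = res.mean_auc
            row[f"{v}_fn_rate"] = res.mean_fn_rate
        return row


def run_subject(config: dict | None = None, seed: int = 0,
                compute_shap: bool = False, out_dir: str | Path | None = None,
                variants: tuple[str, ...] = VARIANTS) -> SubjectResult:
    """Run the full pipeline for one synthetic subject."""
    scenario, decision, noise, prep, net, extras = build_configs(config, seed)
    rng = np.random.default_rng(scenario.rng_seed)
    log = simulate_behavior(scenario, decision, rng=rng)
    active = rng.choice(scenario.n_channels,
                        size=min(extras["n_active"], scenario.n_channels),
                        replace=False)
    rec = simulate_recording(scenario, log, active_channels=active,
                             amplitude=extras["amplitude"],
                             atypical_gain=extras["atypical_gain"],
                             noise=noise, rng=rng)
    conc = preprocess(rec, prep)
    epochs = extract_epochs(conc, log)
    cv = run_cv(epochs, net, variants=variants, grouped=extras["grouped_cv"],
                keep_models=compute_shap)

    shap_report = None
    if compute_shap and "combined" in cv:
        res = cv["combined"]
        clf = res.fold_models[0]
        fm_te = res.fold_test_matrices[0]
        k = min(extras["shap_instances"], fm_te.n_instances)
        idx = rng.choice(fm_te.n_instances, size=k, replace=False)
        bg_idx = rng.choice(fm_te.n_instances, size=min(100, fm_te.n_instances),
                            replace=False)
        shap_report = shap_dataset(clf, fm_te.X[idx], fm_te.X[bg_idx],
                                   fm_te.feature_names, M=extras["shap_m"],
                                   seed=scenario.rng_seed,
                                   labels=fm_te.y[idx])

    em = paired_effect(epochs)
    result = SubjectResult(seed=scenario.rng_seed, log=log, epochs=epochs,
                           cv=cv, effect_map=em, shap=shap_report,
                           n_rejected_channels=len(conc.rejected_channels),
                           active_channels=active)
    if out_dir is not None:
        _write_subject(result, Path(out_dir), config, scenario)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_subject(res: SubjectResult, out: Path, config, scenario) -> None:
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    res.log.to_csv(out / "events.csv")
    tio.write_effectmap_csv(res.effect_map, out / "effect_map.csv")
    pd.DataFrame([res.summary_row()]).to_csv(out / "summary.csv", index=False)
    cv_json = {}
    for v, r in res.cv.items():
        cv_json[v] = {
            "median_accuracy": r.median_accuracy,
            "pooled_accuracy": r.pooled_accuracy,
            "mean_auc": r.mean_auc,
            "sd_auc": r.sd_auc,
            "mean_fn_rate": r.mean_fn_rate,
            "mean_confusion": r.mean_confusion.tolist(),
            "folds": [
                {"tp": f.tp, "tn": f.tn, "fp": f.fp, "fn": f.fn,
                 "accuracy": f.accuracy, "auc": f.auc}
                for f in r.folds
            ],
        }
    (out / "cv_reports.json").write_text(json.dumps(cv_json, indent=2))
    if res.shap is not None:
        imp, names = global_importance(res.shap)
        (out / "shap_importance.json").write_text(
            json.dumps(dict(zip(names, imp.tolist())), indent=2))
        rows = []
        for i in range(res.shap.phi.shape[0]):
            for j, nm in enumerate(res.shap.feature_names):
                rows.append({"instance": i, "feature": nm,
                             "phi": res.shap.phi[i, j],
                             "feature_value": res.shap.feature_values[i, j]})
        pd.DataFrame(rows).to_csv(out / "shap_values.csv", index=False)
    manifest = {
        "seed": res.seed,
        "config": config or {},
        "scenario": asdict(scenario),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json"},
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    summary: pd.DataFrame
    group_effect_map: EffectMap | None
    failures: list[tuple[int, str]] = field(default_factory=list)

    def median_accuracy(self, variant: str) -> float:
        """Median over all subjects x folds (the headline statistic)."""
        accs = [f.accuracy for s in self.subjects for f in s.cv[variant].folds]
        return float(np.median(accs))

    def fn_rates(self, variant: str) -> np.ndarray:
        return np.array([s.cv[variant].mean_fn_rate for s in self.subjects])

    def mean_confusion(self, variant: str) -> np.ndarray:
        return np.mean([s.cv[variant].mean_confusion for s in self.subjects], axis=0)

    def aucs(self, variant: str) -> np.ndarray:
        return np.array([s.cv[variant].mean_auc for s in self.subjects])


def run_cohort(n_subjects: int, config: dict | None = None, master_seed: int = 0,
               compute_shap: bool = False, out_dir: str | Path | None = None,
               variants: tuple[str, ...] = VARIANTS) -> CohortResult:
    """Run ``n_subjects`` independent synthetic subjects and aggregate."""
    if n_subjects < 2:
        raise ValueError("a cohort needs >= 2 subjects")
    subjects, failures = [], []
    for i in range(n_subjects):
        seed = subject_seed(master_seed, i)
        sub_out = None if out_dir is None else Path(out_dir) / f"subject_{i:02d}"
        try:
            subjects.append(run_subject(config, seed=seed,
                                        compute_shap=compute_shap,
                                        out_dir=sub_out, variants=variants))
        except Exception as exc:  # aggregate over completers
            failures.append((i, str(exc)))
    if not subjects:
        raise RuntimeError("every subject failed")
    summary = pd.DataFrame([s.summary_row() for s in subjects])
    group_em = (group_average([s.effect_map for s in subjects])
                if len(subjects) >= 2 else None)
    result = CohortResult(subjects=subjects, summary=summary,
                          group_effect_map=group_em, failures=failures)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        if group_em is not None:
            tio.write_effectmap_csv(group_em, out / "group_effect_map.csv")
    return result
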