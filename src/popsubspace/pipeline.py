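"""Cohort pipeline: run every analysis per session and aggregate.

The pipeline runs segmentation -> subspace -> decoding -> behavior ->
reactivation per session, then applies the cohort-level statistics: paired
Wilcoxon signed-rank (data vs shuffle mean per session), one-sample
signed-rank for relative accuracies and reactivation statistics against
zero, and Kolmogorov-Smirnov tests where distributions are compared.
Significance is flagged at the three alpha levels 0.05, 0.01, 0.005.

The report is a directory of TSV tables plus a JSON manifest carrying the
package version, configuration (seeds, reps, toggles), and a config hash;
identical configuration and seed reproduce a byte-identical report.
Sessions that fail an analysis are skipped with the reason recorded in the
manifest; the pipeline fails only if every session fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .behavior import classify_session, session_performance
from .decoding import (
    FEATURES,
    aligned_labels,
    angle_analysis,
    cross_decode,
    decode_with_null,
)
from .reactivation import FEATURE_VALUES, reactivation_distributions, paired_feature_control
from .segmentation import phase_rate_vectors, select_active_neurons
from .session import SessionRecording, load_session
from .subspace import phase_separability
from .synth import SynthConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("popsubspace")

ALPHAS = (0.05, 0.01, 0.005)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (all provenance lands in the manifest)."""

    input_dir: str | None = None  # directory of session bundles
    simulate: dict | None = None  # {"n_sessions": int, "config": {SynthConfig overrides}}
    seed: int = 0
    shuffle_reps: int = 50
    dims: tuple[int, ...] = (1, 2, 3, 4)
    bin_s: float = 1.0
    analyses: tuple[str, ...] = ("separability", "decoding", "angles", "cross_decoding", "behavior", "reactivation")
    alphas: tuple[float, ...] = ALPHAS

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        d["analyses"] = list(self.analyses)
        d["alphas"] = list(self.alphas)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(cfg: PipelineConfig) -> list[tuple[str, SessionRecording]]:
    if cfg.simulate is not None:
        overrides = dict(cfg.simulate.get("config", {}))
        n = int(cfg.simulate.get("n_sessions", 1))
        synth = SynthConfig(**overrides)
        cohort = generate_cohort(synth, n, cfg.seed)
        return [(f"sim-{i:03d}", s) for i, (s, _) in enumerate(cohort)]
    if cfg.input_dir is None:
        raise ValueError("config needs input_dir or simulate")
    out = []
    for p in sorted(Path(cfg.input_dir).iterdir()):
        if p.is_dir():
            out.append((p.name, p))  # lazily loaded below
    return out


def _signif(p: float, alphas) -> str:
    for a in sorted(alphas):
        if p < a:
            return f"p<{a}"
    return "ns"


def _analyze_session(name: str, session: SessionRecording, cfg: PipelineConfig, seed: int) -> dict:
    out: dict = {"session": name}
    active = select_active_neurons(session)
    out["n_active"] = len(active)
    rng = np.random.default_rng(seed)

    if "separability" in cfg.analyses:
        sep = phase_separability(session, dims=cfg.dims, active_ids=active)
        out["separability"] = [
            {"session": name, "d": d, "error": sep.errors[d], "chance": sep.chance} for d in cfg.dims
        ]

    pv = {p: phase_rate_vectors(session, p, active) for p in ("trial", "iti")}
    refs = {"trial": "current", "iti": "previous"}

    if "decoding" in cfg.analyses:
        rows = []
        for phase in ("trial", "iti"):
            for f in FEATURES:
                idx, lab = aligned_labels(session.trials.labels(f), phase, refs[phase])
                try:
                    res = decode_with_null(
                        pv[phase].rates[idx], lab, reps=cfg.shuffle_reps, seed=rng,
                        feature=f, phase=phase, reference=refs[phase],
                    )
                except ValueError as exc:
                    log.warning("session %s: decoding %s/%s skipped (%s)", name, phase, f, exc)
                    continue
                rows.append(
                    {
                        "session": name, "phase": phase, "feature": f, "reference": refs[phase],
                        "accuracy": res.accuracy, "null_mean": float(np.mean(res.null_accuracies)),
                        "relative_accuracy": res.relative_accuracy,
                    }
                )
        out["decoding"] = rows

    if "angles" in cfg.analyses:
        ang = angle_analysis(session, active, shuffle_reps=10, seed=int(rng.integers(2**31 - 1)))
        out["angles"] = [
            {
                "session": name, "feature": f,
                "angle_rad": ang.between_phase[f],
                "shuffled_median_rad": float(np.median(ang.between_phase_shuffled[f])),
            }
            for f in FEATURES
        ]
        out["angles_within"] = [
            {"session": name, "phase": k[0], "feature_1": k[1], "feature_2": k[2], "angle_rad": v}
            for k, v in ang.within_phase.items()
        ]

    if "cross_decoding" in cfg.analyses:
        rows = []
        for f in FEATURES:
            it, lt = aligned_labels(session.trials.labels(f), "trial", "current")
            ii, li = aligned_labels(session.trials.labels(f), "iti", "previous")
            for (trp, tep, tr, te) in (
                ("trial", "iti", (pv["trial"].rates[it], lt), (pv["iti"].rates[ii], li)),
                ("iti", "trial", (pv["iti"].rates[ii], li), (pv["trial"].rates[it], lt)),
            ):
                try:
                    res = cross_decode(
                        tr, te, mode="full", feature=f, train_phase=trp, test_phase=tep,
                        null_reps=cfg.shuffle_reps, seed=rng,
                    )
                except ValueError as exc:
                    log.warning("session %s: cross-decoding %s skipped (%s)", name, f, exc)
                    continue
                rows.append(
                    {
                        "session": name, "feature": f, "train_phase": trp, "test_phase": tep,
                        "accuracy": res.accuracy, "null_mean": float(np.mean(res.null_accuracies)),
                        "relative_accuracy": res.relative_accuracy,
                    }
                )
        out["cross_decoding"] = rows

    if "behavior" in cfg.analyses:
        a = classify_session(session)
        out["behavior"] = [
            {
                "session": name, "class": a.session_class, "split_trial": a.split_trial,
                "r_before": a.r_before, "r_after": a.r_after, "delta_r": a.delta_r,
                "performance": session_performance(session.trials.labels("outcome")),
            }
        ]

    if "reactivation" in cfg.analyses:
        rows, controls = [], []
        for source in ("trial", "iti"):
            for f in FEATURES:
                for val in FEATURE_VALUES[f]:
                    try:
                        res = reactivation_distributions(
                            session, f, val, source=source, bin_s=cfg.bin_s, active_ids=active
                        )
                    except ValueError as exc:
                        log.warning("session %s: reactivation %s=%s skipped (%s)", name, f, val, exc)
                        continue
                    rows.append(
                        {
                            "session": name, "source": source, "feature": f, "value": val,
                            "m_pre": res.m_pre, "m_post": res.m_post,
                            "statistic": res.statistic, "ks_p": res.ks_p,
                        }
                    )
                for epoch in ("pre", "post"):
                    try:
                        c = paired_feature_control(session, f, epoch, source=source, bin_s=cfg.bin_s, active_ids=active)
                    except ValueError:
                        continue
                    controls.append(
                        {"session": name, "source": source, "feature": f, "epoch": epoch, "median_diff": c}
                    )
        out["reactivation"] = rows
        out["reactivation_controls"] = controls
    return out


def _cohort_stats(tables: dict[str, pd.DataFrame], alphas) -> dict:
    statsd: dict = {}
    dec = tables.get("decoding")
    if dec is not None and not dec.empty:
        rows = {}
        for (phase, f), grp in dec.groupby(["phase", "feature"]):
            entry = {"n": int(len(grp)), "mean_relative_accuracy": float(grp["relative_accuracy"].mean())}
            if len(grp) >= 5 and np.ptp(grp["relative_accuracy"]) > 0:
                w = stats.wilcoxon(grp["accuracy"], grp["null_mean"])
                entry["wilcoxon_p"] = float(w.pvalue)
                entry["significance"] = _signif(float(w.pvalue), alphas)
            rows[f"{phase}/{f}"] = entry
        statsd["decoding"] = rows
    rea = tables.get("reactivation")
    if rea is not None and not rea.empty:
        rows = {}
        for (source, f, val), grp in rea.groupby(["source", "feature", "value"]):
            entry = {"n": int(len(grp)), "median_statistic": float(grp["statistic"].median())}
            if len(grp) >= 5 and np.ptp(grp["statistic"]) > 0:
                w = stats.wilcoxon(grp["statistic"])
                entry["signed_rank_p"] = float(w.pvalue)
                entry["significance"] = _signif(float(w.pvalue), alphas)
            rows[f"{source}/{f}={val}"] = entry
        statsd["reactivation"] = rows
    ang = tables.get("angles")
    if ang is not None and not ang.empty:
        rows = {}
        for f, grp in ang.groupby("feature"):
            rows[f] = {"n": int(len(grp)), "median_angle_rad": float(grp["angle_rad"].median())}
        statsd["angles"] = rows
    return statsd


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all configured analyses over the cohort and write the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = _load_cohort(cfg)
    if not entries:
        raise ValueError("no sessions found")

    seed_rng = np.random.default_rng(cfg.seed)
    session_seeds = seed_rng.integers(0, 2**31 - 1, size=len(entries))

    per_session: list[dict] = []
    skipped: list[dict] = []
    for (name, item), s_seed in zip(entries, session_seeds):
        try:
            session = item if isinstance(item, SessionRecording) else load_session(item)
            per_session.append(_analyze_session(name, session, cfg, int(s_seed)))
            log.info("session %s analyzed", name)
        except Exception as exc:  # session-level failure: skip, keep going
            log.warning("session %s skipped: %s", name, exc)
            skipped.append({"session": name, "reason": str(exc)})
    if not per_session:
        raise RuntimeError("all sessions failed")

    tables: dict[str, pd.DataFrame] = {}
    for key in ("separability", "decoding", "angles", "angles_within", "cross_decoding", "behavior", "reactivation", "reactivation_controls"):
        rows = [r for s in per_session for r in s.get(key, [])]
        if rows:
            tables[key] = pd.DataFrame(rows)
    for key, df in tables.items():
        df.to_csv(out / f"{key}.tsv", sep="\t", index=False, float_format="%.10g")

    manifest = {
        "package": "popsubspace",
        "version": __version__,
        "config": cfg.to_jsonable(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_sessions_analyzed": len(per_session),
        "skipped_sessions": skipped,
        "tables": sorted(tables),
        "cohort_stats": _cohort_stats(tables, cfg.alphas),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
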