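"""File formats, run configuration, and the end-to-end pipeline.

Trial tables are plain CSV, one row per trial, with pulse strengths in
columns ``pulse_1..pulse_N`` (1-based pulse indexing throughout). A
sidecar YAML file records the generating configuration and the seed, so
every simulated dataset is reproducible from its own metadata. Reports
are JSON (group statistics, fits) plus a per-session summary CSV.

All randomness flows from the single configured seed through named
substreams (one per stage and session), so regenerating with the same
config yields byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import analysis, psychometrics, revcorr
from .observers import (
    AccumulatorObserver,
    LinearObserver,
    attach_choices,
    simulate_accumulator_choices,
    simulate_extrema_choices,
    simulate_linear_choices,
)
from .stimulus import CONDITIONS, StimulusConfig, TrialRecord, generate_session

__all__ = [
    "RunConfig",
    "SchemaError",
    "substream",
    "write_trial_table",
    "read_trial_table",
    "write_sidecar",
    "run_pipeline",
]

logger = logging.getLogger("pulsekernel")

_META_COLUMNS = [
    "session_id",
    "subject_id",
    "condition",
    "trial_index",
    "distribution_mu",
    "net_strength",
    "rewarded_direction",
    "frozen_seed",
    "choice",
    "correct",
]


class SchemaError(ValueError):
    """A trial table violates the expected column schema."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, collision-resistant child stream of the run seed."""
    return np.random.default_rng(
        [zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF, int(seed)]
    )


@dataclass
class RunConfig:
    """Configuration of one simulated cohort run.

    ``observer`` is a mapping with a ``type`` key (``linear``,
    ``accumulator`` or ``extrema``) and that observer's parameters, or
    None when trial tables with choices are loaded from ``data_dir``
    instead of simulated.
    """

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    observer: Optional[dict] = None
    conditions: tuple = ("flat",)
    n_trials: int = 1000
    n_sessions: int = 3
    seed: int = 0
    subject_id: str = "S1"
    data_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        stim = asdict(self.stimulus)
        stim["mu_set"] = list(stim["mu_set"])
        stim["trial_type_probabilities"] = list(stim["trial_type_probabilities"])
        d["stimulus"] = stim
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        stim = d.pop("stimulus", {})
        if isinstance(stim.get("mu_set"), list):
            stim["mu_set"] = tuple(stim["mu_set"])
        if isinstance(stim.get("trial_type_probabilities"), list):
            stim["trial_type_probabilities"] = tuple(stim["trial_type_probabilities"])
        d["stimulus"] = StimulusConfig(**stim)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_trial_table(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write one session as CSV with pulse_1..pulse_N strength columns."""
    n_pulses = len(trials[0].pulse_strengths)
    rows = []
    for t in trials:
        row = {
            "session_id": t.session_id,
            "subject_id": t.subject_id,
            "condition": t.condition,
            "trial_index": t.trial_index,
            "distribution_mu": t.distribution_mu,
            "net_strength": t.net_strength,
            "rewarded_direction": t.rewarded_direction,
            "frozen_seed": int(t.frozen_seed),
            "choice": "" if t.choice is None else int(t.choice),
            "correct": "" if t.correct is None else int(t.correct),
        }
        for i in range(n_pulses):
            row[f"pulse_{i + 1}"] = t.pulse_strengths[i]
        rows.append(row)
    cols = _META_COLUMNS + [f"pulse_{i + 1}" for i in range(n_pulses)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.12g")


def read_trial_table(
    path: str | Path,
    n_pulses: Optional[int] = None,
    n_elements: int = 19,
    continuous: bool = False,
) -> list[TrialRecord]:
    """Load and validate a trial table.

    Pulse strengths must lie on the element-count lattice
    ``k / n_elements`` unless ``continuous=True`` (for external datasets
    recorded in other units). Schema violations name the offending row.
    """
    df = pd.read_csv(path)
    pulse_cols = sorted(
        (c for c in df.columns if c.startswith("pulse_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not pulse_cols:
        raise SchemaError("no pulse_* columns found")
    if n_pulses is not None and len(pulse_cols) != n_pulses:
        raise SchemaError(
            f"expected {n_pulses} pulse columns, found {len(pulse_cols)}"
        )
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    trials = []
    for ridx, row in df.iterrows():
        strengths = np.array([row[c] for c in pulse_cols], dtype=float)
        if continuous:
            counts = strengths
        else:
            counts_f = strengths * n_elements
            counts = np.round(counts_f)
            if not np.allclose(counts, counts_f, atol=1e-6):
                raise SchemaError(
                    f"row {ridx}: pulse strengths are off the "
                    f"k/{n_elements} lattice (use continuous=True for external data)"
                )
            counts = counts.astype(int)
        choice = row["choice"]
        if pd.isna(choice):
            choice = None
        else:
            choice = int(choice)
            if choice not in (0, 1):
                raise SchemaError(f"row {ridx}: choice must be 0 or 1, got {choice}")
        correct = row["correct"]
        correct = None if pd.isna(correct) else int(correct)
        cond = str(row["condition"])
        if cond not in CONDITIONS:
            raise SchemaError(f"row {ridx}: unknown condition {cond!r}")
        trials.append(
            TrialRecord(
                session_id=str(row["session_id"]),
                subject_id=str(row["subject_id"]),
                condition=cond,
                trial_index=int(row["trial_index"]),
                distribution_mu=float(row["distribution_mu"]),
                pulse_strengths=strengths,
                pulse_element_counts=counts,
                net_strength=float(row["net_strength"]),
                rewarded_direction=int(row["rewarded_direction"]),
                frozen_seed=bool(row["frozen_seed"]),
                choice=choice,
                correct=correct,
            )
        )
    return trials


def write_sidecar(config: RunConfig, path: str | Path) -> None:
    """Record the generating configuration, observer and seed as YAML."""
    payload = config.to_dict()
    payload["config_hash"] = config.hash()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _make_choices(trials, observer: dict, rng: np.random.Generator) -> np.ndarray:
    kind = observer.get("type")
    params = {k: v for k, v in observer.items() if k != "type"}
    if kind == "linear":
        obs = LinearObserver(
            kernel=np.asarray(params["kernel"], dtype=float),
            bias=params.get("bias", 0.0),
            lapse=params.get("lapse", 0.0),
        )
        return simulate_linear_choices(trials, obs, rng)
    if kind == "accumulator":
        obs = AccumulatorObserver(
            gain=params.get("gain", 1.0),
            bound=params.get("bound", np.inf),
            leak=params.get("leak", 0.0),
            noise_sd=params.get("noise_sd", 0.0),
        )
        return simulate_accumulator_choices(trials, obs, rng)
    if kind == "extrema":
        return simulate_extrema_choices(trials, rng)
    raise ValueError(f"unknown observer type {kind!r}")


def _simulate_cohort(config: RunConfig) -> dict[str, list[TrialRecord]]:
    sessions: dict[str, list[TrialRecord]] = {}
    for cond in config.conditions:
        stim = StimulusConfig(**{**asdict(config.stimulus), "condition": cond})
        for s in range(config.n_sessions):
            sid = f"{cond}_{s + 1:03d}"
            rng = substream(config.seed, f"stimulus/{sid}")
            trials = generate_session(
                stim,
                config.n_trials,
                rng,
                session_id=sid,
                subject_id=config.subject_id,
            )
            if config.observer is None:
                raise ValueError("observer spec required when simulating choices")
            choices = _make_choices(
                trials, config.observer, substream(config.seed, f"observer/{sid}")
            )
            sessions[sid] = attach_choices(trials, choices)
    return sessions


def _load_cohort(config: RunConfig) -> dict[str, list[TrialRecord]]:
    data_dir = Path(config.data_dir)
    sessions = {}
    for path in sorted(data_dir.glob("*.csv")):
        trials = read_trial_table(path, n_elements=config.stimulus.n_elements)
        if trials:
            sessions[trials[0].session_id] = trials
    if not sessions:
        raise ValueError(f"no session tables found in {data_dir}")
    return sessions


def _group_report(slopes_by_condition: dict) -> dict:
    """Lenient group-statistics block: each test runs when its sample-size
    preconditions hold and is reported as null with a note otherwise."""
    from scipy import stats as sps

    report: dict = {"per_condition": {}, "anova_p": None, "bartlett_p": {}, "notes": []}
    for cond, slopes in slopes_by_condition.items():
        v = np.asarray(slopes, dtype=float)
        entry = {
            "n": int(len(v)),
            "mean_slope": float(v.mean()),
            "median_slope": float(np.median(v)),
            "sd_slope": float(v.std(ddof=1)) if len(v) > 1 else None,
            "sign_test_p": None,
        }
        if len(v) >= 6:
            entry["sign_test_p"] = analysis._sign_test_p(v)
        else:
            report["notes"].append(f"{cond}: <6 sessions, sign test skipped")
        report["per_condition"][cond] = entry
    names = [c for c, v in slopes_by_condition.items() if len(v) >= 2]
    if len(names) >= 2:
        report["anova_p"] = float(
            sps.f_oneway(*[np.asarray(slopes_by_condition[c], float) for c in names]).pvalue
        )
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                report["bartlett_p"][f"{a}|{b}"] = float(
                    sps.bartlett(
                        np.asarray(slopes_by_condition[a], float),
                        np.asarray(slopes_by_condition[b], float),
                    ).pvalue
                )
    else:
        report["notes"].append("fewer than 2 eligible conditions; ANOVA/Bartlett skipped")
    return report


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate (or load) a cohort and run the full analysis chain.

    Stages: stimulus/choice generation (or loading) -> session QC ->
    psychometric fits (on per-subject z-scored net strengths) -> kernel
    fits with evidence-optimized ridge -> slope/energy summaries -> group
    statistics. Writes per-session trial tables, a summary CSV, a JSON
    report and the sidecar config; returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "sessions").mkdir(exist_ok=True)
    if config.n_sessions < 1 or not config.conditions:
        raise ValueError("config requests an empty cohort")

    t0 = time.perf_counter()
    sessions = (
        _load_cohort(config) if config.data_dir else _simulate_cohort(config)
    )
    logger.info(
        "stage=simulate sessions=%d trials=%d elapsed=%.2fs",
        len(sessions),
        sum(len(v) for v in sessions.values()),
        time.perf_counter() - t0,
    )

    # per-subject z-scoring pools every session of that subject
    all_trials = [t for trials in sessions.values() for t in trials]
    nets = np.array([t.net_strength for t in all_trials])
    subjects = np.array([t.subject_id for t in all_trials])
    z = psychometrics.zscore_strengths(nets, subjects)
    z_by_session: dict[str, np.ndarray] = {}
    pos = 0
    for sid, trials in sessions.items():
        z_by_session[sid] = z[pos : pos + len(trials)]
        pos += len(trials)

    t1 = time.perf_counter()
    per_session = []
    stats_list = []
    for sid, trials in sessions.items():
        choices = np.array([t.choice for t in trials], dtype=int)
        pf = psychometrics.fit_psychometric(z_by_session[sid], choices)
        kf = revcorr.fit_kernel(revcorr.build_trial_matrix(trials))
        summary = analysis.summarize_kernel(kf.weights_normalized)
        st = analysis.summarize_session(
            trials, pf, slope=summary.slope, energy=summary.energy
        )
        stats_list.append(st)
        per_session.append(
            {
                "session_id": sid,
                "subject_id": st.subject_id,
                "condition": st.condition,
                "n_trials": st.n_trials,
                "alpha": pf.alpha,
                "beta": pf.beta,
                "gamma": pf.gamma,
                "threshold75": pf.threshold75,
                "lambda": kf.lam,
                "weights": [float(w) for w in kf.weights],
                "weights_normalized": [float(w) for w in kf.weights_normalized],
                "bias": kf.bias,
                "slope": summary.slope,
                "energy": summary.energy,
                "strong_accuracy": st.strong_accuracy,
            }
        )
        write_trial_table(trials, out / "sessions" / f"{sid}.csv")
    logger.info("stage=fits sessions=%d elapsed=%.2fs", len(sessions), time.perf_counter() - t1)

    qc = analysis.session_qc(stats_list)
    qc_by_id = {r.session_id: r for r in qc}
    for row in per_session:
        r = qc_by_id[row["session_id"]]
        row["qc_included"] = bool(r.included)
        row["qc_reasons"] = list(r.reasons)

    slopes_by_condition: dict[str, list[float]] = {}
    for row in per_session:
        if row["qc_included"]:
            slopes_by_condition.setdefault(row["condition"], []).append(row["slope"])
    group = _group_report(slopes_by_condition) if slopes_by_condition else None

    report = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_sessions": len(sessions),
        "n_included": sum(1 for r in qc if r.included),
        "sessions": per_session,
        "group_statistics": group,
    }

    summary_cols = [
        "session_id",
        "subject_id",
        "condition",
        "n_trials",
        "threshold75",
        "slope",
        "energy",
        "strong_accuracy",
        "qc_included",
    ]
    pd.DataFrame(per_session)[summary_cols].to_csv(
        out / "summary.csv", index=False, float_format="%.12g"
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    write_sidecar(config, out / "config.yaml")
    logger.info("stage=report elapsed=%.2fs total", time.perf_counter() - t0)
    return report
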