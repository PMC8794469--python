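"""End-to-end orchestration: simulate (or load) -> HMM fit/label -> RL
fit/compare -> switch dynamics -> energy landscape -> metrics -> report.

All artifacts are tab-separated text tables plus JSON sidecars so every
stage output can be inspected and parsed back. A single master seed fans
out to fixed per-stage substreams, so toggling a later stage never changes
an earlier stage's results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import behavior_metrics as bm
from . import energy_landscape as el
from . import explore_hmm as eh
from . import rl_models as rm
from . import switch_dynamics as sd
from .bandit_env import RewardSchedule, Session
from .synthetic_cohort import Cohort, CohortConfig, LatencyConfig, generate_cohort

__all__ = [
    "RunConfig",
    "read_sessions",
    "write_sessions",
    "run_pipeline",
    "make_report",
]

logger = logging.getLogger("explorebandit")

SESSION_COLUMNS = [
    "subject",
    "group",
    "session",
    "trial",
    "choice",
    "reward",
    "response_time",
    "retrieval_time",
    "p_left",
    "p_right",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "explorebandit_run"
    input_sessions: Optional[str] = None  # path; None -> synthesize
    cohort: CohortConfig = field(default_factory=CohortConfig)
    hmm_variants: tuple = ("tied2", "io4", "nt4")
    hmm_restarts: int = 20
    hmm_tol: float = 1e-6
    rl_models: tuple = rm.MODEL_IDS
    rl_restarts: int = 10
    rl_fit_unit: str = "subject"
    mixture_max_components: int = 4
    run_metrics: bool = True

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if cohort_raw:
            latency_raw = cohort_raw.pop("latency", None)
            cohort = CohortConfig(**cohort_raw)
            if latency_raw:
                cohort.latency = LatencyConfig(**latency_raw)
            cfg.cohort = cohort
        for key in ("hmm_variants", "rl_models"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


# ---------------------------------------------------------------------------
# session table IO


def write_sessions(
    sessions: Sequence[Session],
    path: Union[str, Path],
    hmm_states: Optional[dict] = None,
    rl_labels: Optional[dict] = None,
) -> None:
    """Write sessions as one tidy tab-separated table (one row per trial).
    Optional per-(subject, session) label dicts add ``hmm_state`` (E/L/R)
    and ``rl_explore`` columns."""
    rows = []
    for s in sessions:
        key = (s.subject_id, s.session_index)
        codes = hmm_states[key].codes if hmm_states and key in hmm_states else None
        rl = rl_labels[key] if rl_labels and key in rl_labels else None
        for t in range(s.n_trials):
            row = {
                "subject": s.subject_id,
                "group": s.group,
                "session": s.session_index,
                "trial": t + 1,
                "choice": int(s.choices[t]),
                "reward": int(s.rewards[t]),
                "response_time": (
                    float(s.response_time[t]) if s.response_time is not None else np.nan
                ),
                "retrieval_time": (
                    float(s.retrieval_time[t]) if s.retrieval_time is not None else np.nan
                ),
                "p_left": (
                    float(s.schedule.p_reward[t, 0]) if s.schedule is not None else np.nan
                ),
                "p_right": (
                    float(s.schedule.p_reward[t, 1]) if s.schedule is not None else np.nan
                ),
            }
            if codes is not None:
                row["hmm_state"] = codes[t]
            if rl is not None:
                row["rl_explore"] = int(rl[t])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class SessionTableError(ValueError):
    """Schema violation in a session table."""


def read_sessions(path: Union[str, Path]) -> list[Session]:
    """Read a session table back into Session objects, one per
    (subject, session), validating the schema row by row."""
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        logger.warning("session table %s is empty", path)
        return []
    missing = [c for c in ("subject", "session", "trial", "choice", "reward") if c not in table]
    if missing:
        raise SessionTableError(f"missing required columns: {missing}")

    bad = table.index[~table["choice"].isin([0, 1])]
    if len(bad):
        raise SessionTableError(f"choice not in {{0,1}} at row {int(bad[0]) + 2}")
    bad = table.index[~table["reward"].isin([0, 1])]
    if len(bad):
        raise SessionTableError(f"reward not in {{0,1}} at row {int(bad[0]) + 2}")

    sessions = []
    for (subject, sess_idx), grp in table.groupby(["subject", "session"], sort=False):
        grp = grp.sort_values("trial")
        trials = grp["trial"].to_numpy()
        if trials[0] != 1 or not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise SessionTableError(
                f"non-contiguous trials for subject {subject} session {sess_idx}"
            )
        schedule = None
        if "p_left" in grp and grp["p_left"].notna().all() and grp["p_right"].notna().all():
            schedule = RewardSchedule(
                n_trials=len(grp),
                p_reward=np.column_stack([grp["p_left"], grp["p_right"]]),
            )
        def _optional(col):
            if col in grp and grp[col].notna().all():
                return grp[col].to_numpy(dtype=float)
            return None
        sessions.append(
            Session(
                subject_id=str(subject),
                group=str(grp["group"].iloc[0]) if "group" in grp else "",
                session_index=int(sess_idx),
                choices=grp["choice"].to_numpy(),
                rewards=grp["reward"].to_numpy(),
                response_time=_optional("response_time"),
                retrieval_time=_optional("retrieval_time"),
                schedule=schedule,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# pipeline stages


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def _by_subject(sessions: Sequence[Session]) -> dict[str, list[Session]]:
    out: dict[str, list[Session]] = {}
    for s in sessions:
        out.setdefault(s.subject_id, []).append(s)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    t_start = time.time()

    # stage 1: data
    logger.info("stage data: seed=%d", seeds[0])
    if config.input_sessions is not None:
        sessions = read_sessions(config.input_sessions)
        cohort = None
    else:
        cohort = generate_cohort(config.cohort, seed=seeds[0])
        sessions = cohort.sessions
        pd.DataFrame(
            [
                {"subject": a.subject_id, "group": a.group, "model_id": a.model_id,
                 **a.params}
                for a in cohort.agents
            ]
        ).to_csv(out / "ground_truth_params.tsv", sep="\t", index=False)
    if not sessions:
        raise RuntimeError("stage data: no sessions available")
    by_subject = _by_subject(sessions)
    n_obs = sum(s.n_trials for s in sessions)

    # stage 2: HMM fitting, comparison, decoding
    logger.info("stage hmm: %d subjects, variants %s", len(by_subject), config.hmm_variants)
    rng = np.random.default_rng(seeds[1])
    hmm_fits: dict[str, list[eh.HmmFit]] = {v: [] for v in config.hmm_variants}
    for subject, subj_sessions in by_subject.items():
        for variant in config.hmm_variants:
            hmm_fits[variant].append(
                eh.fit_hmm(
                    subj_sessions,
                    variant,
                    n_restarts=config.hmm_restarts,
                    tol=config.hmm_tol,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    all_fits = [f for fits in hmm_fits.values() for f in fits]
    ic_table = eh.information_criteria(all_fits, n_obs=n_obs)
    ic_table.to_csv(out / "hmm_ic.tsv", sep="\t")
    best_variant = ic_table.index[0]
    label_variant = "tied2" if "tied2" in config.hmm_variants else best_variant
    hmm_states = {}
    for fit in hmm_fits[label_variant]:
        for sess in by_subject[fit.subject_id]:
            hmm_states[(fit.subject_id, sess.session_index)] = eh.viterbi_decode(
                fit.spec, sess
            )
    (out / "hmm_fits.json").write_text(
        json.dumps(
            [
                {
                    "subject": f.subject_id,
                    "group": f.group,
                    "variant": f.spec.variant,
                    "params": f.spec.params,
                    "loglik": f.total_loglik,
                    "converged": f.converged,
                    "best_seed": f.best_seed,
                }
                for f in all_fits
            ],
            indent=1,
        )
    )

    # stage 3: RL fitting and comparison
    logger.info("stage rl: models %s", list(config.rl_models))
    rng = np.random.default_rng(seeds[2])
    rl_fits: dict[str, list[rm.RlFit]] = {m: [] for m in config.rl_models}
    rl_labels = {}
    for subject, subj_sessions in by_subject.items():
        for model_id in config.rl_models:
            fit = rm.fit_rl(
                model_id,
                subj_sessions,
                n_restarts=config.rl_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
                fit_unit="subject",
            )
            rl_fits[model_id].append(fit)
    rl_rows = [
        {"subject": f.subject_id, "group": f.group, "model_id": f.model_id,
         "nll": f.nll, "aic": f.aic, "bic": f.bic, "agreement": f.agreement,
         **{f"param_{k}": v for k, v in f.params.items()}}
        for fits in rl_fits.values()
        for f in fits
    ]
    pd.DataFrame(rl_rows).to_csv(out / "rl_fits.tsv", sep="\t", index=False)
    rl_ic_by_group = {}
    groups = sorted({s.group for s in sessions})
    for group in groups:
        group_n = sum(s.n_trials for s in sessions if s.group == group)
        fits_g = [f for fits in rl_fits.values() for f in fits if f.group == group]
        if fits_g and group_n:
            rl_ic_by_group[group] = eh.information_criteria(fits_g, n_obs=group_n)
    if rl_ic_by_group:
        pd.concat(rl_ic_by_group, names=["group"]).to_csv(out / "rl_ic.tsv", sep="\t")
    # explore labels from the best value-based model per AIC
    value_models = [m for m in config.rl_models if m not in ("random", "wsls")]
    if value_models:
        pooled = eh.information_criteria(
            [f for m in value_models for f in rl_fits[m]], n_obs=n_obs
        )
        best_rl = pooled.index[0]
        for fit in rl_fits[best_rl]:
            for sess in by_subject[fit.subject_id]:
                rl_labels[(fit.subject_id, sess.session_index)] = rm.rl_explore_labels(
                    fit, sess
                )

    write_sessions(sessions, out / "sessions.tsv", hmm_states=hmm_states, rl_labels=rl_labels)

    # stage 4: switch dynamics
    logger.info("stage dynamics")
    lengths = np.concatenate([sd.run_lengths(s.choices) for s in sessions])
    mix_table = sd.mixture_model_selection(
        lengths, max_components=config.mixture_max_components, seed=seeds[3]
    )
    mix_table.to_csv(out / "switch_mixture.tsv", sep="\t", index=False)

    # stage 5: energy landscape (tied-variant fits only)
    landscape_path = None
    if label_variant in ("tied2", "nt4"):
        fits_by_group = {}
        for fit in hmm_fits[label_variant]:
            fits_by_group.setdefault(fit.group, []).append(fit)
        summaries = el.landscape_summary(fits_by_group)
        el.landscape_table(summaries).to_csv(out / "landscape.tsv", sep="\t")
        landscape_path = out / "landscape.tsv"

    # stage 6: metrics
    if config.run_metrics:
        logger.info("stage metrics")
        metric_rows = []
        for subject, subj_sessions in by_subject.items():
            frames = []
            for sess in subj_sessions:
                key = (subject, sess.session_index)
                states = hmm_states.get(key)
                row = {"subject": subject, "group": sess.group, "session": sess.session_index}
                if sess.schedule is not None:
                    row["p_reward_obtained"], row["p_reward_chance"] = bm.reward_vs_chance(sess)
                if sess.n_trials >= 2:
                    row.update(bm.wsls_rates(sess, states))
                    row["cmi_bits"] = bm.conditional_mutual_info(sess)
                if sess.response_time is not None and states is not None:
                    rl = rl_labels.get(key)
                    row.update(bm.latency_by_state(sess, states, rl))
                if states is not None:
                    row["explore_fraction"] = eh.explore_fraction(states)
                    rl = rl_labels.get(key)
                    if rl is not None and 0 < states.binary_explore.mean() < 1 and 0 < rl.mean() < 1:
                        row["r_tet_hmm_rl"] = bm.tetrachoric_corr(states.binary_explore, rl)
                frames.append(row)
            metric_rows.extend(frames)
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(out / "metrics_sessions.tsv", sep="\t", index=False)
        subject_means = metrics.groupby(["subject", "group"], sort=True).mean(numeric_only=True)
        subject_means.drop(columns=[c for c in ("session",) if c in subject_means]).to_csv(
            out / "metrics_subjects.tsv", sep="\t"
        )
        group_summary = subject_means.groupby("group").agg(["mean", "std"])
        group_summary.to_csv(out / "metrics_groups.tsv", sep="\t")
        if len(groups) == 2 and "explore_fraction" in subject_means:
            vals = {
                g: subject_means.xs(g, level="group")["explore_fraction"].dropna()
                for g in groups
            }
            if all(len(v) >= 2 for v in vals.values()):
                auc = bm.auc_separability(vals[groups[0]], vals[groups[1]])
                (out / "auc_explore.json").write_text(json.dumps(auc, default=float))

    make_report(out)
    logger.info("pipeline done in %.1fs -> %s", time.time() - t_start, out)
    return out


def make_report(artifact_dir: Union[str, Path]) -> Path:
    """Render a human-readable markdown summary from whatever artifacts
    are present in the directory; missing stages are listed, not fatal."""
    out = Path(artifact_dir)
    lines = ["# explorebandit run report", ""]
    found_any = False

    def table_section(fname: str, title: str, index_col=0):
        nonlocal found_any
        path = out / fname
        if not path.exists():
            lines.append(f"*{title}: no output found ({fname} missing).*\n")
            return
        found_any = True
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {title}\n")
        lines.append(df.round(4).to_string(index=False))
        lines.append("")

    table_section("hmm_ic.tsv", "HMM model comparison (pooled AIC/BIC, relative likelihoods)")
    table_section("rl_ic.tsv", "RL model comparison by group (AIC weights)")
    table_section("switch_mixture.tsv", "Run-length geometric-mixture selection")
    table_section("landscape.tsv", "Energy landscape by group")
    table_section("metrics_groups.tsv", "Behavioral metrics, group means and SDs")

    auc_path = out / "auc_explore.json"
    if auc_path.exists():
        found_any = True
        auc = json.loads(auc_path.read_text())
        lines.append("## Explore-fraction group separability\n")
        lines.append(
            f"AUC = {auc['auc']:.3f} (SE {auc['se']:.3f}, "
            f"95% CI [{auc['ci_low']:.3f}, {auc['ci_high']:.3f}], "
            f"p = {auc['p_value']:.4g})"
        )
        lines.append("")

    if not found_any:
        lines = ["# explorebandit run report", "", "No outputs found."]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
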