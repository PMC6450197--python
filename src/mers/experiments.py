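"""Configuration-driven reproduction of the three simulation studies.

Study 1 compares one-step-ahead prediction accuracy (pooled AUROC) of the
standard unidimensional ERS and the M-ERS on identical simulated streams.
Study 2 traces estimation error (MSE, |bias|) against the number of items
answered and benchmarks the final M-ERS estimates against batch EAP
estimates.  Study 3 compares accuracy-only updating with speed-accuracy
(HSHS) updating on the same streams, summarising per-dimension |bias| and
MSE both averaged over occasions (the headline summary) and at the final
occasion.

Every random choice descends deterministically from the experiment seed:
one item bank per pattern per replication (shared across the correlation
conditions), fresh learner populations and sessions per condition, paired
engines always scoring the same outcome stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine as eng
from . import evaluation as ev
from . import population as pop
from .item_bank import ItemBank, generate_bank

__all__ = ["StudyConfig", "run_study1", "run_study2", "run_study3", "replay_log"]


@dataclass(frozen=True)
class StudyConfig:
    """Shared configuration of the simulation studies (defaults = study design)."""

    patterns: tuple[str, ...] = ("bank1", "bank2")
    rhos: tuple[float, ...] = (0.0, 0.2, 0.5)
    n_learners: int = 250
    n_items: int = 200
    n_dims: int = 3
    proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    mu: tuple[float, ...] = (1.0, 1.0, 1.0)
    k_max: float = 0.4
    k_min: float = 0.1
    horizon: int | None = None  # defaults to n_items
    time_limit: float = 1.0
    seed: int = 0
    replications: int = 1
    eap_prior: str = "standard"  # 'standard' N(0,I) | 'population' N(mu, Sigma)
    eap_nodes: int = 21
    hshs_accuracy: str = "joint"

    def __post_init__(self):
        if not self.patterns or not self.rhos:
            raise ValueError("patterns and rhos must be non-empty")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    @property
    def schedule(self) -> eng.StepSchedule:
        return eng.StepSchedule(self.k_max, self.k_min, self.horizon or self.n_items)

    def engine(self, mode: str, outcome: str = "accuracy") -> eng.EngineConfig:
        return eng.EngineConfig(
            mode=mode,
            outcome=outcome,
            n_dims=self.n_dims,
            schedule=self.schedule,
            time_limit=self.time_limit,
        )


def _conditions(config: StudyConfig, mode: str):
    """Yield (rep, pattern, rho, bank, learners, stream) per condition."""
    for rep in range(config.replications):
        for p_idx, pattern in enumerate(config.patterns):
            bank_ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(rep, p_idx, 0)
            )
            bank = generate_bank(
                pattern,
                n_items=config.n_items,
                n_dims=config.n_dims,
                proportions=config.proportions,
                rng=np.random.default_rng(bank_ss),
            )
            for r_idx, rho in enumerate(config.rhos):
                pop_ss, stream_ss = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(rep, p_idx, r_idx + 1)
                ).spawn(2)
                spec = pop.PopulationSpec(
                    n_learners=config.n_learners,
                    mean=np.asarray(config.mu),
                    cov=pop.equicorrelation(rho, config.n_dims),
                )
                learners = pop.sample_abilities(spec, np.random.default_rng(pop_ss))
                stream = pop.simulate_stream(
                    bank,
                    learners,
                    mode=mode,
                    seed=stream_ss,
                    time_limit=config.time_limit,
                    hshs_accuracy=config.hshs_accuracy,
                )
                yield rep, pattern, rho, bank, learners, stream


def _with_se(detail: pd.DataFrame, by: list[str], values: list[str]) -> pd.DataFrame:
    g = detail.groupby(by, sort=False)[values]
    summary = g.mean().rename(columns={v: f"{v}_mean" for v in values})
    if detail["replication"].nunique() > 1:
        se = g.sem().rename(columns={v: f"{v}_se" for v in values})
        summary = summary.join(se)
    return summary.reset_index()


def run_study1(config: StudyConfig) -> dict:
    """Pooled AUROC of standard ERS vs M-ERS per condition (Table-2 shape)."""
    multi = config.engine("multi")
    uni = config.engine("uni")
    rows = []
    for rep, pattern, rho, bank, _, stream in _conditions(config, "accuracy"):
        outcomes = stream.y.astype(float)
        preds_m, _ = eng.replay_arrays(
            multi, stream.item_idx, outcomes, bank.difficulties, bank.loadings
        )
        preds_u, _ = eng.replay_arrays(
            uni, stream.item_idx, outcomes, bank.difficulties, bank.loadings
        )
        rows.append(
            {
                "replication": rep,
                "pattern": pattern,
                "rho": rho,
                "auroc_standard": ev.auroc(preds_u.ravel(), stream.y.ravel()).auroc,
                "auroc_mers": ev.auroc(preds_m.ravel(), stream.y.ravel()).auroc,
            }
        )
    detail = pd.DataFrame(rows)
    summary = _with_se(detail, ["pattern", "rho"], ["auroc_standard", "auroc_mers"])
    averages = (
        detail.groupby("pattern", sort=False)[["auroc_standard", "auroc_mers"]]
        .mean()
        .reset_index()
    )
    return {"detail": detail, "summary": summary, "averages": averages}


def run_study2(config: StudyConfig) -> dict:
    """MSE/|bias| curves per condition plus EAP correlation table (Figs. 2-3)."""
    multi = config.engine("multi")
    curves: dict[tuple[str, float], ev.MseCurve] = {}
    corr_rows = []
    curve_rows = []
    for rep, pattern, rho, bank, learners, stream in _conditions(config, "accuracy"):
        theta_true = stream.theta_true
        _, traj = eng.replay_arrays(
            multi, stream.item_idx, stream.y.astype(float),
            bank.difficulties, bank.loadings,
        )
        curve = ev.mse_curve(traj, theta_true)
        if rep == 0:
            curves[(pattern, rho)] = curve
        for m in range(config.n_dims):
            for t_idx, t in enumerate(curve.occasions):
                curve_rows.append(
                    {
                        "replication": rep,
                        "pattern": pattern,
                        "rho": rho,
                        "dimension": m + 1,
                        "occasion": int(t),
                        "mse": curve.mse[m, t_idx],
                        "abs_bias": curve.abs_bias[m, t_idx],
                    }
                )
        # responses in bank order for the EAP benchmark
        y_bank = np.empty_like(stream.y)
        np.put_along_axis(y_bank, stream.item_idx, stream.y, axis=1)
        if config.eap_prior == "population":
            prior_mean = np.asarray(config.mu)
            prior_cov = pop.equicorrelation(rho, config.n_dims)
        else:
            prior_mean, prior_cov = None, None
        eap = ev.eap_estimate_batch(
            y_bank, bank, prior_mean, prior_cov, n_nodes=config.eap_nodes
        )
        final = traj[:, -1, :]
        r = ev.corr_vs_eap(final, eap)
        for m in range(config.n_dims):
            corr_rows.append(
                {
                    "replication": rep,
                    "pattern": pattern,
                    "rho": rho,
                    "dimension": m + 1,
                    "pearson_r": r[m],
                }
            )
    corr = pd.DataFrame(corr_rows)
    return {
        "curves": curves,
        "curve_table": pd.DataFrame(curve_rows),
        "correlations": corr,
        "correlations_summary": _with_se(
            corr, ["pattern", "rho", "dimension"], ["pearson_r"]
        ),
    }


def run_study3(config: StudyConfig) -> dict:
    """Accuracy-only vs speed-accuracy M-ERS: |bias| and MSE (Table-3 shape).

    Both engines consume the same HSHS stream (the accuracy engine sees its
    binary outcomes, the score engine its trade-off scores).  Metrics are
    reported averaged over all occasions and at the final occasion.
    """
    acc_engine = config.engine("multi", "accuracy")
    sa_engine = config.engine("multi", "hshs")
    rows = []
    for rep, pattern, rho, bank, _, stream in _conditions(config, "hshs"):
        theta_true = stream.theta_true
        for method, engine_cfg, outcomes in (
            ("accuracy", acc_engine, stream.y.astype(float)),
            ("speed-accuracy", sa_engine, stream.score),
        ):
            _, traj = eng.replay_arrays(
                engine_cfg, stream.item_idx, outcomes,
                bank.difficulties, bank.loadings,
            )
            curve = ev.mse_curve(traj, theta_true)
            bias_t = np.mean(traj - theta_true[:, None, :], axis=0).T  # (M, T)
            for m in range(config.n_dims):
                rows.append(
                    {
                        "replication": rep,
                        "pattern": pattern,
                        "rho": rho,
                        "dimension": m + 1,
                        "method": method,
                        "abs_bias": abs(bias_t[m].mean()),
                        "mse": curve.mse[m].mean(),
                        "abs_bias_final": curve.abs_bias[m, -1],
                        "mse_final": curve.mse[m, -1],
                    }
                )
    detail = pd.DataFrame(rows)
    summary = _with_se(
        detail,
        ["pattern", "dimension", "method", "rho"],
        ["abs_bias", "mse", "abs_bias_final", "mse_final"],
    )
    return {"detail": detail, "summary": summary}


def replay_log(
    log: pd.DataFrame, bank: ItemBank, config: eng.EngineConfig
) -> pd.DataFrame:
    """Re-score an interaction log through an engine, one event at a time.

    Streams each learner's events in occasion order through the
    single-interaction update API and returns the log with a fresh
    ``predicted`` column; replaying a logged session reproduces the logged
    predictions exactly.
    """
    id_to_item = {it.item_id: it for it in bank.items}
    out = log.sort_values(["learner_id", "occasion"]).copy()
    outcome_col = "score" if config.outcome == "hshs" else "y"
    preds = np.empty(len(out))
    pos = 0
    for learner_id, grp in out.groupby("learner_id", sort=False):
        state = eng.init_state(config, learner_id=int(learner_id))
        for _, row in grp.iterrows():
            item = id_to_item[int(row["item_id"])]
            preds[pos] = eng.predict(config, state, item)
            eng.update(config, state, item, float(row[outcome_col]))
            pos += 1
    out["predicted"] = preds
    return out
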