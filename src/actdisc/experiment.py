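"""Protocol runner and behavioural metrics.

An experiment consists of consecutive daily 15-min sessions: a habituation
phase (default 5 virtual days) in which block interactions have no
consequences, followed by a response-contingent phase (default 10 days) in
which bumps on the red block can trigger the light flash under the configured
schedule (VI or FR1).  State that represents learning — cortico-striatal
weights, the outcome-prediction model, the <y^2> trackers and the habituating
saliences — carries over between days; at each day boundary the intrinsic
salience of each block restarts from ``gamma_a`` times the previous day's
first-interaction value (overnight dishabituation).

Metrics follow the in-vivo conventions: completed interactions with the red
block are *active responses* (flash or not), with the white block *inactive
responses*.  ``r_peak`` is the ratio, rounded half-up to the nearest integer,
of the peak mean daily active-response count during response contingency to
the mean inactive count over that phase.  Within-day structure is summarized
by binning interactions into three 5-min epochs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from actdisc import network as nw
from actdisc.config import RunConfig, config_hash
from actdisc.engine import (EVENT_CAP, EV_BLOCK, EV_T, N_EV_COLS,
                            PS_SEEN_FIRST, PS_SINT_RED, PS_SINT_WHITE,
                            PS_Y_LATENT, N_PS, pack_params,
                            run_session_kernel)

EVENT_COLUMNS = (
    "t", "block", "flash", "y_star_pre", "y_latent_post", "s_nov", "s_int",
    "d_max", "d_min", "w_mot_d1", "w_mot_d2", "w_sen_d1", "w_sen_d2",
    "s_tot_red",
)


def session_seed(base_seed: int, run_index: int, day_index: int) -> int:
    """Deterministic, well-mixed per-session seed below 2**31."""
    ss = np.random.SeedSequence((base_seed, run_index, day_index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ReplicateState:
    """Learning state carried across the days of one replicate."""

    weights: nw.CorticoStriatalWeights
    ysq: np.ndarray
    ps: np.ndarray  # prediction/salience vector (engine layout)
    s_day_start: dict[str, float]

    @classmethod
    def fresh(cls, config: RunConfig) -> "ReplicateState":
        w = nw.CorticoStriatalWeights.initial(
            motor_value=config.network.motor_weight_init,
            lam=config.network.lam)
        ps = np.zeros(N_PS)
        ps[PS_SINT_RED] = config.prediction.s_init
        ps[PS_SINT_WHITE] = config.prediction.s_init
        return cls(weights=w, ysq=np.zeros((2, nw.N_CHANNELS)), ps=ps,
                   s_day_start={"red": config.prediction.s_init,
                                "white": config.prediction.s_init})


@dataclass
class SessionLog:
    """Events of one session plus the session-end weight snapshot."""

    day: int
    events: pd.DataFrame
    weights_end: np.ndarray  # (2, 2): rows D1/D2, cols motor/sensory (red)


def run_session(state: ReplicateState, config: RunConfig, day_index: int,
                seed: int, gains: np.ndarray | None = None,
                eps: np.ndarray | None = None) -> SessionLog:
    """Simulate one daily session, mutating the carried-over state."""
    c = config
    if gains is None:
        gains = nw.gains_from_overrides(c.network.gains)
    if eps is None:
        eps = nw.eps_from_overrides(c.network.eps)
    if day_index > 0:
        # overnight dishabituation from the previous day's first-interaction
        # value; the internal prediction model carries over unchanged
        for block, idx in (("red", PS_SINT_RED), ("white", PS_SINT_WHITE)):
            start = c.prediction.gamma_a * state.s_day_start[block]
            state.ps[idx] = start
            state.s_day_start[block] = start
    rc_phase = day_index >= c.protocol.days_habituation
    a = np.zeros((nw.N_POP, nw.N_CHANNELS))
    out_ev = np.zeros((EVENT_CAP, N_EV_COLS))
    n_ev = run_session_kernel(
        pack_params(c), gains, eps, a, state.weights.motor,
        state.weights.sensory, state.ysq, state.ps, seed, rc_phase,
        c.protocol.pda_enabled, c.protocol.schedule == "fr1", out_ev)
    if not (np.all(np.isfinite(state.weights.motor))
            and np.all(np.isfinite(a))):
        raise FloatingPointError(
            f"non-finite state in session day={day_index}; "
            "check network/plasticity parameterization")
    events = pd.DataFrame(out_ev[:n_ev], columns=list(EVENT_COLUMNS))
    events.insert(0, "day", day_index)
    w_end = np.column_stack((state.weights.motor[:, 1],
                             state.weights.sensory[:, 1]))
    return SessionLog(day=day_index, events=events, weights_end=w_end)


@dataclass
class ExperimentResults:
    """Aggregated outputs of a multi-day, multi-replicate experiment."""

    config: RunConfig
    responses: pd.DataFrame  # run, day, block, epoch, count
    events: pd.DataFrame     # per-interaction records with run/day/t_abs
    weights: pd.DataFrame    # time, run, receptor, source, channel, weight
    summary: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def r_peak(active_per_day: np.ndarray, inactive_per_day: np.ndarray):
    """Rounded (half-up) ratio of peak active count to mean inactive count
    over the response-contingent phase; None if no inactive responding."""
    active = np.asarray(active_per_day, dtype=float)
    inactive = np.asarray(inactive_per_day, dtype=float)
    denom = inactive.mean()
    if denom == 0:
        return None
    return int(math.floor(active.max() / denom + 0.5))


def epoch_counts(events: pd.DataFrame, epoch_length: float,
                 session_length: float) -> pd.DataFrame:
    """Interaction counts per (run, day, block, epoch); zero-filled."""
    n_epochs = int(round(session_length / epoch_length))
    ev = events.copy()
    ev["epoch"] = np.minimum((ev["t"] // epoch_length).astype(int),
                             n_epochs - 1)
    runs = sorted(ev["run"].unique()) if len(ev) else []
    days = sorted(ev["day"].unique()) if len(ev) else []
    full = pd.MultiIndex.from_product(
        [runs, days, [0.0, 1.0], range(n_epochs)],
        names=["run", "day", "block", "epoch"])
    counts = (ev.groupby(["run", "day", "block", "epoch"]).size()
              .reindex(full, fill_value=0).rename("count").reset_index())
    return counts


def run_experiment(config: RunConfig, progress=None) -> ExperimentResults:
    """Run ``n_runs`` independent replicates of the full protocol.

    Each replicate uses seeds derived from ``base_seed + run`` index; a
    replicate that fails numerically is recorded, and the aggregate requires
    at least 80% of replicates to succeed.
    """
    c = config
    gains = nw.gains_from_overrides(c.network.gains)
    eps = nw.eps_from_overrides(c.network.eps)
    n_days = c.protocol.days_habituation + c.protocol.days_response_contingent
    slen = c.protocol.session_length
    all_events = []
    weight_rows = []
    failures = []
    for run in range(c.protocol.n_runs):
        run_seed = c.protocol.base_seed + run
        state = ReplicateState.fresh(c)
        try:
            for day in range(n_days):
                log = run_session(state, c, day,
                                  session_seed(run_seed, run, day),
                                  gains=gains, eps=eps)
                ev = log.events
                ev.insert(0, "run", run)
                ev["t_abs"] = ev["day"] * slen + ev["t"]
                all_events.append(ev)
                t_end = (day + 1) * slen
                for r_i, receptor in enumerate(("D1", "D2")):
                    for s_i, source in enumerate(("motor", "sensory")):
                        weight_rows.append(
                            (t_end, run, receptor, source, "red",
                             log.weights_end[r_i, s_i]))
                if progress is not None:
                    progress(run, day)
        except FloatingPointError as exc:  # pragma: no cover - defensive
            failures.append((run, str(exc)))
    n_ok = c.protocol.n_runs - len(failures)
    if n_ok < 0.8 * c.protocol.n_runs:
        raise RuntimeError(
            f"only {n_ok}/{c.protocol.n_runs} replicates succeeded: "
            f"{failures}")
    events = (pd.concat(all_events, ignore_index=True) if all_events
              else pd.DataFrame(columns=["run", "day", *EVENT_COLUMNS,
                                         "t_abs"]))
    responses = epoch_counts(events, c.protocol.epoch_length, slen)
    weights = pd.DataFrame(
        weight_rows,
        columns=["time", "run", "receptor", "source", "channel", "weight"])
    results = ExperimentResults(config=c, responses=responses, events=events,
                                weights=weights, failures=failures)
    results.summary = summarize(results)
    return results


def daily_counts(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean daily count per (day, block) across runs."""
    per_run = responses.groupby(["run", "day", "block"])["count"].sum()
    return per_run.groupby(["day", "block"]).mean().rename("count").reset_index()


def summarize(results: ExperimentResults) -> dict:
    """Headline quantities: r_peak, peak day, phase means, epoch profile."""
    c = results.config
    h = c.protocol.days_habituation
    daily = daily_counts(results.responses)
    rc = daily[daily["day"] >= h]
    active = rc[rc["block"] == 0.0].set_index("day")["count"]
    inactive = rc[rc["block"] == 1.0].set_index("day")["count"]
    rp = None
    peak_day_rel = None
    if len(active):
        rp = r_peak(active.to_numpy(), inactive.to_numpy())
        peak_day_rel = int(active.idxmax() - h + 1)  # 1 = first RC day
    rc_resp = results.responses[results.responses["day"] >= h]
    epoch_profile = (rc_resp[rc_resp["block"] == 0.0]
                     .groupby("epoch")["count"].mean())
    hab = daily[daily["day"] < h]
    return {
        "schedule": c.protocol.schedule,
        "pda_enabled": c.protocol.pda_enabled,
        "n_runs": c.protocol.n_runs,
        "r_peak": rp,
        "peak_active_day_in_rc": peak_day_rel,
        "rc_active_mean_per_day": float(active.mean()) if len(active) else None,
        "rc_inactive_mean_per_day": (float(inactive.mean())
                                     if len(inactive) else None),
        "rc_active_peak": float(active.max()) if len(active) else None,
        "hab_active_mean_per_day": float(
            hab[hab["block"] == 0.0]["count"].mean()) if len(hab) else None,
        "hab_inactive_mean_per_day": float(
            hab[hab["block"] == 1.0]["count"].mean()) if len(hab) else None,
        "rc_epoch_profile_active": [float(v) for v in epoch_profile],
        "n_flashes": int(results.events["flash"].sum()) if len(results.events) else 0,
    }


def write_outputs(results: ExperimentResults, outdir: str | Path) -> None:
    """Write responses.csv, weights.csv, events.csv and summary.json.

    Every file carries the config hash and base seed in a header line (CSV
    comment) or metadata field (JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = (f"# config_hash={config_hash(results.config)} "
            f"base_seed={results.config.protocol.base_seed}\n")
    for name, df in (("responses", results.responses),
                     ("weights", results.weights),
                     ("events", results.events)):
        path = outdir / f"{name}.csv"
        with open(path, "w", newline="") as f:
            f.write(meta)
            df.to_csv(f, index=False)
    payload = {"config_hash": config_hash(results.config),
               "base_seed": results.config.protocol.base_seed,
               "summary": results.summary,
               "failures": results.failures}
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
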