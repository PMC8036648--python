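"""Full fixture-directory generation for pipeline runs.

Writes the same CSV schemas the processing stages read: one PPG CSV
per duty-cycle session under ``ppg/<participant>/``, one actigraphy
CSV per participant, cohort daily records plus metadata, and a
``truth.json`` with the generating parameters and per-session ground
truth so recovery can be measured end to end.

An optional anomalous episode re-parameterizes the PPG generator
(higher heart rate, stronger LF modulation — the stress direction)
for a contiguous block of days, leaving everything else unchanged.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as pio
from .schedule import SchedulePlan, daily_schedule
from .synthetic import ActigraphySimConfig, Modulation, PpgSimConfig, simulate_actigraphy, simulate_cohort, simulate_session, CohortSimConfig

__all__ = ["write_fixture"]


def write_fixture(
    out_dir: str | Path,
    n_participants: int = 1,
    n_days: int = 7,
    plan: SchedulePlan = SchedulePlan(),
    ppg_cfg: PpgSimConfig = PpgSimConfig(),
    act_cfg: ActigraphySimConfig = ActigraphySimConfig(),
    cohort_cfg: CohortSimConfig | None = None,
    anomaly_days: tuple[int, int] | None = None,
    anomaly_hr_delta: float = 15.0,
    anomaly_lf_amp: float = 55.0,
    seed: int = 0,
) -> dict:
    """Generate and write a complete fixture directory; returns the truth.

    ``anomaly_days=(lo, hi)`` marks days ``lo <= d < hi`` as an
    anomalous episode: sessions on those days are generated with
    ``mean_hr + anomaly_hr_delta`` and LF amplitude ``anomaly_lf_amp``.
    Per-session seeds derive from ``seed`` so the whole fixture is
    reproducible from one integer.
    """
    out = Path(out_dir)
    (out / "ppg").mkdir(parents=True, exist_ok=True)
    (out / "actigraphy").mkdir(exist_ok=True)
    starts, _ = daily_schedule(plan)
    session_s = plan.session_min * 60.0
    truth: dict = {
        "plan_interval_min": plan.interval_min,
        "anomaly_days": list(anomaly_days) if anomaly_days else None,
        "sessions": {},
        "participants": [],
    }
    rng = np.random.default_rng(seed)
    for p in range(n_participants):
        pid = f"P{p:03d}"
        truth["participants"].append(pid)
        pdir = out / "ppg" / pid
        pdir.mkdir(exist_ok=True)
        for day in range(n_days):
            anomalous = anomaly_days is not None and anomaly_days[0] <= day < anomaly_days[1]
            for s_min in starts:
                slot = int(day * 1440 + s_min)
                sess_seed = int(rng.integers(0, 2**31 - 1))
                cfg = replace(ppg_cfg, seed=sess_seed)
                if anomalous:
                    cfg = replace(
                        cfg,
                        mean_hr=ppg_cfg.mean_hr + anomaly_hr_delta,
                        lf_mod=Modulation(ppg_cfg.lf_mod.freq_hz, anomaly_lf_amp),
                    )
                ts_ms, x, bt = simulate_session(cfg, session_s)
                pio.write_ppg_csv(pdir / f"session_{slot}.csv", ts_ms, x)
                truth["sessions"][f"{pid}/{slot}"] = {
                    "anomalous": anomalous,
                    "mean_hr": 60000.0 / float(np.mean(bt.ibis_ms)),
                    "avnn_ms": float(np.mean(bt.ibis_ms)),
                    "sdnn_ms": bt.sdnn_ms,
                    "rmssd_ms": bt.rmssd_ms,
                    "lf_hf_analytic": (
                        (cfg.lf_mod.amp_ms**2) / (cfg.hf_mod.amp_ms**2)
                        if cfg.hf_mod.amp_ms > 0
                        else None
                    ),
                }
        a_cfg = replace(act_cfg, seed=int(rng.integers(0, 2**31 - 1)))
        epochs, a_truth = simulate_actigraphy(a_cfg, n_days)
        pio.write_activity_csv(out / "actigraphy" / f"{pid}.csv", epochs)
        truth[f"actigraphy_{pid}"] = {
            "tst_min": a_truth.tst_min,
            "waso_min": a_truth.waso_min,
            "wear_h": float(a_truth.wear_h[0]),
        }
    if cohort_cfg is not None:
        rec, meta, c_truth = simulate_cohort(cohort_cfg)
        rec.to_csv(out / "cohort.csv", index=False)
        meta.to_csv(out / "meta.csv", index=False)
        truth["cohort"] = c_truth
    pio.write_json(out / "truth.json", truth)
    return truth
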