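"""End-to-end analysis runner for the vesicular-pH calibration pipeline.

Ingests a calibration trace table plus a stimulus schedule, applies the
responder gates, measures gamma and epsilon, solves each punctum for
(pH, SF), and writes per-punctum and per-genotype summary tables plus a
run log recording every exclusion with its rule and every constant used.

Trace naming convention: each punctum contributes two recordings,
``<punctum>_nh4cl`` and ``<punctum>_mes``; optional background traces
are named ``background_nh4cl`` / ``background_mes`` (one per recording
type, shared across puncta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import vesicle_ph as vp
from .io import read_schedule, read_trace_table, write_results
from .traces import (
    TimeSeriesTrace,
    WindowSpec,
    above_background_gate,
    classify_responder,
    delta_f_over_f,
)

__all__ = ["PipelineConfig", "run_ph_pipeline"]

log = logging.getLogger("synphys.pipeline")

DEFAULT_SCHEDULE = {
    "baseline": WindowSpec(0.0, 10.0),
    "kcl": WindowSpec(10.0, 20.0),
    "nh4cl": WindowSpec(20.0, 60.0),
    "mes": WindowSpec(20.0, 80.0),
}


@dataclass
class PipelineConfig:
    traces_path: str
    outdir: str
    schedule_path: str | None = None
    constants: vp.Constants = field(default_factory=vp.Constants)
    responder_filter_width: float = 1.0  # s; gating filter
    measure_filter_width: float = 5.0  # s; gamma/epsilon measurement filter
    k_sd: float = 3.0


def _gate(
    trace: TimeSeriesTrace,
    background: TimeSeriesTrace | None,
    baseline: WindowSpec,
    response: WindowSpec,
    direction: str,
    cfg: PipelineConfig,
) -> tuple[bool, str]:
    """Background gate + responder gate; returns (passed, reason)."""
    above = True
    if background is not None and trace.F is not None:
        above = above_background_gate(trace, background, baseline, cfg.k_sd)
    call = classify_responder(
        trace, baseline, response, cfg.responder_filter_width,
        cfg.k_sd, direction, above_background=above,
    )
    return call.responder, call.reason


def run_ph_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the calibration analysis; returns the result tables it writes."""
    c = config.constants
    log.info("constants: pK=%.4g pH_external=%.4g pH_acid=%.4g pH_floor=%.4g",
             c.pK, c.pH_external, c.pH_acid, c.pH_floor)
    log.info("note: pK=%.4g used for all equations including the exocytosis "
             "correction factor; track-QC speed threshold reading: mean track speed",
             c.pK)

    schedule = dict(DEFAULT_SCHEDULE)
    if config.schedule_path:
        schedule.update(read_schedule(config.schedule_path))
        log.info("schedule overridden from %s", config.schedule_path)
    baseline = schedule["baseline"]

    traces = read_trace_table(config.traces_path)
    by_id = {tr.trace_id: tr for tr in traces}
    bg_nh4 = by_id.get("background_nh4cl")
    bg_mes = by_id.get("background_mes")

    puncta = sorted(
        {tid[: -len("_nh4cl")] for tid in by_id if tid.endswith("_nh4cl")
         and not tid.startswith("background")}
    )

    rows = []
    solutions_by_genotype: dict[str, list[vp.PHSolution]] = {}
    for pid in puncta:
        nh4 = by_id.get(f"{pid}_nh4cl")
        mes = by_id.get(f"{pid}_mes")
        if nh4 is None or mes is None:
            log.warning("punctum %s: missing paired recording; skipped", pid)
            continue
        if nh4.dff is None:
            nh4 = delta_f_over_f(nh4, baseline)
        if mes.dff is None:
            mes = delta_f_over_f(mes, baseline)

        nh4_ok, nh4_reason = _gate(nh4, bg_nh4, baseline, schedule["nh4cl"],
                                   "increase", config)
        mes_ok, mes_reason = _gate(mes, bg_mes, baseline, schedule["mes"],
                                   "decrease", config)
        row = {"punctum_id": pid, "genotype": nh4.genotype,
               "nh4_responder": nh4_ok, "mes_responder": mes_ok,
               "gamma": float("nan"), "epsilon": float("nan"),
               "pH": float("nan"), "SF": float("nan"),
               "converged": False, "excluded": True, "reason": ""}
        if not (nh4_ok and mes_ok):
            reason = nh4_reason if not nh4_ok else mes_reason
            row["reason"] = f"gate:{reason}"
            log.info("punctum %s excluded by responder gate (%s)", pid, row["reason"])
            rows.append(row)
            continue

        gamma = vp.measure_gamma(nh4, schedule["nh4cl"], config.measure_filter_width)
        epsilon = vp.measure_epsilon(mes, schedule["mes"], config.measure_filter_width)
        sol = vp.solve_ph_sf(gamma, epsilon, c, punctum_id=pid)
        row.update(gamma=gamma, epsilon=epsilon, pH=sol.pH, SF=sol.SF,
                   converged=sol.converged, excluded=sol.excluded,
                   reason=sol.reason)
        if sol.excluded or not sol.converged:
            log.info("punctum %s excluded by solver (%s)", pid, sol.reason)
        else:
            solutions_by_genotype.setdefault(nh4.genotype, []).append(sol)
        rows.append(row)

    per_punctum = pd.DataFrame(rows)
    summary_rows = []
    for genotype, sols in sorted(solutions_by_genotype.items()):
        mean_ph, mean_sf, n, sd_ph, sd_sf = vp.summarize_genotype(sols)
        summary_rows.append({"genotype": genotype, "mean_pH": mean_ph,
                             "mean_SF": mean_sf, "n": n,
                             "sd_pH": sd_ph, "sd_SF": sd_sf})
        log.info("genotype %s: mean pH %.3f, mean SF %.3f (n=%d)",
                 genotype, mean_ph, mean_sf, n)
    summary = pd.DataFrame(summary_rows)

    tables = {"puncta": per_punctum, "genotype_summary": summary}
    write_results(tables, config.outdir)
    log_path = Path(config.outdir) / "run_log.txt"
    n_total = len(per_punctum)
    n_excluded = int(per_punctum["excluded"].sum()) if n_total else 0
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(f"pK = {c.pK}\npH_external = {c.pH_external}\n"
                 f"pH_acid = {c.pH_acid}\npH_floor = {c.pH_floor}\n"
                 f"excluded {n_excluded} (of {n_total}) puncta\n")
        if n_total:
            for _, r in per_punctum[per_punctum["excluded"]].iterrows():
                fh.write(f"excluded punctum {r['punctum_id']}: {r['reason']}\n")
    return tables
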