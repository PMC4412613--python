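"""Reproducible simulate -> analyze -> report runs.

A :class:`RunConfig` (YAML) names a set of recording conditions (gating
model + voltage + duration), analysis parameters, and optional
electrochemistry/chelation tables.  :func:`run_pipeline` simulates each
condition with a seed derived from the run seed by a fixed offset, analyses
the traces, and writes every intermediate artifact (traces, histograms,
mixture fits) plus a machine-readable ``report.json``.  Re-running with the
same config and seed reproduces the report byte-identically; timings and
progress go to ``run.log``, never into the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chelation import solve_equilibrium
from .electrochem import (
    fit_permeability_ratio,
    henderson_junction_potential,
    nernst_potential,
)
from .errors import ConfigurationError
from .gating import (
    DEFAULT_NOISE_SD_PA,
    GatingModel,
    simulate_constant_voltage,
)
from .single_channel import analyze_trace
from .solutions import SolutionSpec, egta_buffered_bath
from .traceio import write_trace

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("vactrace.pipeline")

_CONDITION_SEED_OFFSET = 1000  # fixed per-condition seed spacing


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see examples/demo_run.yaml)."""

    seed: int
    conditions: tuple[dict, ...] = ()
    analysis: dict = field(default_factory=dict)
    electrochem: dict | None = None
    chelation: tuple[dict, ...] = ()
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ConfigurationError("config must set a seed")
        conditions = tuple(d.get("conditions", []))
        for c in conditions:
            for key in ("name", "gating", "voltage_mV", "duration_s"):
                if key not in c:
                    raise ConfigurationError(f"condition missing {key!r}: {c}")
            g = c["gating"]
            if "po" not in g and "open_rate_s" not in g:
                raise ConfigurationError(
                    f"condition {c['name']!r}: gating needs 'po' or 'open_rate_s'"
                )
        return cls(
            seed=int(d["seed"]),
            conditions=conditions,
            analysis=dict(d.get("analysis", {})),
            electrochem=d.get("electrochem"),
            chelation=tuple(d.get("chelation", [])),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def effective_analysis(self) -> dict:
        """Analysis parameters with all defaults made explicit."""
        out = {"bin_width_pA": 0.1, "max_channels": 4,
               "sampling_rate_hz": 10_000.0, "filter_hz": 2_000.0}
        out.update(self.analysis)
        return out


@dataclass(frozen=True)
class RunReport:
    """Machine-readable results of one pipeline run."""

    provenance: dict
    conditions: dict
    electrochem: dict | None
    chelation: list

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "conditions": self.conditions,
            "electrochem": self.electrochem,
            "chelation": self.chelation,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _gating_from_config(g: dict) -> GatingModel:
    kw = dict(
        n_channels=int(g.get("n_channels", 1)),
        unitary_conductance_pS=float(g.get("unitary_conductance_pS", 95.5)),
        reversal_mV=float(g.get("reversal_mV", 0.0)),
    )
    if g.get("v_half_mV") is not None:
        kw["v_half_mV"] = float(g["v_half_mV"])
        kw["slope_mV"] = float(g["slope_mV"])
    if "po" in g:
        return GatingModel.from_open_probability(
            float(g["po"]), close_rate_s=float(g.get("close_rate_s", 50.0)), **kw)
    return GatingModel(open_rate_s=float(g["open_rate_s"]),
                       close_rate_s=float(g["close_rate_s"]), **kw)


def _solution_from_config(entry) -> SolutionSpec:
    if isinstance(entry, str):
        return SolutionSpec.from_yaml(Path(entry).read_text())
    return SolutionSpec.from_dict(entry)


def _round(x, nd=9):
    return None if x is None else round(float(x), nd)


def run_pipeline(config: RunConfig, out_dir) -> RunReport:
    """Execute the full simulate/analyze/report chain; returns the report.

    All artifacts are written under ``out_dir``.  Any stage error is
    re-raised annotated with the stage name; artifacts written so far are
    retained for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t_start = time.perf_counter()
    analysis = config.effective_analysis()
    log.info("run start: config_hash=%s seed=%d version=%s",
             config.config_hash, config.seed, __version__)

    stage = "init"
    try:
        cond_results = {}
        for idx, cond in enumerate(config.conditions):
            stage = f"condition:{cond['name']}"
            t0 = time.perf_counter()
            model = _gating_from_config(cond["gating"])
            seed = config.seed + _CONDITION_SEED_OFFSET * idx
            trace = simulate_constant_voltage(
                model,
                voltage_mV=float(cond["voltage_mV"]),
                duration_s=float(cond["duration_s"]),
                noise_sd_pA=float(cond.get("noise_sd_pA", DEFAULT_NOISE_SD_PA)),
                seed=seed,
                sampling_rate_hz=analysis["sampling_rate_hz"],
                filter_hz=analysis["filter_hz"],
            )
            write_trace(out / f"trace_{cond['name']}.csv", trace)
            res = analyze_trace(trace, bin_width_pA=analysis["bin_width_pA"],
                                max_channels=int(analysis["max_channels"]))
            hist_path = out / f"hist_{cond['name']}.csv"
            with hist_path.open("w") as fh:
                fh.write("bin_centre_pA,count\n")
                for c, n in zip(res.histogram.bin_centres_pA, res.histogram.counts):
                    fh.write(f"{c:.10g},{n}\n")
            mix_json = {
                "peaks": [{"centre_pA": p.centre_pA, "sd_pA": p.sd_pA,
                           "area": p.area} for p in res.mixture.peaks],
                "n_channels": res.n_channels,
                "open_probability": res.open_probability,
                "unitary_current_pA": res.unitary_current_pA,
                "conductance_pS": res.conductance_pS,
            }
            (out / f"fit_{cond['name']}.json").write_text(
                json.dumps(mix_json, indent=2, sort_keys=True))
            cond_results[cond["name"]] = {
                "voltage_mV": float(cond["voltage_mV"]),
                "n_channels": res.n_channels,
                "open_probability": _round(res.open_probability, 6),
                "unitary_current_pA": _round(res.unitary_current_pA, 6),
                "conductance_pS": _round(res.conductance_pS, 6),
                "true_po": _round(model.stationary_po(float(cond["voltage_mV"])), 6),
                "seed": seed,
            }
            log.info("%s done in %.2f s", stage, time.perf_counter() - t0)

        stage = "electrochem"
        ec_table = None
        if config.electrochem:
            t0 = time.perf_counter()
            cyt = _solution_from_config(config.electrochem["cytoplasmic"])
            vac = _solution_from_config(config.electrochem["vacuolar"])
            ec_table = {"cytoplasmic": cyt.label, "vacuolar": vac.label,
                        "nernst_mV": {}, }
            for ion in config.electrochem.get("nernst_ions", []):
                ec_table["nernst_mV"][ion] = _round(nernst_potential(ion, cyt, vac), 4)
            pr = config.electrochem.get("permeability")
            if pr:
                res = fit_permeability_ratio(
                    float(pr["measured_e_rev_mV"]), pr["test_ion"],
                    pr["reference_ion"], cyt, vac)
                ec_table["permeability_ratio"] = {
                    "test_ion": pr["test_ion"], "reference_ion": pr["reference_ion"],
                    "e_rev_mV": float(pr["measured_e_rev_mV"]),
                    "ratio": _round(res.permeability_ratio, 4),
                }
            if config.electrochem.get("junction_potential"):
                ec_table["junction_potential_mV"] = _round(
                    henderson_junction_potential(vac, cyt), 4)
            log.info("electrochem done in %.2f s", time.perf_counter() - t0)

        stage = "chelation"
        chel_table = []
        for recipe in config.chelation:
            t0 = time.perf_counter()
            kw = {k: v for k, v in recipe.items() if k != "label"}
            sol = egta_buffered_bath(**kw)
            st = solve_equilibrium(sol)
            chel_table.append({
                "label": recipe.get("label", sol.label),
                "free_Ca_uM": _round(st.free_ca_uM, 6),
                "free_Mg_mM": _round(st.free_mg_mM, 6),
                "ionic_strength_M": _round(st.ionic_strength_M, 6),
            })
            log.info("chelation %s done in %.2f s", recipe.get("label", "?"),
                     time.perf_counter() - t0)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}").with_traceback(
            exc.__traceback__) from None
    finally:
        log.removeHandler(handler)
        handler.close()

    report = RunReport(
        provenance={"config_hash": config.config_hash, "seed": config.seed,
                    "vactrace_version": __version__,
                    "analysis": analysis},
        conditions=cond_results,
        electrochem=ec_table,
        chelation=chel_table,
    )
    (out / "report.json").write_text(report.to_json())
    logging.getLogger("vactrace.pipeline").info(
        "run finished in %.2f s", time.perf_counter() - t_start)
    return report
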