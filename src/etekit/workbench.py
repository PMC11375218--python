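"""High-level workflows, run configuration and result serialization.

Ties the stages into the two top-level analyses: converting measured
escape-time tables into effective charges via a device calibration, and the
model-based comparison computing q_calc for rods and structures. Every
workflow writes a manifest (inputs, parameters, seeds, output hashes) that
suffices to reproduce the run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import effective_charge as ec
from . import escape_time as et
from . import rod_inference as ri
from .pb_core import Electrolyte, SlitDevice, SolverOptions
from .synthetic_data import generate_device_fixture

log = logging.getLogger("etekit")

__all__ = ["RunConfig", "write_manifest", "result_to_json",
           "run_fit_escape", "run_calibrate", "run_infer_qeff", "run_rod_curve"]


@dataclass
class RunConfig:
    """Declarative description of a run.

    Either a named device fixture or explicit geometry/electrolyte values;
    the species panel maps labels to (q_str, dye count, r_H).
    """

    device_fixture: Optional[str] = None
    half_height: Optional[float] = None
    pocket_depth: Optional[float] = None
    phi_s: Optional[float] = None
    c0: Optional[float] = None
    seed: int = 0
    n_excluded_lags: int = 2
    species: dict = field(default_factory=dict)
    outdir: str = "."

    def build(self):
        if self.device_fixture:
            dev, elec, _ = generate_device_fixture(self.device_fixture)
        else:
            dev = SlitDevice(half_height=self.half_height,
                             pocket_depth=self.pocket_depth, phi_s=self.phi_s)
            elec = Electrolyte.monovalent(self.c0)
        return dev, elec

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str, stage: str, params: dict, outputs: list[str]):
    """JSON manifest listing the stage, parameters, seeds and output hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": params,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def result_to_json(result, path: str):
    """Serialize an EffectiveChargeResult / EscapeFit / Calibration to JSON."""
    if hasattr(result, "to_dict"):
        data = result.to_dict()
    else:
        data = asdict(result)
        data = {k: v for k, v in data.items()
                if isinstance(v, (int, float, str, bool, type(None), dict, list))}
    Path(path).write_text(json.dumps(data, indent=2, default=float))


def run_fit_escape(events_path: str, n_excluded_lags: int, outdir: str):
    events = et.EscapeEventTable.read(events_path)
    fit = et.fit_escape_time(events, n_excluded_lags=n_excluded_lags)
    out = Path(outdir) / "escape_fit.json"
    Path(outdir).mkdir(parents=True, exist_ok=True)
    result_to_json(fit, out)
    log.info("fit t_esc = %.3f +- %.3f ms (N = %d)", fit.t_esc, fit.stderr,
             fit.n_events)
    write_manifest(outdir, "fit-escape",
                   {"events": events_path, "n_excluded_lags": n_excluded_lags},
                   [str(out)])
    return fit


def run_calibrate(events_path: str, q_eff_cal: float, fixture: str,
                  r_h: float, outdir: str):
    dev, elec, _ = generate_device_fixture(fixture)
    events = et.EscapeEventTable.read(events_path)
    fit = et.fit_escape_time(events)
    trap = et.TrapModel(r_h=r_h, dF_trans=et.confinement_entropy(dev, r_h))
    cal = et.calibrate_surface_potential(q_eff_cal, fit, dev, elec, trap)
    Path(outdir).mkdir(parents=True, exist_ok=True)
    out = Path(outdir) / "calibration.json"
    out.write_text(json.dumps({
        "phi_s": cal.phi_s, "phi_m": cal.phi_m,
        "calibrator_q_eff": cal.calibrator_q_eff,
        "calibrator_t_esc": cal.calibrator_t_esc,
        "fixture": fixture, "r_h": r_h}, indent=2))
    write_manifest(outdir, "calibrate",
                   {"events": events_path, "q_eff_cal": q_eff_cal,
                    "fixture": fixture, "r_h": r_h}, [str(out)])
    return cal


def run_infer_qeff(events_path: str, calibration_path: str, r_h: float,
                   outdir: str):
    cal_data = json.loads(Path(calibration_path).read_text())
    dev, elec, _ = generate_device_fixture(cal_data["fixture"])
    trap = et.TrapModel(r_h=r_h, dF_trans=et.confinement_entropy(dev, r_h))
    cal = et.Calibration(phi_s=cal_data["phi_s"], phi_m=cal_data["phi_m"],
                         calibrator_q_eff=cal_data["calibrator_q_eff"],
                         calibrator_t_esc=cal_data["calibrator_t_esc"],
                         trap=trap, device=dev, electrolyte=elec)
    events = et.EscapeEventTable.read(events_path)
    fit = et.fit_escape_time(events)
    q, dq = et.infer_qeff(fit, cal, trap)
    Path(outdir).mkdir(parents=True, exist_ok=True)
    out = Path(outdir) / "qeff.json"
    out.write_text(json.dumps({"q_eff": q, "q_eff_err": dq,
                               "t_esc": fit.t_esc, "species": events.species},
                              indent=2))
    write_manifest(outdir, "infer-qeff",
                   {"events": events_path, "calibration": calibration_path},
                   [str(out)])
    return q, dq


def run_half_helix_panel(n_bs=(5, 8, 9, 11, 12), fixture: str = "fig1_device",
                         options: SolverOptions | None = None):
    """Effective charges of ideal half-helix models for the short-fragment panel.

    Builds the bead half-helix for each chain length, solves the nonlinear
    PB equation in bulk at the fixture's salt concentration, matches the far
    field, and adds the configured dye offsets (one dye at n_b = 5, two
    otherwise). Returns a DataFrame with core and total charges, eta, the
    published measured values and the percent deviation.
    """
    import pandas as pd

    from .molecular_models import build_half_helix
    from .reference_data import SHORT_PANEL_DYES, SHORT_PANEL_QEFF

    _, elec, _ = generate_device_fixture(fixture)
    options = options or SolverOptions(padding_debye=6.0)
    rows = []
    for n_b in n_bs:
        hh = build_half_helix(n_b)
        res = ec.solve_and_match(hh, elec, options)
        dye = ec.DyeSpec(SHORT_PANEL_DYES.get(n_b, 2))
        tot = ec.add_dye_effective_charge(res, dye)
        meas = SHORT_PANEL_QEFF.get(n_b)
        dev = (abs(tot.q_calc) - meas) / meas * 100.0 if meas else None
        rows.append({"n_b": n_b, "q_core_e": res.q_calc, "eta_core": res.eta,
                     "q_total_e": tot.q_calc, "measured_qeff_e": meas,
                     "pct_dev": dev})
        log.info("half-helix n_b=%d: q_core %.2f e, total %.2f e, measured %s",
                 n_b, res.q_calc, tot.q_calc, meas)
    return pd.DataFrame(rows)


def run_rod_curve(radius: float, n_b: int, fixture: str, outdir: str,
                  options: SolverOptions | None = None):
    _, elec, _ = generate_device_fixture(fixture)
    curve = ri.compute_qcalc_vs_b(radius, n_b, elec, options=options)
    Path(outdir).mkdir(parents=True, exist_ok=True)
    out = Path(outdir) / f"rod_curve_r{radius}.tsv"
    arr = np.column_stack([curve.b, curve.q_abs])
    np.savetxt(out, arr, delimiter="\t", header="b_nm\tq_abs_e")
    fitout = Path(outdir) / f"rod_fit_r{radius}.json"
    fitout.write_text(json.dumps({"slope": curve.fit.slope,
                                  "intercept": curve.fit.intercept,
                                  "r_squared": curve.fit.r_squared}, indent=2))
    log.info("rod curve r=%g: slope %.2f e/nm intercept %.2f e",
             radius, curve.fit.slope, curve.fit.intercept)
    write_manifest(outdir, "rod-curve",
                   {"radius": radius, "n_b": n_b, "fixture": fixture},
                   [str(out), str(fitout)])
    return curve
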