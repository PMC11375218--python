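"""Escape-time statistics, the trap model, and effective-charge inference.

A molecule in an electrostatic fluidic trap escapes after an exponentially
distributed residence time whose mean follows Kramers' relation,
t_esc ~ exp(W/kBT), with the well depth W the sum of the electrostatic
free-energy difference between slit and pocket, dF_el = q_eff * phi_m, and
an entropic confinement term dF_trans. The mapping between W and t_esc used
here is the exact mean first-passage time of an overdamped particle in a
radially symmetric well (flat bottom of depth W, a narrow linear rim ramp,
an absorbing circle beyond the rim); Brownian-dynamics simulation of the
same landscape validates the quadrature. A calibration species of known
effective charge fixes the device surface potential phi_s, after which
measured escape times invert to effective charges.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import BOLTZMANN, WATER_VISCOSITY
from .pb_core import Electrolyte, SlitDevice

__all__ = [
    "EscapeEventTable", "EscapeFit", "TrapModel", "Calibration",
    "fit_escape_time", "kramers_ratio", "bd_escape_simulate",
    "calibrate_surface_potential", "infer_qeff", "stokes_einstein_diffusivity",
]


def stokes_einstein_diffusivity(r_h: float, temperature: float = 298.15) -> float:
    """Diffusion coefficient of a sphere of hydrodynamic radius r_h (nm),
    in nm^2/ms."""
    d_m2s = BOLTZMANN * temperature / (6 * math.pi * WATER_VISCOSITY * r_h * 1e-9)
    return d_m2s * 1e18 / 1e3


@dataclass
class EscapeEventTable:
    """Per-event residence durations (ms) with acquisition metadata."""

    dt: np.ndarray
    frame_interval: float = 0.0   # ms; 0 means continuous-time durations
    exposure: float = 0.0         # ms
    species: str = ""
    device_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dt = np.asarray(self.dt, float)
        if not np.all(np.isfinite(self.dt)):
            raise ValueError("event durations must be finite")
        if self.frame_interval > 0 and np.any(self.dt < self.frame_interval - 1e-9):
            raise ValueError("durations shorter than the frame interval")

    @property
    def n_events(self) -> int:
        return len(self.dt)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"dt_ms": self.dt,
                             "frame_ms": self.frame_interval,
                             "species": self.species,
                             "device": self.device_id})

    def write(self, path: str):
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str) -> "EscapeEventTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(dt=df["dt_ms"].to_numpy(),
                   frame_interval=float(df["frame_ms"].iloc[0]) if len(df) else 0.0,
                   species=str(df["species"].iloc[0]) if len(df) else "",
                   device_id=str(df["device"].iloc[0]) if len(df) else "")


@dataclass(frozen=True)
class EscapeFit:
    t_esc: float          # ms
    stderr: float         # ms, ~ t_esc/sqrt(N)
    n_events: int
    n_excluded_lags: int
    species: str = ""


def fit_escape_time(events: EscapeEventTable, n_excluded_lags: int = 2,
                    truncation: Optional[float] = None) -> EscapeFit:
    """Maximum-likelihood mean escape time from an exponential residence-time
    distribution, excluding the shortest lag bins.

    The first ``n_excluded_lags`` discrete lag bins are dropped because the
    shortest events carry contributions from transiently trapped weakly
    charged contaminants. For frame-discretized data the estimator is the
    exact geometric-distribution MLE of the surviving tail, which by
    memorylessness is unbiased for the underlying exponential mean; for
    continuous data it reduces to the truncated-exponential MLE,
    mean(dt - T0). The standard error is t_esc/sqrt(N).
    """
    dt = events.dt
    if events.frame_interval > 0:
        f = events.frame_interval
        k = np.rint(dt / f).astype(int)
        k0 = n_excluded_lags
        j = k[k > k0] - k0
        if len(j) < 100:
            raise ValueError("need at least 100 events after lag exclusion")
        if np.all(j == j[0]):
            raise ValueError("all events in a single lag bin; cannot fit")
        mean_j = j.mean()
        theta = 1.0 - 1.0 / mean_j          # P(j) = (1-theta) theta^(j-1)
        t_esc = -f / math.log(theta)
    else:
        t0 = truncation if truncation is not None else 0.0
        kept = dt[dt > t0]
        if len(kept) < 100:
            raise ValueError("need at least 100 events after lag exclusion")
        if np.ptp(kept) < 1e-12:
            raise ValueError("all events at one value; cannot fit")
        t_esc = float(np.mean(kept - t0))
    n = int((dt > 0).sum())
    n_kept = len(j) if events.frame_interval > 0 else len(kept)
    return EscapeFit(t_esc=float(t_esc), stderr=float(t_esc / math.sqrt(n_kept)),
                     n_events=n_kept, n_excluded_lags=n_excluded_lags,
                     species=events.species)


def kramers_ratio(w1: float, w2: float) -> float:
    """Ratio of mean escape times for wells of depth w1 and w2 (kBT)."""
    return math.exp(w1 - w2)


@dataclass(frozen=True)
class TrapModel:
    """Radially symmetric in-plane trap landscape and its escape-time map.

    The free energy is U(rho) = -W for rho < a - delta, rises linearly to 0
    at the rim rho = a, and is flat beyond; escapes are scored on an
    absorbing circle at ``absorb_radius`` (default 2a), far enough outside
    the rim that the Kramers prefactor is depth-independent.

    pocket_radius a and rim width come from the device geometry (the rim
    width is of the order of the Debye length, small against a); r_h sets
    the diffusivity via Stokes-Einstein.
    """

    pocket_radius: float = 300.0      # nm
    rim_width: float = 15.0           # nm, of order the Debye length
    r_h: float = 3.0                  # nm
    absorb_radius: Optional[float] = None
    temperature: float = 298.15
    dF_trans: float = 0.0             # kBT, entropic well-depth component

    def __post_init__(self):
        if self.absorb_radius is None:
            # score escapes midway to the neighbouring trap of the lattice
            object.__setattr__(self, "absorb_radius", 1.5 * self.pocket_radius)

    @property
    def diffusivity(self) -> float:
        """nm^2/ms."""
        return stokes_einstein_diffusivity(self.r_h, self.temperature)

    def potential(self, rho, depth: float):
        """U(rho) in kBT for well depth ``depth``."""
        a, d = self.pocket_radius, self.rim_width
        ramp = np.clip((a - np.asarray(rho, float)) / d, 0.0, 1.0)
        return -depth * ramp

    def mean_escape_time(self, depth: float) -> float:
        """Exact 2D mean first-passage time (ms) from the trap centre to the
        absorbing circle, by quadrature of the double integral
        T = (1/D) int_0^b dr e^{U}/r int_0^r dr' r' e^{-U}."""
        b = self.absorb_radius
        n = 4000
        r = np.linspace(b / n * 0.5, b, n)
        u = self.potential(r, depth)
        inner = np.concatenate([[0.0], np.cumsum(
            0.5 * (r[1:] * np.exp(-u[1:]) + r[:-1] * np.exp(-u[:-1])) * np.diff(r))])
        integrand = np.exp(u) / r * inner
        return float(np.trapezoid(integrand, r) / self.diffusivity)

    def well_depth(self, t_esc: float, bracket=(1e-3, 40.0)) -> float:
        """Invert the escape-time map: W such that mean_escape_time(W) = t_esc."""
        f = lambda w: self.mean_escape_time(w) - t_esc
        if f(bracket[0]) > 0:
            raise ValueError("escape time below the attempt-time prefactor")
        return brentq(f, *bracket, xtol=1e-10)


def _bd_loop_py(seed, n_events, dt, d_coef, a, delta, b, slope):
    np.random.seed(seed)
    sig = math.sqrt(2.0 * d_coef * dt)
    drift_fac = -d_coef * slope * dt
    b2 = b * b
    lo = a - delta
    times = np.empty(n_events)
    chunk = 2048
    for i in range(n_events):
        x = 0.0
        y = 0.0
        steps = 0
        done = False
        while not done:
            noise = np.random.standard_normal(2 * chunk) * sig
            for j in range(chunk):
                r2 = x * x + y * y
                if r2 >= b2:
                    done = True
                    break
                if r2 > lo * lo:
                    rho = math.sqrt(r2)
                    if rho < a:
                        fac = drift_fac / rho
                        x += fac * x
                        y += fac * y
                x += noise[2 * j]
                y += noise[2 * j + 1]
                steps += 1
        times[i] = steps * dt
    return times


try:  # the stepping loop is serial per walker; jit it when numba is present
    import numba as _numba

    _bd_loop = _numba.njit(cache=False)(_bd_loop_py)
except Exception:  # pragma: no cover
    _bd_loop = _bd_loop_py


def bd_escape_simulate(trap: TrapModel, depth: float, seed: int, n_events: int,
                       dt: Optional[float] = None, frame_interval: float = 0.0,
                       species: str = "bd") -> EscapeEventTable:
    """Overdamped Langevin simulation of the escape process.

    All walkers start at the trap centre and diffuse in the plane with
    drift -D grad U; an event ends at the first crossing of the absorbing
    circle. Reproducible under a fixed seed. The timestep must satisfy
    dt <= 0.01 (rim width)^2 / D.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    d_coef = trap.diffusivity
    dt_max = 0.01 * trap.rim_width ** 2 / d_coef
    if dt is None:
        dt = dt_max
    if dt > dt_max * (1 + 1e-9):
        raise ValueError(f"timestep {dt:.3g} ms exceeds the stability bound "
                         f"{dt_max:.3g} ms")
    a, delta, b = trap.pocket_radius, trap.rim_width, trap.absorb_radius
    slope = depth / delta          # dU/drho inside the ramp, kBT/nm
    times = _bd_loop(int(seed), int(n_events), float(dt), float(d_coef),
                     float(a), float(delta), float(b), float(slope))
    if frame_interval > 0:
        times = np.maximum(np.ceil(times / frame_interval), 1) * frame_interval
    return EscapeEventTable(dt=times, frame_interval=frame_interval,
                            species=species,
                            meta={"seed": seed, "depth_kBT": depth, "dt_ms": dt})


@dataclass(frozen=True)
class Calibration:
    """Device calibration from a species of known effective charge."""

    phi_s: float                 # kBT/e
    phi_m: float                 # kBT/e
    calibrator_q_eff: float      # e
    calibrator_t_esc: float      # ms
    trap: TrapModel
    device: SlitDevice = None
    electrolyte: Electrolyte = None


def _phi_m(phi_s: float, device: SlitDevice, electrolyte: Electrolyte) -> float:
    return 2.0 * phi_s * math.exp(-electrolyte.kappa * device.half_height)


def model_escape_time(q_eff: float, phi_s: float, device: SlitDevice,
                      electrolyte: Electrolyte, trap: TrapModel) -> float:
    """Mean escape time (ms) predicted for effective charge q_eff at surface
    potential phi_s: W = q_eff phi_m + dF_trans fed through the MFPT map."""
    w = q_eff * _phi_m(phi_s, device, electrolyte) + trap.dF_trans
    return trap.mean_escape_time(w)


def confinement_entropy(device: SlitDevice, r_h: float) -> float:
    """Entropic well-depth component dF_trans (kBT): the pocket offers the
    molecule's centre more accessible height than the slit,
    ln[(2h + d - 2 r_h)/(2h - 2 r_h)]."""
    num = device.pocket_gap - 2 * r_h
    den = device.gap - 2 * r_h
    if den <= 0 or num <= 0:
        raise ValueError("hydrodynamic radius exceeds the slit gap")
    return math.log(num / den)


def calibrate_surface_potential(calibrator_q_eff: float, calibrator_fit: EscapeFit,
                                device: SlitDevice, electrolyte: Electrolyte,
                                trap: TrapModel) -> Calibration:
    """Root-solve the device surface potential from a calibrator measurement.

    Finds phi_s in (-6, 0) kBT/e such that the trap model reproduces the
    calibrator's measured mean escape time given its known effective charge
    (28.2 e for 30 bp and 45.6 e for 60 bp dsDNA in this workflow).
    """
    t_meas = calibrator_fit.t_esc

    def f(phi_s):
        return model_escape_time(calibrator_q_eff, phi_s, device,
                                 electrolyte, trap) - t_meas

    lo, hi = -6.0, -1e-6
    if f(lo) * f(hi) > 0:
        raise ValueError("no surface potential in (-6, 0) kBT/e reproduces the "
                         "calibrator escape time")
    phi_s = brentq(f, lo, hi, xtol=1e-10)
    return Calibration(phi_s=phi_s,
                       phi_m=_phi_m(phi_s, device, electrolyte),
                       calibrator_q_eff=calibrator_q_eff,
                       calibrator_t_esc=t_meas, trap=trap,
                       device=device, electrolyte=electrolyte)


def infer_qeff(fit: EscapeFit, calibration: Calibration,
               trap: Optional[TrapModel] = None) -> tuple[float, float]:
    """Invert a measured escape time into an effective charge (e).

    q_eff = [W(t_esc) - dF_trans] / phi_m with W from the calibrated trap
    model; returns (q_eff, propagated standard error). A species identical
    to the calibrator returns the calibrator charge exactly.
    """
    trap = trap or calibration.trap
    w = trap.well_depth(fit.t_esc)
    q = (w - trap.dF_trans) / calibration.phi_m
    # dW = dt/t for t ~ exp(W); propagate through the division
    dq = abs((fit.stderr / fit.t_esc) / calibration.phi_m)
    return float(q), float(dq)
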