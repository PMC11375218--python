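"""Synthetic stand-ins for the study's raw inputs.

The measurement chain starts from microscopy-derived residence events and
MD-derived conformational ensembles; neither is available to a desk-scale
pipeline, so this module generates statistically faithful substitutes:
exponential escape-event streams (with the short-lag contaminant component
that motivates lag exclusion), discrete worm-like-chain conformational
ensembles, and the device/electrolyte fixtures of the two measurement
configurations. Every generator is reproducible under a fixed seed.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .escape_time import Calibration, EscapeEventTable, model_escape_time
from .molecular_models import Conformer, Ensemble
from .pb_core import Electrolyte, SlitDevice

__all__ = [
    "generate_escape_events", "generate_chain_ensemble",
    "generate_device_fixture", "DEVICE_FIXTURES", "bond_correlation",
]

#: Device fixtures: geometry, calibrated surface potential (kBT/e), salt (mol/L)
#: and, where the source prints one, its kappa*h bookkeeping value (stored
#: verbatim, never recomputed from h and c0).
DEVICE_FIXTURES = {
    "fig1_device": dict(half_height=35.0, pocket_depth=280.0, phi_s=-1.91,
                        c0=0.6e-3, printed_kappa_h=5.5),
    "fig3_device": dict(half_height=37.5, pocket_depth=280.0, phi_s=-2.24,
                        c0=1.2e-3, printed_kappa_h=None),
    "fig1c_geometry": dict(half_height=35.0, pocket_depth=210.0, phi_s=-2.2,
                           c0=1.2e-3, printed_kappa_h=None),
}


def generate_device_fixture(name: str):
    """(SlitDevice, Electrolyte, meta) for a named measurement configuration."""
    if name not in DEVICE_FIXTURES:
        raise KeyError(f"unknown device fixture '{name}'; "
                       f"choose from {sorted(DEVICE_FIXTURES)}")
    f = DEVICE_FIXTURES[name]
    dev = SlitDevice(half_height=f["half_height"], pocket_depth=f["pocket_depth"],
                     phi_s=f["phi_s"])
    elec = Electrolyte.monovalent(f["c0"])
    meta = {"name": name, "printed_kappa_h": f["printed_kappa_h"]}
    return dev, elec, meta


def generate_escape_events(n_events: int, seed: int,
                           t_esc: Optional[float] = None,
                           q_eff: Optional[float] = None,
                           calibration: Optional[Calibration] = None,
                           frame_interval: float = 0.1,
                           contaminant_fraction: float = 0.0,
                           contaminant_mean: float = 2.0,
                           species: str = "synthetic") -> EscapeEventTable:
    """Exponential residence events, frame-discretized, optionally contaminated.

    Either the true mean ``t_esc`` (ms) is given directly, or a true
    ``q_eff`` (e) together with a device calibration, in which case the mean
    follows from the calibrated trap model. A contaminant component of
    short-mean exponential events emulates transiently trapped weakly
    charged species (free dye, degraded material) at the stated fraction.
    Durations are recorded as ceil(t / frame) frames.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    if t_esc is None:
        if q_eff is None or calibration is None:
            raise ValueError("give either t_esc, or q_eff plus a calibration")
        t_esc = model_escape_time(q_eff, calibration.phi_s, calibration.device,
                                  calibration.electrolyte, calibration.trap)
    rng = np.random.default_rng(seed)
    t = rng.exponential(t_esc, size=n_events)
    if contaminant_fraction > 0:
        m = rng.random(n_events) < contaminant_fraction
        t[m] = rng.exponential(contaminant_mean, size=int(m.sum()))
    if frame_interval > 0:
        t = np.maximum(np.ceil(t / frame_interval), 1) * frame_interval
    return EscapeEventTable(dt=t, frame_interval=frame_interval, species=species,
                            meta={"seed": seed, "true_t_esc": t_esc,
                                  "contaminant_fraction": contaminant_fraction,
                                  "contaminant_mean": contaminant_mean})


def bond_correlation(l_p: float, b_c: float) -> float:
    """Mean bond-angle cosine of a discrete chain with persistence length l_p.

    Uses the Kuhn-segment convention b_K = b (1+c)/(1-c) = 2 l_p, so the
    freely jointed limit corresponds to l_p = b_c/2 (c = 0) and c -> 1 as
    l_p -> infinity.
    """
    if l_p < b_c / 10.0:
        raise ValueError("persistence length below b_c/10 is numerically "
                         "meaningless for a discrete chain")
    x = 2.0 * l_p / b_c
    return (x - 1.0) / (x + 1.0)


def _bend_concentration(c: float) -> float:
    """Stiffness kb of the thermal bending density p(cos t) ~ exp(kb cos t)
    whose mean cosine equals c (Langevin-function inversion)."""
    if c <= 1e-9:
        return 0.0
    f = lambda k: (1.0 / math.tanh(k) - 1.0 / k) - c
    return brentq(f, 1e-8, 1e6, xtol=1e-12)


def _sample_cos_theta(rng, kb: float, n: int) -> np.ndarray:
    if kb == 0.0:
        return rng.uniform(-1.0, 1.0, n)
    u = rng.random(n)
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kb)) / kb


def generate_chain_ensemble(n_b: int = 30, b_c: float = 0.56, l_p: float = 2.0,
                            n_conformers: int = 500, seed: int = 0,
                            label: str = "wlc") -> Ensemble:
    """Discrete worm-like-chain conformers with one charge site per base.

    Chains of n_b + 1 sites have fixed bond length ``b_c`` and thermally
    distributed bond angles whose stiffness reproduces the requested
    persistence length; azimuths are uniform. Defaults (b_c = 0.56 nm from
    scattering measurements on poly-dT, l_p = 2 nm) emulate an ssDNA
    homopolymer at low ionic strength.
    """
    if n_b < 2:
        raise ValueError("n_b must be at least 2")
    if l_p <= 0 or b_c <= 0:
        raise ValueError("persistence length and spacing must be positive")
    c = bond_correlation(l_p, b_c)
    kb = _bend_concentration(c)
    rng = np.random.default_rng(seed)
    n_bonds = n_b  # n_b + 1 sites
    conformers = []
    for i in range(n_conformers):
        cos_t = _sample_cos_theta(rng, kb, n_bonds - 1)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_bonds - 1)
        u = np.zeros((n_bonds, 3))
        u[0] = (0.0, 0.0, 1.0)
        for j in range(1, n_bonds):
            t = u[j - 1]
            # orthonormal frame around the previous bond direction
            a = np.array([1.0, 0.0, 0.0]) if abs(t[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
            e1 = np.cross(t, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            st = math.sqrt(max(0.0, 1.0 - cos_t[j - 1] ** 2))
            u[j] = cos_t[j - 1] * t + st * (math.cos(phi[j - 1]) * e1 +
                                            math.sin(phi[j - 1]) * e2)
        sites = np.vstack([np.zeros(3), np.cumsum(b_c * u, axis=0)])
        conformers.append(Conformer(sites, label=f"{label}-{i}"))
    return Ensemble(conformers, label=label)
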