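"""Published measured effective charges used as comparison inputs.

These are experimental readouts (escape-time electrometry), shipped so the
model-based pipeline can be compared against them; they are inputs, never
outputs, of this package. Charges in e (magnitudes), escape times in ms.
The stated absolute accuracy of the measurements is about 10%, with
relative precision of 0.1-1%.
"""

#: Short-fragment panel (singly labelled at n_b = 5, doubly labelled above),
#: measured in the 2h = 70 nm device at 0.6 mM NaCl.
SHORT_PANEL_QEFF = {5: 6.3, 8: 9.2, 9: 9.8, 11: 10.7, 12: 11.9}
SHORT_PANEL_TESC_MS = {5: 29.16, 8: 50.82, 9: 65.68, 11: 79.24, 12: 98.08}
SHORT_PANEL_DYES = {5: 1, 8: 2, 9: 2, 11: 2, 12: 2}

#: 60-base homopolymers, two measurement datasets (2h = 75 nm, 1.2 mM NaCl).
QEFF_60 = {
    "poly-dT": (44.3, 44.1),
    "poly-dA": (40.7, 38.7),
    "poly-rU": (41.5, 40.7),
    "mixed": (42.3, None),
}

#: 30-base poly-dT and poly-rU (same device family).
QEFF_30 = {"poly-dT": 27.4, "poly-rU": 26.2}

#: Calibrator effective charges (30 bp / 60 bp dsDNA with two dyes).
CALIBRATOR_QEFF = {30: 28.2, 60: 45.6}

#: Renormalization factors quoted for one 60-base dataset.
ETA_60 = {"poly-dT": 0.70, "poly-dA": 0.61, "poly-rU": 0.65}


def qeff60_mean(species: str) -> float:
    """Two-dataset mean measured |q_eff| (e) for a 60-base species."""
    a, b = QEFF_60[species]
    return a if b is None else 0.5 * (a + b)
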