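"""Effective charge of a short single-stranded fragment.

Builds an ideal 5-base half-helix bead model (one -1 e site per phosphate
plus the terminal site), solves the nonlinear PB equation at the 0.6 mM
measurement conditions, matches the far field, adds the dye contribution,
and compares with the measured value. At this length the molecule is
smaller than the Debye length, so renormalization is weak (eta near 1).
"""
from etekit import build_half_helix
from etekit.effective_charge import DyeSpec, add_dye_effective_charge, solve_and_match
from etekit.pb_core import SolverOptions
from etekit.reference_data import SHORT_PANEL_QEFF
from etekit.synthetic_data import generate_device_fixture

n_b = 5
_, elec, _ = generate_device_fixture("fig1_device")
hh = build_half_helix(n_b)
print(f"half-helix n_b={n_b}: {hh.n_atoms} charge sites, "
      f"q_str = {hh.total_charge:+.0f} e")

core = solve_and_match(hh, elec, SolverOptions(padding_debye=6.0))
total = add_dye_effective_charge(core, DyeSpec(count=1))
print(f"core q_calc = {core.q_calc:+.2f} e (eta = {core.eta:.3f})")
print(f"with one dye: q_calc = {total.q_calc:+.2f} e; "
      f"measured |q_eff| = {SHORT_PANEL_QEFF[n_b]} e")
print("eta close to 1 confirms that fragments shorter than the Debye length"
      " are barely renormalized.")
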