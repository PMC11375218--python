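"""Electrostatics of the nanoslit trap device.

Solves the 1D two-plate problem and the 2D slit-pocket cross-section for
the published device geometry and prints the wall, midplane and pocket
potentials. The midplane offset between slit and pocket is the lever arm
that converts a molecule's effective charge into a trap depth.
"""
from etekit import solve_planar_slit, solve_slit_pocket_2d
from etekit.synthetic_data import generate_device_fixture

dev, elec, _ = generate_device_fixture("fig1c_geometry")
print(f"device: 2h = {dev.gap} nm, pocket depth {dev.pocket_depth} nm, "
      f"c0 = {elec.c0*1e3:.1f} mM (Debye length {elec.debye:.2f} nm)")

fld1 = solve_planar_slit(dev, elec)
print(f"1D slit: wall potential {fld1.wall_potential:+.3f} kBT/e, "
      f"midplane {fld1.midplane_potential:+.4f} kBT/e")

fld2 = solve_slit_pocket_2d(dev, elec)
print(f"2D slit-pocket: slit midplane {fld2.slit_midplane:+.4f}, "
      f"pocket midplane {fld2.pocket_midplane:+.6f}, "
      f"offset dphi_mid = {fld2.delta_phi_mid:+.4f} kBT/e")
print("dphi_mid is the potential a trapped molecule sees when it leaves the"
      " pocket: depth W = q_eff * dphi_mid (plus an entropic term).")
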