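"""Worm-like-chain conformational ensembles and representative structures.

Generates a discrete worm-like-chain ensemble standing in for an MD
conformational ensemble of a 30-base single strand, summarizes it in the
(R_g, R) plane, and picks the mode and the extreme-R members of the densest
25% of conformers -- the structures one would feed to the PB solver.
"""
import numpy as np

from etekit.molecular_models import ensemble_metrics_table, select_representatives
from etekit.synthetic_data import generate_chain_ensemble

ens = generate_chain_ensemble(n_b=30, b_c=0.56, l_p=2.0, n_conformers=800, seed=7)
df = ensemble_metrics_table(ens)
print(df[["R_g", "R", "l_c", "b_c"]].describe().loc[["mean", "std"]].round(3))

mode, c_max, c_min = select_representatives(ens, percentile=25)
print(f"mode conformer:   R_g = {mode.r_g:.2f} nm, R = {mode.end_to_end:.2f} nm")
print(f"max-R on contour: R_g = {c_max.r_g:.2f} nm, R = {c_max.end_to_end:.2f} nm")
print(f"min-R on contour: R_g = {c_min.r_g:.2f} nm, R = {c_min.end_to_end:.2f} nm")
print("extended conformers (large R_g, R) renormalize less and carry a"
      " larger effective charge than compact ones of the same sequence.")
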