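"""Generate the sparse and detailed training datasets for a case study.

Simulates the case-B S-system from the five printed starting sets (200
samples over 20 time units) and writes the CSV dialect used throughout
the package.
"""

import numpy as np

import grncompare as g

model = g.build_case("B", "SS")
sparse = g.generate_sparse(model)
detailed = g.generate_detailed(model)

tr = sparse.trajectories[0]
print(f"sparse dataset: {len(sparse.trajectories)} trajectory, "
      f"{tr.n_points} points x {tr.n_genes} genes")
print(f"detailed dataset: {len(detailed.trajectories)} trajectories "
      f"(starting sets {[t.label for t in detailed.trajectories]})")
print(f"X(0) of trajectory 1: {tr.x[0]}")
print(f"X(t_end) of trajectory 1: {np.round(tr.x[-1], 4)}")
print()
print("Each row of the matrix is one sampling instant; the network input")
print("X1 decays from 0.8 while the cascade genes X2..X5 respond and")
print("relax toward their steady states.")

detailed.to_csv("scratch_case_b_ss_detailed.csv")
print("wrote scratch_case_b_ss_detailed.csv (series_id,time,X1..X5)")
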