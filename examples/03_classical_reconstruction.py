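"""Reconstruct a two-target scene with the four classical iterative solvers.

Builds the weight matrix once, simulates noisy measurements for two 4 mm
targets 2 mm apart, and compares adaptive FISTA, fixed-budget FISTA (300
iterations), Poisson MLEM (800 iterations) and GMRF MAP-ICD by DICE and CNR.
Expect the L1 methods to give sparse but fragmented targets and MLEM/MAP
smoother ones; none resolves closely-spaced targets as well as the trained
network (example 04).
"""

import time

from xlct import ReconSettings, Study, scaled_spec
from xlct.experiments import aggregate_reports

study = Study(scaled_spec())
print(f"mesh {study.mesh.n_nodes} nodes; "
      f"W {study.weight_matrix.shape} (views x pixels, voxels)")

case = study.make_case(study.symmetric_pair(eed_mm=2.0), "eed2mm",
                       snr_db=30.0, seed=1, eed_mm=2.0)
print(f"case: two 4 mm targets at EED 2.0 mm, 30 dB measurement noise")

settings = {
    "adfista": ReconSettings(lam=0.1, step=0.01, max_iter=600, tol=1e-6),
    "tfista": None,   # defaults: lam 0.1, 300 iterations
    "admlem": ReconSettings(max_iter=800),
    "map": ReconSettings(max_iter=15, tol=1e-4),
}
reports = []
for method, s in settings.items():
    t0 = time.time()
    r = study.evaluate(method, case, settings=s)
    reports.append(r)
    print(f"{method:8s} DICE {r.dice:.3f}  CNR {r.cnr:.2f}  "
          f"components@half-max {r.extra['n_components_halfmax']}  "
          f"({time.time() - t0:.1f} s)")

agg = aggregate_reports(reports)
print("DICE close to 1 and exactly 2 half-max components would mean the two "
      "targets are recovered with their true shapes; the classical solvers "
      "typically stay well short of that on this diffuse inverse problem.")
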