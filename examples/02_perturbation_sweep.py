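"""How the sharing score emerges from an eigenvector perturbation sweep.

Builds a plate-focused network (even food deliveries plus a little
off-task activity), sweeps the uniform diagonal perturbation q applied to
the four plate vertices and prints, for a few q values, the smallest
plate-vertex entry and the largest non-plate entry of the leading left
eigenvector.  The sharing score is the largest q at which the plates
still dominate.
"""

import numpy as np

from playnet import compute_sharing_score, default_zone_map, normalise_with_baseline
from playnet.network import TransitionNetwork
from playnet.score import _leading_left_vectors
from playnet.zones import N_ZONES

zm = default_zone_map()
f = zm.food_vertex
psi = sorted(zm.plate_vertices)

transitions = [(f, p) for p in psi] * 3 + [(1, 2), (2, 3), (12, 14)]
T = np.zeros((N_ZONES, N_ZONES), dtype=np.int64)
for o, d in transitions:
    T[o, d] += 1
net = TransitionNetwork(T=T, variant="direct", zone_map=zm, transitions=transitions)
adj = normalise_with_baseline(net)

mask = np.zeros(N_ZONES, dtype=bool)
mask[psi] = True
print(" q       min plate entry   max other entry   plates dominant?")
for q in (-0.10, -0.05, 0.0, 0.05, 0.074, 0.076, 0.10):
    P = np.asarray(adj.A).copy()
    P[psi, psi] -= q
    _, vec = _leading_left_vectors(P[None, ...])
    lo, hi = vec[0][mask].min(), vec[0][~mask].max()
    print(f"{q:+.3f}        {lo:.4f}            {hi:.4f}          {lo > hi}")

score = compute_sharing_score(adj, zm)
print(f"\nsharing score (bisection): {score.score:+.4f}")
print(
    "Negative q inflates the plate entries, positive q suppresses them;\n"
    "the dominance indicator flips exactly once, and the flip point is\n"
    "the sharing score."
)
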