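"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal method
available (double loops, ODE integration, sort-then-prefix) so they share
no code path with the implementation they check.
"""

import numpy as np
from scipy.integrate import solve_ivp


def brute_force_steric(structure) -> float:
    """O(n²) soft-sphere repulsion with the same exclusion rule."""
    coords = structure.coords
    radii = structure.radii
    chains = structure.chain_ids
    res = structure.res_ids
    e = 0.0
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if chains[i] == chains[j] and abs(int(res[i]) - int(res[j])) <= 1:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            overlap = radii[i] + radii[j] - d
            if overlap > 0:
                e += overlap**2
    return e


def filter_then_top_k(values, energies, ids, threshold, k):
    """Sort-the-strict-pass-subset oracle for filter + selection."""
    passing = [(e, i) for v, e, i in zip(values, energies, ids)
               if v > threshold]
    passing.sort()
    return [i for _, i in passing[:k]]


def pairwise_rmsd_mean(coord_sets) -> float:
    """Brute-force mean pairwise RMSD (no superposition)."""
    rmsds = []
    m = len(coord_sets)
    for a in range(m):
        for b in range(a + 1, m):
            d = coord_sets[a] - coord_sets[b]
            rmsds.append(np.sqrt(np.mean(np.sum(d**2, axis=1))))
    return float(np.mean(rmsds))


def langmuir_ode(kon, koff, rmax, C, t_assoc, t_eval):
    """1:1 binding kinetics integrated numerically (independent of the
    closed form): dR/dt = kon·C·(Rmax − R) − koff·R during association,
    then dR/dt = −koff·R."""
    def rhs(t, r):
        c = C if t <= t_assoc else 0.0
        return kon * c * (rmax - r[0]) - koff * r[0]

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [0.0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, max_step=1.0)
    return sol.y[0]


def discrete_hourglass_radius(z, zs, ring_radii, atom_radius):
    """Closed-form pore radius of a stack of rings: the on-axis distance
    to the nearest ring surface."""
    z = np.atleast_1d(z)
    d = np.sqrt(ring_radii[None, :] ** 2 + (z[:, None] - zs[None, :]) ** 2)
    return d.min(axis=1) - atom_radius
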