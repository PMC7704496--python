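"""Independent numerical oracles used by the test suite.

These solve the same physical problems as the package, but by generic
root bracketing on the mass-balance equations rather than through the
closed-form expressions under test, so agreement is informative.
"""

from __future__ import annotations


def fraction_bound_bisection(
    c_protein: float, c_ligand: float, n_sites: float, kd: float, tol: float = 1e-16
) -> float:
    """Bound protein fraction by bisection on the free-protein mass balance.

    Unknown: free protein A_free in [0, c_A].  Constraints:
    bound = c_A - A_free, free sites S_free = N c_B - bound, and the
    equilibrium condition A_free * S_free / K_D = bound.  The residual
    f(A_free) = A_free * S_free / K_D - (c_A - A_free) is monotonically
    increasing, negative at A_free = 0 and non-negative at A_free = c_A.
    """
    if c_ligand == 0.0:
        return 0.0
    if kd <= 0.0:
        raise ValueError("bisection oracle needs kd > 0")

    def residual(a_free: float) -> float:
        bound = c_protein - a_free
        s_free = n_sites * c_ligand - bound
        return a_free * s_free / kd - bound

    lo, hi = 0.0, c_protein
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * c_protein:
            break
    a_free = 0.5 * (lo + hi)
    return (c_protein - a_free) / c_protein
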