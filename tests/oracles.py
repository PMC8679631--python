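"""Independent numerical oracles used by the tests.

These deliberately avoid the package's analytic-convolution path: the
compartment ODEs are integrated with an adaptive stiff solver against
the same interpolated input function.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_2tcm(params, aif, times):
    """Adaptive-ODE solution of the two-tissue model at the given times."""
    def rhs(t, y):
        cp = aif.plasma_at(t)
        c1, c2 = y
        return [params.K1 * cp - (params.k2 + params.k3) * c1 + params.k4 * c2,
                params.k3 * c1 - params.k4 * c2]

    sol = solve_ivp(rhs, (0.0, float(times[-1])), [0.0, 0.0], t_eval=times,
                    method="LSODA", rtol=1e-8, atol=1e-10, max_step=0.1)
    tissue = sol.y[0] + sol.y[1]
    return (1.0 - params.vb) * tissue + params.vb * aif.blood_at(times)
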