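"""Closed-form Kalman filter/smoother for a single AR(1)-deviation series.

Independent oracle used against the package's FFBS-based imputation: the
same linear-Gaussian state model, solved exactly with known parameters.
"""

import numpy as np


def smoother_means(y_prec, y_pm, rho, sig_proc, T, init_scale=3.0):
    """RTS-smoothed means and variances of the deviation series.

    ``y_prec``/``y_pm`` are per-hour observation precision and
    precision*mean on the deviations (0 where unobserved).
    """
    m = np.zeros(T)
    P = np.zeros(T)
    mp, Pp = 0.0, (init_scale * sig_proc) ** 2
    for t in range(T):
        if t > 0:
            mp = rho * m[t - 1]
            Pp = rho * rho * P[t - 1] + sig_proc**2
        prec = 1.0 / Pp + y_prec[t]
        P[t] = 1.0 / prec
        m[t] = P[t] * (mp / Pp + y_pm[t])
    ms = m.copy()
    Vs = P.copy()
    for t in range(T - 2, -1, -1):
        Pp_next = rho * rho * P[t] + sig_proc**2
        J = P[t] * rho / Pp_next
        ms[t] = m[t] + J * (ms[t + 1] - rho * m[t])
        Vs[t] = P[t] + J * J * (Vs[t + 1] - Pp_next)
    return ms, Vs
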