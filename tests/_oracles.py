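"""Independent brute-force oracles shared by the unit and acceptance tests.

These are deliberately plain transcriptions — scalar loops, explicit
bisection, exhaustive path sums — kept free of the package's numerical
kernels so they can stand as independent checks of them.
"""

import numpy as np


def oracle_tcl(ta, tmrt, v, person, tol=1e-6):
    """Brute-force bisection for the implicit clothing temperature."""
    icl = person.icl
    fcl = 1.00 + 1.290 * icl if icl <= 0.078 else 1.05 + 0.645 * icl
    tsk = 35.7 - 0.028 * (person.met - person.work)

    def f(t):
        hc = max(2.38 * abs(t - ta) ** 0.25, 12.1 * np.sqrt(v))
        rhs = tsk - icl * (
            3.96e-8 * fcl * ((t + 273.0) ** 4 - (tmrt + 273.0) ** 4)
            + fcl * hc * (t - ta)
        )
        return t - rhs

    lo, hi = min(ta, tmrt, tsk) - 80.0, max(ta, tmrt, tsk) + 40.0
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def oracle_pmv(ta, tmrt, v, rh, person):
    """Straight-line transcription of the ISO heat balance, term by term."""
    pa = rh / 100.0 * 611.2 * np.exp(17.62 * ta / (243.12 + ta))
    m, w = person.met, person.work
    mw = m - w
    tcl = oracle_tcl(ta, tmrt, v, person)
    icl = person.icl
    fcl = 1.00 + 1.290 * icl if icl <= 0.078 else 1.05 + 0.645 * icl
    hc = max(2.38 * abs(tcl - ta) ** 0.25, 12.1 * np.sqrt(v))
    load = (
        mw
        - 3.05e-3 * (5733.0 - 6.99 * mw - pa)
        - max(0.0, 0.42 * (mw - 58.15))
        - 1.7e-5 * m * (5867.0 - pa)
        - 0.0014 * m * (34.0 - ta)
        - 3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tmrt + 273.0) ** 4)
        - fcl * hc * (tcl - ta)
    )
    return (0.303 * np.exp(-0.036 * m) + 0.028) * load


def oracle_garson(w, v):
    """Exhaustive path enumeration of the Garson decomposition."""
    n_in, n_hid = w.shape
    n_out = v.shape[1]
    q = np.zeros(n_in)
    for i in range(n_in):
        for h in range(n_hid):
            for o in range(n_out):
                q[i] += (
                    abs(w[i, h]) / sum(abs(w[k, h]) for k in range(n_in))
                ) * abs(v[h, o])
    return q / q.sum()
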