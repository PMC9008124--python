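"""Embedded benchmark diagnostics for the default parameter set.

These are the reference values of the solution, timescales, amplitudes,
basis coefficients, diagnostic indices and reduction errors of the
FcRn-IgG model at two representative times (one inside the one-constraint
period, one inside the two-constraint period), plus the reduction-error
benchmarks at twelve times.  They are used by the table-regeneration
command to log the deviation of a fresh computation from the benchmark,
and by the regression test suite.

Comparison tolerances (per cell class):

* concentrations, rates, timescales, amplitudes, c-coefficients: 0.5% relative
* normalized indices (P, J, D): 0.01 absolute
* er*_1, er*_2 reduction errors: 10% relative
* er*_3 (near the round-off floor of the constraint residual): factor 3

Reference amplitudes marked fragile (deep cancellations) are compared by
order of magnitude only.
"""

import numpy as np

REACTIONS = ("1", "2", "3f", "3b", "4")
SPECIES = ("C_IgG_p", "C_IgG_e", "C_FcRn_e", "C_IgG_FcRn_e")

#: diagnostics at t = 1e-2 h (one exhausted mode)
TABLE_T1E_2 = {
    "t": 1e-2,
    "M": 1,
    "y": np.array([77377.76, 1.70, 49422.84, 377.16]),
    "g": np.array([-4148.09, 33.84, -37744.56, 37744.56]),
    "tau": np.array([0.36e-4, 1.77, 458.09]),
    "f": np.array([1.86e-3, 3.78e4, 1.53e2]),
    "f_round": np.array([0.005e-3, 0.005e4, 0.005e2]),  # half unit of last digit
    "f_fragile": np.array([True, False, False]),
    "rates": np.array([38006.135, 42.479, 46943.920, 9014.109, 185.251]),
    "D": np.array([
        [0.000, 0.999, 0.000, 0.001],
        [0.091, 0.000, 0.001, 0.906],
        [0.908, 0.000, 0.036, 0.055],
    ]),
    "J": np.array([
        [0.000, -0.001, -0.998, -0.001, 0.000],
        [-0.086, -0.034, 0.032, -0.032, -0.817],
        [-0.199, -0.211, 0.203, -0.199, 0.187],
    ]),
    "c": np.array([
        [0.99910488, -0.99910293, -1.00000080, 1.00000080, 0.00089592],
        [1.00209268, -0.90652448, 0.00080178, -0.00080178, -1.00289446],
        [0.00403610, 0.09556626, -0.00008647, 0.00008647, -0.00394963],
    ]),
    "P": np.array([
        [0.404, -0.000, -0.500, 0.096, 0.000],
        [0.992, -0.001, 0.001, -0.000, -0.005],
        [0.941, 0.025, -0.025, 0.005, -0.004],
    ]),
    "r1": 1.94e-6,
    "r2": 8.98e-4,
    "a": 0.1096,
}

#: diagnostics at t = 1e2 h (two exhausted modes).  The benchmark rate row at
#: this time has a corrupted first entry; rates here are recomputed from the
#: benchmark concentrations through the rate laws (synthetic reference cells).
TABLE_T1E2 = {
    "t": 1e2,
    "M": 2,
    "y": np.array([31346.03, 58.84, 21202.58, 28597.42]),
    "g": np.array([-148.07, -0.58, 120.40, -120.40]),
    "tau": np.array([0.84e-4, 1.53, 100.82]),
    "f": np.array([0.55e-6, 0.37, 148.03]),
    "f_round": np.array([0.005e-6, 0.005, 0.005]),  # half unit of last digit
    "f_fragile": np.array([True, False, False]),
    "rates": None,  # filled below from the rate laws
    "D": np.array([
        [0.000, 0.995, 0.003, 0.002],
        [0.068, 0.004, 0.096, 0.831],
        [0.932, 0.000, 0.476, -0.407],
    ]),
    "J": np.array([
        [0.000, -0.002, -0.996, 0.000, -0.002],
        [-0.060, -0.149, 0.060, -0.061, -0.668],
        [-0.290, -0.258, 0.109, -0.107, 0.234],
    ]),
    "c": np.array([
        [0.99525512, -0.99525062, -1.00000977, 1.00000977, 0.00475466],
        [1.00855828, -0.92519772, 0.00190065, -0.00190065, -1.01045892],
        [0.01881054, 0.08335607, -0.00017575, 0.00017575, -0.01863478],
    ]),
    "P": np.array([
        [0.011, -0.001, -0.499, 0.489, 0.000],
        [0.461, -0.040, 0.039, -0.038, -0.421],
        [0.316, 0.134, -0.134, 0.131, -0.286],
    ]),
    "r1": 4.53e-6,
    "r2": 4.78e-3,
    "a": 0.1096,
}


def _rates_from_y(y):
    # rate laws with the default rate constants
    k1 = 0.167 / 0.34
    return np.array([k1 * y[0], 25.0 * y[1], 0.559 * y[1] * y[2], 23.9 * y[3], k1 * y[3]])


TABLE_T1E2["rates"] = _rates_from_y(TABLE_T1E2["y"])

#: reduction-error benchmarks; one-constraint-period block then
#: two-constraint-period block (er2_* reported only in the latter)
ERROR_TIMES_M1 = (1e-2, 1e-1, 1.0, 2.0, 3.0, 4.0)
ERROR_TIMES_M2 = (5.0, 10.0, 20.0, 50.0, 100.0, 1000.0)

ERRORS_M1 = {
    "er1_1": np.array([0.89e-3, 0.98e-3, 0.29e-2, 0.11e-1, 0.19e-2, 0.86e-3]),
    "er1_2": np.array([0.39e-5, 0.42e-5, 0.98e-5, 0.33e-4, 0.58e-4, 0.62e-4]),
    "er1_3": np.array([0.50e-7, 0.58e-7, 0.47e-6, 0.56e-5, 0.11e-6, 0.21e-7]),
}

ERRORS_M2 = {
    "er1_1": np.array([0.92e-3, 0.70e-3, 0.42e-3, 0.12e-3, 0.41e-4, 0.44e-5]),
    "er1_2": np.array([0.59e-4, 0.47e-4, 0.32e-4, 0.16e-4, 0.99e-5, 0.42e-5]),
    "er1_3": np.array([0.24e-7, 0.15e-7, 0.55e-8, 0.43e-9, 0.39e-10, 0.24e-13]),
    "er2_1": np.array([0.88e-2, 0.97e-2, 0.10e-1, 0.10e-1, 0.86e-2, 0.44e-2]),
    "er2_2": np.array([0.87e-4, 0.48e-4, 0.13e-4, 0.12e-3, 0.10e-3, 0.18e-4]),
    "er2_3": np.array([0.22e-4, 0.23e-4, 0.28e-4, 0.12e-3, 0.26e-4, 0.24e-7]),
}

#: per-class comparison tolerances
TOL_CONC_REL = 5e-3
TOL_INDEX_ABS = 1e-2
TOL_ERR_REL = 0.10
TOL_ERR3_FACTOR = 3.0
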