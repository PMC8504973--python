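"""Published study inputs used as defaults and cross-checks.

These are the printed summary values of the GLIC bimane-sensor study that
the pipeline takes as inputs: per-construct pH50 means from the summary
table, the fixed per-state sensor fluorescence intensities, the anchor
constants of the stepwise MWC fit, and the published isomerization-constant
multiplication factors.  Nothing here is produced by this package's own
fitting; fitted quantities always come out of :mod:`mwcgate.mwcfit`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allosteric import MWCParameters, SensorOptics

__all__ = [
    "TABLE1",
    "SENSOR_OPTICS",
    "ANCHOR_L_PA",
    "ANCHOR_K_R",
    "ANCHOR_K_PA",
    "PUBLISHED_FACTORS",
    "anchor_two_state_parameters",
    "study_truth_parameters",
]

#: Per-construct summary means: electrophysiological and fluorescence pH50
#: (mean, sd, n).  NaN marks non-functional (no current) or not determined.
TABLE1 = pd.DataFrame(
    [
        # construct, e_ph50, e_sd, e_n, f_ph50, f_sd, f_n, F0, dFmax
        ("Bim136-Q101W", 5.42, 0.08, 10, 5.85, 0.21, 17, 0.71, 0.45),
        ("Bim136-Q101W+E26Q", 4.83, 0.12, 6, 5.28, 0.34, 4, 0.53, 0.22),
        ("Bim136-Q101W+Y28F", 3.88, 0.08, 3, 3.68, 0.34, 3, 0.70, 0.38),
        ("Bim136-Q101W+D32E", 4.65, 0.12, 6, 5.52, 0.05, 3, 0.68, 0.38),
        ("Bim136-Q101W+E222Q", 4.68, 0.09, 5, 5.36, 0.14, 3, 0.66, 0.40),
        ("Bim136-Q101W+H235Q", 4.04, 0.21, 6, 5.00, 0.09, 3, 0.70, 0.42),
        ("Bim136-Q101W+propofol", 5.16, 0.13, 3, 5.33, 0.06, 4, 0.67, 0.38),
        ("Bim136-Q101W+H235Q+propofol", 4.71, 0.15, 6, 5.67, 0.14, 3, 0.70, 0.43),
        ("Bim136-Q101W+H235F", np.nan, np.nan, 3, 5.25, 0.08, 3, 0.70, 0.38),
        ("Bim136-Q101W+L157A", np.nan, np.nan, 3, 5.42, 0.65, 4, 0.67, 0.19),
        ("Bim136-Q101W+L246A", np.nan, np.nan, 3, 4.87, 0.14, 3, 0.65, 0.24),
        ("Bim250-Y197", 4.66, 0.18, 12, 5.83, 0.17, 8, 0.59, 0.33),
        ("Bim250-Y197+H235F", np.nan, np.nan, 3, 5.40, 0.13, 4, 0.54, 0.20),
        ("Bim250-Y197+L157A", np.nan, np.nan, 3, 5.81, 0.19, 3, 0.49, 0.45),
        ("Bim250-Y197+L246A", np.nan, np.nan, 3, 5.53, 0.03, 3, 0.64, 0.30),
    ],
    columns=[
        "construct",
        "electro_pH50", "electro_sd", "electro_n",
        "fluor_pH50", "fluor_sd", "fluor_n",
        "F0", "dF_max",
    ],
).set_index("construct")

#: Fixed per-state fluorescence intensities of the two sensors (F/F_SDS).
SENSOR_OPTICS = {
    "Bim136-Q101W": SensorOptics(F_R=0.70, F_pA=0.30, F_A=0.30, tie_pa_a=True),
    "Bim250-Y197": SensorOptics(F_R=0.56, F_pA=0.92, F_A=0.92, tie_pa_a=True),
}

#: Anchor of the stepwise fit: assumed pre-activation isomerization constant
#: of the pore-opening-dead H235F construct, and the proton affinities of
#: site class 1 extracted with it.
ANCHOR_L_PA = 100.0
ANCHOR_K_R = 3.6e-6
ANCHOR_K_PA = 1.0e-6

#: Published isomerization-constant multiplication factors
#: (f_L_pA, f_L_A) relative to the Bim136-Q101W sensor.
PUBLISHED_FACTORS = {
    "E26Q": (15.0, 10.0),
    "D32E": (2.0, 80.0),
    "H235Q": (1.5, 40.0),
    "E222Q": (7.0, 700.0),
}


def anchor_two_state_parameters(L_pA: float = ANCHOR_L_PA) -> MWCParameters:
    """Two-state (R/pA) model with the published anchor constants."""
    return MWCParameters.two_state(K_R=ANCHOR_K_R, K_pA=ANCHOR_K_PA, L_pA=L_pA)


def study_truth_parameters(sensor: str = "Bim136-Q101W") -> MWCParameters:
    """Three-state, two-site parameter set emulating one of the two sensors.

    Class 1 carries the published step-1 affinities; the sensor's L_pA and
    the class-2 (activation) constants were derived analytically, once, so
    that the model midpoints match the printed sensor summary values:
    L_pA = 15 places the R/pA midpoint at pH ~5.85 given the class-1 K's
    (both sensors print fluorescence midpoints of 5.85/5.83); the
    primed-site affinities (K_Rp = K_pAp = 1e-4 M, K_Ap = 1e-6 M, i.e.
    pKa 4 -> 6 on activation, plausible for carboxylates) leave enough
    dynamic range to represent the largest published activation factor
    (700).  The active fraction then crosses one half at the printed
    current midpoint (pH 5.42 or 4.66) for L_A = 1738 (ECD-compaction
    sensor) or 2.235e6 (M2-M3-loop sensor, whose bimane labeling itself
    destabilizes the active state).
    """
    if sensor not in SENSOR_OPTICS:
        raise KeyError(f"unknown sensor {sensor!r}")
    l_a = 1738.0 if sensor == "Bim136-Q101W" else 2.235e6
    return MWCParameters(
        K_R=ANCHOR_K_R,
        K_pA=ANCHOR_K_PA,
        K_A=ANCHOR_K_PA,
        K_Rp=1.0e-4,
        K_pAp=1.0e-4,
        K_Ap=1.0e-6,
        L_pA=15.0,
        L_A=l_a,
        constraint_flags=True,
    )
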