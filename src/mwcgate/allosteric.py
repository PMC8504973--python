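"""Three-state Monod-Wyman-Changeux model of proton-gated channel gating.

The channel is a pentamer in concerted equilibrium between a resting (R),
a pre-active (pA) and an active (A) conformation.  Two classes of proton
binding site, each present in ``n_sites`` identical copies, bias the
equilibrium: class 1 (unprimed) drives the R -> pA step, class 2 (primed)
drives the pA -> A step.  Each state s carries its own dissociation
constants ``K_s`` and ``K_sp`` for the two classes, and the zero-ligand
state ratios are set by the isomerization constants ``L_pA = R/pA`` and
``L_A = pA/A``.

The statistical weight of state s at proton concentration ``h`` is

    w_s = L_s * (1 + h/K_s)**n * (1 + h/K_sp)**n

with cumulative zero-ligand factors L_R = L_pA*L_A, L_pA-state = L_A,
L_A-state = 1, and fractional populations w_s / sum(w).  All weights are
evaluated in log space so that (1 + h/K)**5 never overflows even for
h/K ~ 1e8.

Observables built on the populations:

* fluorescence of a bimane conformational sensor, the population-weighted
  mean of per-state intrinsic intensities (on the F/F_SDS scale),
* macroscopic current, proportional to the active fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "MWCParameters",
    "StateFractions",
    "SensorOptics",
    "ModelCurve",
    "state_fractions",
    "state_fraction_curves",
    "fluorescence_response",
    "current_response",
    "half_transition_ph",
    "apparent_hill",
    "NoCrossingError",
]

#: L_A used by the two-state (R/pA) reduction: large enough to suppress the
#: active state below 1e-12 for any sensor-scale proton occupancy.
TWO_STATE_LA = 1.0e30


class NoCrossingError(ValueError):
    """The requested response does not cross its half level exactly once."""


@dataclass(frozen=True)
class MWCParameters:
    """Constants of the three-state, two-site-class MWC model.

    Dissociation constants are molar; isomerization constants are the
    dimensionless zero-ligand ratios L_pA = R/pA and L_A = pA/A.  Field
    names follow the standard MWC notation and are used verbatim in the
    flat JSON/YAML serialization.
    """

    K_R: float
    K_pA: float
    K_A: float
    K_Rp: float
    K_pAp: float
    K_Ap: float
    L_pA: float
    L_A: float
    n_sites: int = 5
    #: enforce the site-class assignment K_pA == K_A (class 1 drives
    #: pre-activation only) and K_Rp == K_pAp (class 2 drives activation only)
    constraint_flags: bool = False

    def __post_init__(self) -> None:
        for name in ("K_R", "K_pA", "K_A", "K_Rp", "K_pAp", "K_Ap"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")
        for name in ("L_pA", "L_A"):
            value = getattr(self, name)
            if value < 0 or math.isnan(value):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.constraint_flags:
            if self.K_pA != self.K_A:
                raise ValueError("constraint_flags requires K_pA == K_A exactly")
            if self.K_Rp != self.K_pAp:
                raise ValueError("constraint_flags requires K_Rp == K_pAp exactly")

    # -- derived concentration ratios (computed, never stored) -------------
    @property
    def C_pA(self) -> float:
        return self.K_pA / self.K_R

    @property
    def C_A(self) -> float:
        return self.K_A / self.K_pA

    @property
    def C_pAp(self) -> float:
        return self.K_pAp / self.K_Rp

    @property
    def C_Ap(self) -> float:
        return self.K_Ap / self.K_pAp

    # -- constructors -------------------------------------------------------
    @classmethod
    def two_state(
        cls,
        K_R: float,
        K_pA: float,
        L_pA: float,
        n_sites: int = 5,
        inert_K: float = 1.0e-6,
    ) -> "MWCParameters":
        """R/pA reduction: the active state is suppressed (L_A huge) and the
        primed site class is inert (equal K in all states, so it cancels)."""
        return cls(
            K_R=K_R,
            K_pA=K_pA,
            K_A=K_pA,
            K_Rp=inert_K,
            K_pAp=inert_K,
            K_Ap=inert_K,
            L_pA=L_pA,
            L_A=TWO_STATE_LA,
            n_sites=n_sites,
        )

    def with_multipliers(self, f_L_pA: float = 1.0, f_L_A: float = 1.0) -> "MWCParameters":
        """Mutant phenotype: same site affinities, isomerization constants
        scaled by per-transition multiplication factors."""
        if f_L_pA <= 0 or f_L_A <= 0:
            raise ValueError("multiplication factors must be positive")
        return replace(self, L_pA=self.L_pA * f_L_pA, L_A=self.L_A * f_L_A)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "K_R": self.K_R,
            "K_pA": self.K_pA,
            "K_A": self.K_A,
            "K_Rp": self.K_Rp,
            "K_pAp": self.K_pAp,
            "K_Ap": self.K_Ap,
            "L_pA": self.L_pA,
            "L_A": self.L_A,
            "n_sites": self.n_sites,
            "constraint_flags": self.constraint_flags,
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "MWCParameters":
        return cls(**{k: mapping[k] for k in cls.__dataclass_fields__ if k in mapping})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class StateFractions:
    """Fractional populations (r, pa, a); they sum to one."""

    r: float
    pa: float
    a: float

    def __post_init__(self) -> None:
        for name in ("r", "pa", "a"):
            value = getattr(self, name)
            if not (-1e-12 <= value <= 1 + 1e-12):
                raise ValueError(f"{name} outside [0, 1]: {value!r}")
        if abs(self.r + self.pa + self.a - 1.0) > 1e-12:
            raise ValueError("state fractions must sum to 1 within 1e-12")


@dataclass(frozen=True)
class SensorOptics:
    """Intrinsic fluorescence of each state on the F/F_SDS scale.

    Under the hypothesis that fluorescence changes are complete after
    pre-activation, F_pA == F_A; `tie_pa_a` asserts it.
    """

    F_R: float
    F_pA: float
    F_A: float
    tie_pa_a: bool = False

    def __post_init__(self) -> None:
        for name in ("F_R", "F_pA", "F_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tie_pa_a and self.F_pA != self.F_A:
            raise ValueError("tie_pa_a requires F_pA == F_A exactly")


@dataclass(frozen=True)
class ModelCurve:
    """A model-predicted response on a strictly monotone pH grid."""

    ph: np.ndarray
    values: np.ndarray
    kind: Literal["fluorescence", "active-fraction", "normalized-current"]
    note: str = ""

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ph.size == 0:
            raise ValueError("empty pH grid")
        if ph.size != values.size:
            raise ValueError("pH grid and values must have equal length")
        if np.any(ph < 0) or np.any(ph > 14):
            raise ValueError("pH values must lie in [0, 14]")
        diffs = np.diff(ph)
        if ph.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("pH grid must be strictly monotone")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "values", values)

    def to_csv(self, path) -> None:
        header = f"# response kind: {self.kind}"
        if self.note:
            header += f" | {self.note}"
        with open(path, "w") as fh:
            fh.write(header + "\npH,value\n")
            for p, v in zip(self.ph, self.values):
                fh.write(f"{p:.6g},{v:.10g}\n")


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def _log_weights(params: MWCParameters, h: np.ndarray) -> np.ndarray:
    """Log statistical weights of (R, pA, A), shape (3, len(h)).

    Weights are w_R = L_pA L_A (1+h/K_R)^n (1+h/K_Rp)^n,
    w_pA = L_A (1+h/K_pA)^n (1+h/K_pAp)^n, w_A = (1+h/K_A)^n (1+h/K_Ap)^n;
    equivalent to the C-ratio form with alpha = h/K_A, alpha' = h/K_Ap.
    """
    h = np.asarray(h, dtype=float)
    n = params.n_sites
    log_l_pa = math.log(params.L_pA) if params.L_pA > 0 else -math.inf
    log_l_a = math.log(params.L_A) if params.L_A > 0 else -math.inf
    lw_r = log_l_pa + log_l_a + n * (np.log1p(h / params.K_R) + np.log1p(h / params.K_Rp))
    lw_pa = log_l_a + n * (np.log1p(h / params.K_pA) + np.log1p(h / params.K_pAp))
    lw_a = n * (np.log1p(h / params.K_A) + np.log1p(h / params.K_Ap))
    return np.stack([np.broadcast_to(lw_r, h.shape), np.broadcast_to(lw_pa, h.shape), lw_a])


def _fractions_array(params: MWCParameters, h: np.ndarray) -> np.ndarray:
    lw = _log_weights(params, np.asarray(h, dtype=float))
    lw = lw - np.max(lw, axis=0, keepdims=True)  # softmax, overflow-safe
    w = np.exp(lw)
    return w / np.sum(w, axis=0, keepdims=True)


def state_fractions(params: MWCParameters, proton_conc: float) -> StateFractions:
    """Fractional populations (R, pA, A) at one proton concentration (molar)."""
    if not (proton_conc > 0 and math.isfinite(proton_conc)):
        raise ValueError(f"proton concentration must be positive, got {proton_conc!r}")
    r, pa, a = _fractions_array(params, np.array([proton_conc]))[:, 0]
    return StateFractions(r=float(r), pa=float(pa), a=float(a))


def state_fraction_curves(params: MWCParameters, ph_grid) -> dict[str, np.ndarray]:
    """Populations of all three states over a pH grid (vectorized)."""
    ph = np.asarray(ph_grid, dtype=float)
    fr = _fractions_array(params, 10.0 ** (-ph))
    return {"r": fr[0], "pa": fr[1], "a": fr[2]}


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def fluorescence_values(params: MWCParameters, optics: SensorOptics, ph) -> np.ndarray:
    """Weighted fluorescence at arbitrary (not necessarily sorted) pH points."""
    fr = state_fraction_curves(params, ph)
    return fr["r"] * optics.F_R + fr["pa"] * optics.F_pA + fr["a"] * optics.F_A


def active_fraction(params: MWCParameters, ph) -> np.ndarray:
    """Active-state population at arbitrary pH points."""
    return state_fraction_curves(params, ph)["a"]


def fluorescence_response(params: MWCParameters, optics: SensorOptics, ph_grid) -> ModelCurve:
    """Population-weighted sensor fluorescence F = r F_R + pa F_pA + a F_A."""
    values = fluorescence_values(params, optics, ph_grid)
    return ModelCurve(ph=np.asarray(ph_grid, dtype=float), values=values, kind="fluorescence")


def current_response(
    params: MWCParameters,
    ph_grid,
    normalization: Literal["max", "none"] = "none",
) -> ModelCurve:
    """Active-state population, optionally normalized to its grid maximum.

    Normalization to the maximum mirrors the treatment of constructs whose
    active population never reaches one, so that model and peak-current data
    share the [0, 1] scale.
    """
    a = state_fraction_curves(params, ph_grid)["a"]
    if normalization == "none":
        return ModelCurve(ph=np.asarray(ph_grid, dtype=float), values=a, kind="active-fraction")
    if normalization == "max":
        peak = float(np.max(a))
        if peak <= 1e-12:
            raise ValueError("active fraction is effectively zero (non-functional construct)")
        return ModelCurve(
            ph=np.asarray(ph_grid, dtype=float),
            values=a / peak,
            kind="normalized-current",
            note=f"normalized to grid maximum A={peak:.6g}",
        )
    raise ValueError(f"unknown normalization {normalization!r}")


# ---------------------------------------------------------------------------
# midpoints and steepness
# ---------------------------------------------------------------------------

_SCAN_PH = np.arange(0.0, 10.0 + 1e-9, 0.01)

Which = Literal["r", "pa", "a", "fluorescence-amplitude"]


def _response_on(params: MWCParameters, which: Which, optics: SensorOptics | None, ph: np.ndarray) -> np.ndarray:
    if which in ("r", "pa", "a"):
        return state_fraction_curves(params, ph)[which]
    if which == "fluorescence-amplitude":
        if optics is None:
            raise ValueError("optics required for fluorescence-amplitude midpoint")
        return fluorescence_response(params, optics, ph).values
    raise ValueError(f"unknown response {which!r}")


def half_transition_ph(
    params: MWCParameters,
    which: Which,
    optics: SensorOptics | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the requested response crosses its half level.

    For state fractions the half level is 0.5; for fluorescence it is the
    midpoint of the extreme values over pH 0-10.  A sign scan on a 0.01-pH
    grid must find exactly one crossing; otherwise (flat or bell-shaped
    response) an error names the condition.
    """
    y = _response_on(params, which, optics, _SCAN_PH)
    if which == "fluorescence-amplitude":
        half = 0.5 * (float(np.min(y)) + float(np.max(y)))
    else:
        half = 0.5
    g = y - half
    sign_change = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
    if sign_change.size == 0:
        raise NoCrossingError(
            f"response {which!r} has no half-level crossing on pH 0-10 (flat or saturated)"
        )
    if sign_change.size > 1:
        raise NoCrossingError(
            f"response {which!r} crosses its half level {sign_change.size} times "
            "(bell-shaped response); midpoint undefined"
        )
    i = int(sign_change[0])
    lo, hi = _SCAN_PH[i], _SCAN_PH[i + 1]
    # bisection on the 0.01-pH bracket down to the requested tolerance
    f_lo = g[i]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = float(_response_on(params, which, optics, np.array([mid]))[0]) - half
        if f_mid == 0.0:
            return mid
        if (f_lo < 0) == (f_mid < 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apparent_hill(
    params: MWCParameters,
    which: Which,
    optics: SensorOptics | None = None,
) -> float:
    """Apparent Hill slope of the response at its midpoint.

    nH = d logit(normalized response) / d ln[H+] evaluated by a centered
    finite difference with a 0.01-pH step; for a pure Hill curve this
    returns the Hill exponent exactly.  Returned as a positive magnitude.
    """
    mid = half_transition_ph(params, which, optics)
    step = 0.01
    ph_pair = np.array([mid - step, mid + step])  # higher then lower [H+]
    y = _response_on(params, which, optics, ph_pair)
    if which == "fluorescence-amplitude":
        scan = _response_on(params, which, optics, _SCAN_PH)
        lo, hi = float(np.min(scan)), float(np.max(scan))
        y = (y - lo) / (hi - lo)
    y = np.clip(y, 1e-15, 1 - 1e-15)
    logit = np.log(y / (1.0 - y))
    slope = (logit[0] - logit[1]) / (2.0 * step * math.log(10.0))
    return abs(float(slope))
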