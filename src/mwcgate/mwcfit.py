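"""Stepwise fitting of the three-state MWC model to titration panels.

The strategy mirrors how such a model is constrained in practice:

1.  A pore-opening-dead construct reduces the model to two states (R/pA).
    Its pre-activation isomerization constant cannot be separated from the
    two proton affinities, so it is *anchored* at a chosen value (default
    100) and the class-1 affinities (K_R, K_pA) are fitted to its
    fluorescence curve.  The parent sensors' own L_pA is then fitted with
    the affinities held fixed.
2.  A second proton-site class driving activation (K_Rp = K_pAp > K_Ap)
    plus L_A are fitted jointly to the sensor's fluorescence and
    normalized-current curves.  One site class alone cannot reproduce the
    observed >10-fold proton-concentration separation between the two
    modalities; ``single_site_separation_scan`` documents this by
    exhaustive grid search.
3.  Each mutant is fitted by adjusting only L_pA and L_A, reported as
    multiplication factors relative to its parent sensor.  Re-running the
    whole chain for alternative anchor values checks that the factor
    pattern, not its absolute scale, is the robust outcome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .allosteric import (
    TWO_STATE_LA,
    MWCParameters,
    SensorOptics,
    active_fraction,
    fluorescence_values,
    half_transition_ph,
)
from .prep import normalize_fluorescence, rundown_correct
from .titration import TitrationSeries

__all__ = [
    "FitConfig",
    "PanelRoster",
    "SensorModel",
    "MutantPhenotype",
    "PanelFit",
    "IdentifiabilityError",
    "step1_anchor_fit",
    "step1_fit_lpa",
    "step2_activation_fit",
    "fit_mutant_multipliers",
    "fit_panel",
    "sensitivity_scan",
    "single_site_separation_scan",
    "is_functional",
]


class IdentifiabilityError(RuntimeError):
    """The requested joint fit lies in a flat loss valley."""


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the stepwise fit.

    ``anchor_L_pA`` is the assumed pre-activation isomerization constant of
    the anchor (pore-dead) construct; ``alternates`` are re-run values for
    the sensitivity scan.  All constants are optimized in log10 space
    within the stated bounds; the loss is the sum of per-modality mean
    squared residuals on normalized curves (equal modality weight).
    """

    anchor_L_pA: float = 100.0
    alternates: tuple[float, ...] = (1000.0, 100000.0)
    k_bounds_log10: tuple[float, float] = (-9.0, -3.0)
    l_bounds_log10: tuple[float, float] = (-4.0, 8.0)
    factor_bounds_log10: tuple[float, float] = (-4.0, 8.0)
    exclude_below_ph: float | None = None
    #: affinities of the activation (primed) site class, held fixed in
    #: step 2.  The activation branch is under-determined from steady-state
    #: data (fluorescence cannot separate pA from A when their intensities
    #: are tied, and the current sigmoid constrains fewer features than the
    #: branch has parameters), so its affinities are chosen rather than
    #: fitted and only L_A is estimated; set either to None to fit it and
    #: accept the flat valley.
    K_pAp_fixed: float | None = 1.0e-4
    K_Ap_fixed: float | None = 1.0e-6
    #: refine the sensor's L_pA jointly with L_A in step 2: the two-state
    #: reduction used in step 1 ignores the active state and therefore
    #: biases the sensor's L_pA low; step 2 keeps it as a starting value
    refine_L_pA: bool = True
    #: mutant fits are flagged "poor" above 3x the sensor's per-point RSS,
    #: with this floor so that near-perfect sensor fits don't flag everything
    poor_rss_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.anchor_L_pA > 0:
            raise ValueError("anchor_L_pA must be positive")
        if any(a <= 0 for a in self.alternates):
            raise ValueError("alternate anchors must be positive")
        for name in ("k_bounds_log10", "l_bounds_log10", "factor_bounds_log10"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be finite with lo < hi")


@dataclass
class PanelRoster:
    """Names and per-construct options of one sensor's panel."""

    sensor: str
    anchor_mutant: str
    mutants: list[str]
    optics: SensorOptics
    two_state_only: set[str] = field(default_factory=set)
    exclude_below_ph: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SensorModel:
    """Fully parameterized sensor: the reference for mutant multipliers."""

    construct: str
    params: MWCParameters
    optics: SensorOptics
    rss_per_point: float


@dataclass(frozen=True)
class MutantPhenotype:
    """Fitted isomerization constants of one construct vs its parent sensor."""

    construct: str
    L_pA: float
    L_A: float | None
    f_L_pA: float
    f_L_A: float | None
    rss: float
    n_points: int
    quality: str  # ok | poor | two-state-only

    def __post_init__(self) -> None:
        if self.f_L_pA <= 0:
            raise ValueError("multiplication factors must be positive")
        if self.quality == "two-state-only" and self.f_L_A is not None:
            raise ValueError("two-state-only fits report no activation factor")


@dataclass
class PanelFit:
    """Result of the full stepwise chain at one anchor value."""

    anchor_L_pA: float
    K_R: float
    K_pA: float
    sensor: SensorModel
    phenotypes: dict[str, MutantPhenotype]
    errors: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data pooling
# ---------------------------------------------------------------------------

def _as_list(series) -> list[TitrationSeries]:
    return [series] if isinstance(series, TitrationSeries) else list(series)


def pool_fluorescence(
    series, exclude_below_ph: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (pH, F/F_SDS) points across replicates; normalizes raw series."""
    ph_all, y_all = [], []
    for s in _as_list(series):
        if s.modality != "fluorescence":
            raise ValueError("expected fluorescence series")
        if s.f_sds is not None and not s.normalized:
            s = normalize_fluorescence(s)
        pts = s.test_points()
        keep = np.ones(pts.ph.size, dtype=bool)
        if exclude_below_ph is not None:
            keep = pts.ph >= exclude_below_ph
        ph_all.append(pts.ph[keep])
        y_all.append(pts.response[keep])
    return np.concatenate(ph_all), np.concatenate(y_all)


def pool_currents(series) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (pH, I/Imax) points; rundown-corrects and per-replicate
    max-normalizes each recording."""
    ph_all, y_all = [], []
    for s in _as_list(series):
        if s.modality != "current":
            raise ValueError("expected current series")
        if s.is_reference.any():
            s = rundown_correct(s)
        peak = float(np.max(s.response))
        if peak <= 0:
            raise ValueError(f"{s.construct}/{s.replicate}: no positive current")
        ph_all.append(s.ph)
        y_all.append(s.response / peak)
    return np.concatenate(ph_all), np.concatenate(y_all)


def is_functional(series) -> bool:
    """Heuristic: does a current series carry signal above its baseline noise?

    Signal is the excess of the peak response over the high-pH baseline;
    noise is the spread of the baseline points.  Constructs failing this
    are fitted in two-state-only mode.
    """
    sig, noise = 0.0, 0.0
    for s in _as_list(series):
        if s.is_reference.any():
            s = rundown_correct(s)
        order = np.argsort(s.ph)[::-1]  # highest pH first
        resp = s.response[order]
        baseline = resp[:3]
        sig = max(sig, float(np.max(resp) - np.mean(baseline)))
        noise = max(noise, float(np.std(baseline)))
    return sig > 6.0 * noise and sig > 0


def _noise_estimate(y: np.ndarray) -> float:
    steps = np.diff(y)
    mad = float(np.median(np.abs(steps - np.median(steps))))
    return max(1.4826 * mad / math.sqrt(2.0), 1e-3)


def _check_direction_and_amplitude(ph, y, optics: SensorOptics) -> None:
    order = np.argsort(ph)[::-1]  # high pH -> low pH
    y_sorted = y[order]
    third = max(2, y.size // 3)
    high_end = float(np.mean(y_sorted[:third]))
    low_end = float(np.mean(y_sorted[-third:]))
    amplitude = abs(high_end - low_end)
    if amplitude < 3.0 * _noise_estimate(y_sorted):
        raise ValueError("flat series: amplitude below 3x the noise estimate")
    quenching = optics.F_R > optics.F_pA
    decreasing = high_end > low_end
    if quenching != decreasing:
        raise ValueError(
            "direction mismatch: data trend with acidification is opposite to "
            "the sign implied by the sensor optics"
        )


# ---------------------------------------------------------------------------
# model evaluation helpers
# ---------------------------------------------------------------------------

def _two_state_fluor(ph, log10_K_R, log10_K_pA, L_pA, optics: SensorOptics) -> np.ndarray:
    params = MWCParameters.two_state(10.0**log10_K_R, 10.0**log10_K_pA, L_pA)
    return fluorescence_values(params, optics, ph)


def _three_state_params(
    K_R, K_pA, L_pA, log10_K_pAp, delta_log10_KAp, log10_L_A
) -> MWCParameters:
    K_pAp = 10.0**log10_K_pAp
    return MWCParameters(
        K_R=K_R,
        K_pA=K_pA,
        K_A=K_pA,  # class 1 drives pre-activation only
        K_Rp=K_pAp,  # class 2 drives activation only
        K_pAp=K_pAp,
        K_Ap=10.0 ** (log10_K_pAp - delta_log10_KAp),
        L_pA=L_pA,
        L_A=10.0**log10_L_A,
        constraint_flags=True,
    )


def _joint_residuals(params, optics, phf, yf, phc, yc) -> np.ndarray:
    rf = (fluorescence_values(params, optics, phf) - yf) / math.sqrt(phf.size)
    curve = active_fraction(params, phc)
    peak = max(float(np.max(curve)), 1e-300)
    rc = (curve / peak - yc) / math.sqrt(phc.size)
    return np.concatenate([rf, rc])


_LS = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000)


def _best_ls(residual, starts, lb, ub):
    best = None
    for theta0 in starts:
        sol = optimize.least_squares(residual, np.asarray(theta0, float), bounds=(lb, ub), **_LS)
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    return best[1]


# ---------------------------------------------------------------------------
# step 1: pre-activation parameters
# ---------------------------------------------------------------------------

def step1_anchor_fit(
    anchor_fluor,
    optics: SensorOptics,
    config: FitConfig = FitConfig(),
    anchor_L_pA: float | None = None,
) -> tuple[float, float]:
    """Fit (K_R, K_pA) of the two-state reduction at a fixed anchor L_pA.

    With ``anchor_L_pA=None`` a joint (L_pA, K_R, K_pA) fit is attempted
    and refused when the loss valley is flat: profiling L_pA one decade
    away from its best value and refitting the K's changes the rms misfit
    by less than the measurement-noise scale (0.01 on F/F_SDS), so the
    three constants are not jointly identifiable from one curve.
    """
    ph, y = pool_fluorescence(anchor_fluor, config.exclude_below_ph)
    _check_direction_and_amplitude(ph, y, optics)
    klo, khi = config.k_bounds_log10

    if anchor_L_pA is None:
        flat_rms_tol = 0.01  # noise scale of normalized fluorescence

        def best_rms_at(L):
            def residual2(theta):
                return _two_state_fluor(ph, theta[0] + theta[1], theta[0], L, optics) - y

            sol = _best_ls(
                residual2,
                [(k0, d0) for k0 in np.linspace(klo + 1, khi - 1, 3) for d0 in (0.3, 1.0)],
                lb=[klo, 0.0],
                ub=[khi, 4.0],
            )
            return math.sqrt(float(np.sum(sol.fun**2)) / ph.size)

        def residual3(theta):
            return _two_state_fluor(ph, theta[0] + theta[1], theta[0], 10.0 ** theta[2], optics) - y

        llo, lhi = config.l_bounds_log10
        sol = _best_ls(
            residual3,
            [(k0, 0.5, l0) for k0 in np.linspace(klo + 1, khi - 1, 3) for l0 in (1.0, 3.0)],
            lb=[klo, 0.0, llo],
            ub=[khi, 4.0, lhi],
        )
        l_best = 10.0 ** sol.x[2]
        profile = min(best_rms_at(l_best * 10.0), best_rms_at(l_best / 10.0))
        if profile < flat_rms_tol:
            raise IdentifiabilityError(
                "joint (L_pA, K_R, K_pA) fit of a single two-state curve is "
                f"under-determined: moving L_pA a decade off its optimum and "
                f"refitting the K's leaves an rms misfit of {profile:.2e} "
                f"(< noise scale {flat_rms_tol:g}); anchor L_pA and refit"
            )
        return 10.0 ** (sol.x[0] + sol.x[1]), 10.0 ** sol.x[0]

    L = float(anchor_L_pA)

    def residual(theta):  # theta = (log10 K_pA, log10 K_R/K_pA >= 0)
        return _two_state_fluor(ph, theta[0] + theta[1], theta[0], L, optics) - y

    sol = _best_ls(
        residual,
        [(k0, d0) for k0 in np.linspace(klo + 1, khi - 1, 4) for d0 in (0.3, 1.0)],
        lb=[klo, 0.0],
        ub=[khi, 4.0],
    )
    log_kpa, delta = sol.x
    return 10.0 ** (log_kpa + delta), 10.0**log_kpa  # (K_R, K_pA), K_R >= K_pA


def step1_fit_lpa(
    fluor,
    optics: SensorOptics,
    K_R: float,
    K_pA: float,
    config: FitConfig = FitConfig(),
) -> float:
    """Fit a construct's L_pA with the class-1 affinities held fixed."""
    ph, y = pool_fluorescence(fluor, config.exclude_below_ph)
    _check_direction_and_amplitude(ph, y, optics)
    lkr, lkpa = math.log10(K_R), math.log10(K_pA)

    def sse(log10_l):
        r = _two_state_fluor(ph, lkr, lkpa, 10.0**log10_l, optics) - y
        return float(np.sum(r**2))

    lo, hi = config.l_bounds_log10
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(10.0**res.x)


# ---------------------------------------------------------------------------
# step 2: activation parameters
# ---------------------------------------------------------------------------

def step2_activation_fit(
    sensor_fluor,
    sensor_current,
    K_R: float,
    K_pA: float,
    L_pA: float,
    optics: SensorOptics,
    config: FitConfig = FitConfig(),
) -> tuple[MWCParameters, float]:
    """Fit the activation site class (K_Rp = K_pAp > K_Ap) and L_A.

    Joint least squares on the sensor's fluorescence and normalized-current
    curves with equal modality weight.  Returns the full three-state
    parameter set and the per-point RSS of the joint fit.

    Because tied pA/A fluorescence intensities leave the activation branch
    under-determined, the primed-site affinities default to the configured
    constants (the same role the hand-chosen activation constants play in
    manual fits) and only L_A is estimated; setting them to None fits the
    full branch and accepts the flat valley.
    """
    phf, yf = pool_fluorescence(sensor_fluor, config.exclude_below_ph)
    phc, yc = pool_currents(sensor_current)
    klo, khi = config.k_bounds_log10
    llo, lhi = config.l_bounds_log10

    if config.K_pAp_fixed is None and config.K_Ap_fixed is not None:
        raise ValueError("K_Ap_fixed without K_pAp_fixed is not supported")

    # assemble the free-parameter vector: optionally log10 L_pA, then the
    # unfixed activation constants, then log10 L_A
    refine = config.refine_L_pA
    lpa0 = math.log10(L_pA)

    def unpack(theta):
        i = 0
        lpa = 10.0 ** theta[0] if refine else L_pA
        i += int(refine)
        if config.K_pAp_fixed is not None and config.K_Ap_fixed is not None:
            kp = math.log10(config.K_pAp_fixed)
            d = kp - math.log10(config.K_Ap_fixed)
            if d <= 0:
                raise ValueError("fixed affinities must satisfy K_pAp > K_Ap")
        elif config.K_pAp_fixed is not None:
            kp = math.log10(config.K_pAp_fixed)
            d = theta[i]
            i += 1
        else:
            kp = theta[i]
            d = theta[i + 1]
            i += 2
        return _three_state_params(K_R, K_pA, lpa, kp, d, theta[i])

    def residual(theta):
        return _joint_residuals(unpack(theta), optics, phf, yf, phc, yc)

    la_starts = (1.0, 3.0, 5.0)
    head = [(lpa0,)] if refine else [()]
    head_lb = [max(llo, lpa0 - 2.0)] if refine else []
    head_ub = [min(lhi, lpa0 + 2.0)] if refine else []
    if config.K_pAp_fixed is not None and config.K_Ap_fixed is not None:
        starts = [h + (la,) for h in head for la in la_starts]
        lb, ub = head_lb + [llo], head_ub + [lhi]
    elif config.K_pAp_fixed is not None:
        starts = [h + (d, la) for h in head for d in (0.5, 1.0, 2.0) for la in la_starts]
        lb, ub = head_lb + [0.02, llo], head_ub + [6.0, lhi]
    else:
        starts = [
            h + (kp, d, la)
            for h in head
            for kp in (-7.0, -6.0, -5.0, -4.0)
            for d in (0.5, 1.5)
            for la in la_starts
        ]
        lb, ub = head_lb + [klo, 0.02, llo], head_ub + [khi, 6.0, lhi]
    sol = _best_ls(residual, starts, lb=lb, ub=ub)
    params = unpack(sol.x)
    n_points = phf.size + phc.size
    rss_per_point = float(np.sum(sol.fun**2))  # residuals already 1/sqrt(n)-scaled
    try:
        sep = half_transition_ph(params, "fluorescence-amplitude", optics) - half_transition_ph(
            params, "a"
        )
        if abs(sep) < 0.1:
            warnings.warn(
                "fluorescence and current midpoints differ by < 0.1 pH; the "
                "two-site model is over-parameterized for these data",
                RuntimeWarning,
                stacklevel=2,
            )
    except ValueError:
        pass
    return params, rss_per_point / 2.0  # mean of the two per-modality MSEs


# ---------------------------------------------------------------------------
# mutant multipliers
# ---------------------------------------------------------------------------

def fit_mutant_multipliers(
    mutant_fluor,
    mutant_current,
    sensor: SensorModel,
    config: FitConfig = FitConfig(),
    construct: str | None = None,
) -> MutantPhenotype:
    """Fit a mutant by adjusting only its isomerization constants.

    With current data, (f_L_pA, f_L_A) are fitted jointly in log space;
    without (non-functional construct), the two-state reduction fits
    f_L_pA alone and no activation factor is reported.  Fits whose
    per-point RSS exceeds 3x the sensor's (with a small floor) are flagged
    "poor".
    """
    if mutant_fluor is None:
        raise ValueError("fluorescence data are required to fit a mutant")
    name = construct or _as_list(mutant_fluor)[0].construct
    phf, yf = pool_fluorescence(mutant_fluor, config.exclude_below_ph)
    flo, fhi = config.factor_bounds_log10
    base = sensor.params

    if mutant_current is None:
        def residual(theta):
            params = MWCParameters.two_state(base.K_R, base.K_pA, base.L_pA * 10.0 ** theta[0])
            return fluorescence_values(params, sensor.optics, phf) - yf

        sol = _best_ls(residual, [(0.0,), (2.0,), (4.0,)], lb=[flo], ub=[fhi])
        f_lpa = float(10.0 ** sol.x[0])
        rss = float(np.sum(sol.fun**2))
        rss_pp = rss / phf.size
        quality = "two-state-only"
        if rss_pp > max(3.0 * sensor.rss_per_point, config.poor_rss_floor):
            quality = "poor"
        return MutantPhenotype(
            construct=name,
            L_pA=base.L_pA * f_lpa,
            L_A=None,
            f_L_pA=f_lpa,
            f_L_A=None,
            rss=rss,
            n_points=int(phf.size),
            quality=quality,
        )

    phc, yc = pool_currents(mutant_current)

    def residual(theta):
        params = base.with_multipliers(10.0 ** theta[0], 10.0 ** theta[1])
        return _joint_residuals(params, sensor.optics, phf, yf, phc, yc)

    starts = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (0.0, 2.0), (2.0, 0.0)]
    sol = _best_ls(residual, starts, lb=[flo, flo], ub=[fhi, fhi])
    f_lpa, f_la = (float(10.0**v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    rss_pp = rss / 2.0  # residuals are 1/sqrt(n)-scaled per modality
    quality = "ok"
    if rss_pp > max(3.0 * sensor.rss_per_point, config.poor_rss_floor):
        quality = "poor"
    return MutantPhenotype(
        construct=name,
        L_pA=base.L_pA * f_lpa,
        L_A=base.L_A * f_la,
        f_L_pA=f_lpa,
        f_L_A=f_la,
        rss=rss,
        n_points=int(phf.size + phc.size),
        quality=quality,
    )


# ---------------------------------------------------------------------------
# whole-panel chain and anchor sensitivity
# ---------------------------------------------------------------------------

def _split(series_list):
    fluor = [s for s in series_list if s.modality == "fluorescence"]
    curr = [s for s in series_list if s.modality == "current"]
    return fluor or None, curr or None


def fit_panel(
    panel: dict[str, list[TitrationSeries]],
    roster: PanelRoster,
    config: FitConfig = FitConfig(),
    anchor_L_pA: float | None = None,
) -> PanelFit:
    """Run the full stepwise chain on one sensor's panel of constructs."""
    anchor = config.anchor_L_pA if anchor_L_pA is None else float(anchor_L_pA)
    if anchor <= 0:
        raise ValueError("anchor must be positive")
    anchor_fluor, _ = _split(panel[roster.anchor_mutant])
    K_R, K_pA = step1_anchor_fit(anchor_fluor, roster.optics, config, anchor_L_pA=anchor)

    sensor_fluor, sensor_curr = _split(panel[roster.sensor])
    if sensor_curr is None:
        raise ValueError("the sensor construct needs current recordings")
    sensor_lpa = step1_fit_lpa(sensor_fluor, roster.optics, K_R, K_pA, config)
    sensor_params, sensor_rss = step2_activation_fit(
        sensor_fluor, sensor_curr, K_R, K_pA, sensor_lpa, roster.optics, config
    )
    sensor = SensorModel(
        construct=roster.sensor,
        params=sensor_params,
        optics=roster.optics,
        rss_per_point=sensor_rss,
    )

    phenotypes: dict[str, MutantPhenotype] = {}
    errors: dict[str, str] = {}
    for mutant in roster.mutants:
        try:
            fluor, curr = _split(panel[mutant])
            if mutant in roster.two_state_only or curr is None or not is_functional(curr):
                curr = None
            sub = replace(
                config,
                exclude_below_ph=roster.exclude_below_ph.get(mutant, config.exclude_below_ph),
            )
            phenotypes[mutant] = fit_mutant_multipliers(fluor, curr, sensor, sub, construct=mutant)
        except Exception as exc:
            errors[mutant] = str(exc)
    return PanelFit(
        anchor_L_pA=anchor,
        K_R=K_R,
        K_pA=K_pA,
        sensor=sensor,
        phenotypes=phenotypes,
        errors=errors,
    )


def sensitivity_scan(
    panel: dict[str, list[TitrationSeries]],
    roster: PanelRoster,
    config: FitConfig = FitConfig(),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Re-run the full chain for each anchor value; tabulate factors.

    Returns the per-anchor factor table and the Spearman rank correlations
    of f_L_pA and f_L_A across each anchor pair; identical mutant ordering
    across anchors gives correlations of 1.
    """
    anchors = [config.anchor_L_pA, *config.alternates]
    fits: dict[float, PanelFit] = {}
    rows = []
    for anchor in anchors:
        try:
            fits[anchor] = fit_panel(panel, roster, config, anchor_L_pA=anchor)
        except Exception as exc:
            rows.append({"anchor": anchor, "construct": "<chain>", "error": str(exc)})
    for anchor, pf in fits.items():
        for name, ph in pf.phenotypes.items():
            rows.append(
                {
                    "anchor": anchor,
                    "construct": name,
                    "f_L_pA": ph.f_L_pA,
                    "f_L_A": ph.f_L_A if ph.f_L_A is not None else np.nan,
                    "quality": ph.quality,
                }
            )
        for name, msg in pf.errors.items():
            rows.append({"anchor": anchor, "construct": name, "error": msg})
    table = pd.DataFrame(rows)

    correlations: dict[str, float] = {}
    done = list(fits)
    for i in range(len(done)):
        for j in range(i + 1, len(done)):
            a, b = done[i], done[j]
            common = [
                m
                for m in fits[a].phenotypes
                if m in fits[b].phenotypes
            ]
            for col in ("f_L_pA", "f_L_A"):
                va = [getattr(fits[a].phenotypes[m], col) for m in common]
                vb = [getattr(fits[b].phenotypes[m], col) for m in common]
                keep = [k for k in range(len(common)) if va[k] is not None and vb[k] is not None]
                if len(keep) >= 2:
                    rho = float(
                        stats.spearmanr([va[k] for k in keep], [vb[k] for k in keep]).statistic
                    )
                    correlations[f"{col}[{a:g} vs {b:g}]"] = rho
    return table, correlations


# ---------------------------------------------------------------------------
# single-site separation limit
# ---------------------------------------------------------------------------

def single_site_separation_scan(
    n_per_axis: int = 12,
    ph_grid: np.ndarray | None = None,
    amplitude_tol: float = 0.02,
    chunk: int = 20000,
) -> dict:
    """Maximum fluorescence/current midpoint separation of the one-site model.

    Exhaustive log-grid search over (K_A, K_pA/K_A, K_R/K_pA, L_pA, L_A)
    for the three-state model with a single proton-site class, keeping only
    parameter sets whose resting fraction and active fraction both sweep
    their full amplitude over pH 9 -> 0.  Because fluorescence is affine in
    the resting fraction when F_pA = F_A, the fluorescence midpoint is the
    half-crossing of R and the current midpoint the half-crossing of A.

    Returns the maximal separation in pH units (positive = fluorescence
    midpoint at higher pH) with the best parameter set; the one-site model
    tops out near a fivefold (~0.7 pH) proton-concentration separation,
    far short of the >10-fold separation two site classes reproduce.
    """
    if ph_grid is None:
        ph_grid = np.arange(9.0, -0.001, -0.05)
    h = 10.0 ** (-ph_grid)  # increasing [H+] along the grid

    lg_ka = np.linspace(-9.0, -4.0, n_per_axis)
    lg_dpa = np.linspace(0.0, 4.0, n_per_axis)  # log10 K_pA/K_A >= 0
    lg_dr = np.linspace(0.0, 4.0, n_per_axis)   # log10 K_R/K_pA >= 0
    lg_lpa = np.linspace(0.0, 8.0, n_per_axis)
    lg_la = np.linspace(0.0, 8.0, n_per_axis)
    grids = np.meshgrid(lg_ka, lg_dpa, lg_dr, lg_lpa, lg_la, indexing="ij")
    flat = np.stack([g.ravel() for g in grids], axis=1)
    n_combos = flat.shape[0]

    best_sep = -np.inf
    best_row = None
    n_valid = 0
    log_h = np.log(h)
    for start in range(0, n_combos, chunk):
        block = flat[start : start + chunk]
        ka = 10.0 ** block[:, 0]
        kpa = ka * 10.0 ** block[:, 1]
        kr = kpa * 10.0 ** block[:, 2]
        ln_lpa = block[:, 3] * math.log(10.0)
        ln_la = block[:, 4] * math.log(10.0)
        # log statistical weights, shape (m, p)
        lw_r = (ln_lpa + ln_la)[:, None] + 5.0 * np.log1p(h[None, :] / kr[:, None])
        lw_pa = ln_la[:, None] + 5.0 * np.log1p(h[None, :] / kpa[:, None])
        lw_a = 5.0 * np.log1p(h[None, :] / ka[:, None])
        top = np.maximum(np.maximum(lw_r, lw_pa), lw_a)
        w_r = np.exp(lw_r - top)
        w_pa = np.exp(lw_pa - top)
        w_a = np.exp(lw_a - top)
        denom = w_r + w_pa + w_a
        r = w_r / denom
        a = w_a / denom
        valid = (
            (r[:, 0] >= 1 - amplitude_tol)
            & (r[:, -1] <= amplitude_tol)
            & (a[:, -1] >= 1 - amplitude_tol)
            & (a[:, 0] <= amplitude_tol)
        )
        if not np.any(valid):
            continue
        n_valid += int(np.sum(valid))
        idx = np.flatnonzero(valid)
        # r decreases, a increases along the grid; locate half-crossings
        ri = np.argmax(r[idx] < 0.5, axis=1)
        ai = np.argmax(a[idx] >= 0.5, axis=1)

        def cross_ph(y, k, rising):
            y0, y1 = y[np.arange(k.size), k - 1], y[np.arange(k.size), k]
            frac = (0.5 - y0) / (y1 - y0)
            return ph_grid[k - 1] + frac * (ph_grid[k] - ph_grid[k - 1])

        ph_fluor = cross_ph(r[idx], ri, False)
        ph_curr = cross_ph(a[idx], ai, True)
        sep = ph_fluor - ph_curr
        k = int(np.argmax(sep))
        if sep[k] > best_sep:
            best_sep = float(sep[k])
            row = block[idx[k]]
            best_row = {
                "K_A": 10.0 ** row[0],
                "K_pA": 10.0 ** (row[0] + row[1]),
                "K_R": 10.0 ** (row[0] + row[1] + row[2]),
                "L_pA": 10.0 ** row[3],
                "L_A": 10.0 ** row[4],
            }
    return {
        "max_separation_ph": best_sep,
        "max_separation_fold_h": 10.0**best_sep if np.isfinite(best_sep) else np.nan,
        "n_combos": int(n_combos),
        "n_valid": int(n_valid),
        "best_params": best_row,
    }


def modality_separation(params: MWCParameters, optics: SensorOptics) -> float:
    """Fluorescence-minus-current midpoint separation of a model, pH units."""
    return half_transition_ph(params, "fluorescence-amplitude", optics) - half_transition_ph(
        params, "a"
    )
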