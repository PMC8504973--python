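"""Empirical Hill fits of pH-titration curves and their comparison logic.

Fluorescence curves are fitted as ``y = F0 + dF * x^n / (x^n + EC50^n)``
with ``x = [H+]`` and a signed amplitude dF (quenching gives dF < 0 on a
descending curve, de-quenching dF > 0); current curves as
``y = Imax * x^n / (x^n + EC50^n)``.  pH50 = -log10(EC50).

Group comparisons report Welch two-sample tests with Holm adjustment for
the mutant-vs-parent family; this is a documented stand-in for the
one-way-ANOVA/Dunnett procedure usually quoted with such tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .titration import TitrationSeries

__all__ = [
    "HillFit",
    "HillFitError",
    "BellShapedError",
    "fit_hill_fluorescence",
    "fit_hill_current",
    "delta_ph50",
    "compare_groups",
    "significance_stars",
    "hill_table",
]


class HillFitError(RuntimeError):
    """The Hill fit failed to converge; the message carries diagnostics."""


class BellShapedError(HillFitError):
    """Data deviate substantially beyond the plateau band; not fitted."""


@dataclass(frozen=True)
class HillFit:
    """Estimated Hill parameters for one titration series."""

    EC50: float
    nH: float
    F0: float | None
    dF_signed: float | None
    Imax: float | None
    rss: float
    n_points: int
    constraints: str = ""

    def __post_init__(self) -> None:
        if not self.EC50 > 0:
            raise ValueError("EC50 must be positive")

    @property
    def pH50(self) -> float:
        return -math.log10(self.EC50)

    @property
    def dF_max(self) -> float | None:
        """Amplitude as reported in summary tables: absolute value."""
        return None if self.dF_signed is None else abs(self.dF_signed)

    def to_dict(self) -> dict:
        return {
            "EC50": self.EC50,
            "pH50": self.pH50,
            "nH": self.nH,
            "F0": self.F0,
            "dF_signed": self.dF_signed,
            "dF_max": self.dF_max,
            "Imax": self.Imax,
            "rss": self.rss,
            "n_points": self.n_points,
            "constraints": self.constraints,
        }


def _hill_x(series: TitrationSeries, exclude_below_ph: float | None) -> tuple[np.ndarray, np.ndarray, int]:
    pts = series.test_points()
    ph, y = pts.ph, pts.response
    excluded = 0
    if exclude_below_ph is not None:
        keep = ph >= exclude_below_ph
        excluded = int(np.sum(~keep))
        ph, y = ph[keep], y[keep]
    if ph.size < 4:
        raise HillFitError(f"only {ph.size} points after exclusions; need >= 4")
    return 10.0 ** (-ph), y, excluded


def _check_bell(ph: np.ndarray, y: np.ndarray) -> None:
    """Flag non-monotone (bell-shaped) data: a saturating curve keeps its
    interior within the band spanned by the two end plateaus, so a large
    interior excursion beyond that band on either side marks a bell."""
    order = np.argsort(ph)
    y_sorted = y[order]
    hi_plateau = float(np.mean(y_sorted[-2:]))   # high-pH end
    lo_plateau = float(np.mean(y_sorted[:2]))    # low-pH end
    inner = y_sorted[2:-2]
    if inner.size == 0:
        return
    steps = np.diff(y_sorted)
    noise = 1.4826 * float(np.median(np.abs(steps - np.median(steps)))) / math.sqrt(2)
    span = float(np.max(y)) - float(np.min(y)) + 1e-30
    dev_above = float(np.max(inner)) - max(hi_plateau, lo_plateau)
    dev_below = min(hi_plateau, lo_plateau) - float(np.min(inner))
    excursion = max(dev_above, dev_below)
    if excursion > 3 * noise and excursion > 0.25 * span:
        raise BellShapedError(
            "interior response deviates beyond the plateau band by "
            f"{excursion:.3g} (> 25% of the {span:.3g} span): bell-shaped "
            "curve, not fitted"
        )


_LS_OPTS = dict(method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)


def _multi_start(residual, build_theta, x, fix_nH):
    """Trust-region least squares from >= 5 starts over log-spaced EC50."""
    log_lo, log_hi = math.log10(float(np.min(x))), math.log10(float(np.max(x)))
    ec_starts = np.linspace(log_lo, log_hi, 5)
    nh_starts = [1.5] if fix_nH is not None else [0.8, 1.5, 2.5]
    best = None
    failures = []
    for lec in ec_starts:
        for nh0 in nh_starts:
            theta0, lb, ub = build_theta(lec, nh0)
            try:
                sol = optimize.least_squares(residual, theta0, bounds=(lb, ub), **_LS_OPTS)
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            rss = float(np.sum(sol.fun**2))
            nh_val = fix_nH if fix_nH is not None else sol.x[1]
            key = (rss, nh_val)
            if sol.success and (best is None or key < best[0]):
                best = (key, sol)
    if best is None:
        raise HillFitError(
            "Hill fit did not converge from any of the "
            f"{len(ec_starts) * len(nh_starts)} starts; diagnostics: {failures!r}"
        )
    return best[1]


def fit_hill_fluorescence(
    series: TitrationSeries,
    fix_nH: float | None = None,
    nH_upper_bound: float | None = None,
    exclude_below_ph: float | None = None,
) -> HillFit:
    """Least-squares Hill fit of a normalized fluorescence series.

    ``exclude_below_ph=3.5`` drops the very-acidic points that move in the
    direction opposite to the quenching curve in some constructs.  The Hill
    exponent may be fixed or bounded above, matching published table
    conventions for poorly constrained steep curves.
    """
    if series.modality != "fluorescence":
        raise ValueError("expected a fluorescence series")
    if series.f_sds is not None and not series.normalized:
        raise ValueError("series carries raw counts; normalize to F/F_SDS first")
    x, y, n_excluded = _hill_x(series, exclude_below_ph)
    _check_bell(-np.log10(x), y)

    nh_hi = nH_upper_bound if nH_upper_bound is not None else 10.0
    f0_guess = float(y[np.argmin(x)])
    df_guess = float(y[np.argmax(x)]) - f0_guess

    def build_theta(lec, nh0):
        if fix_nH is not None:
            theta0 = [lec, f0_guess, df_guess]
            lb = [-12.0, -np.inf, -np.inf]
            ub = [0.0, np.inf, np.inf]
        else:
            theta0 = [lec, min(nh0, nh_hi * 0.95), f0_guess, df_guess]
            lb = [-12.0, 0.05, -np.inf, -np.inf]
            ub = [0.0, nh_hi, np.inf, np.inf]
        return np.array(theta0), np.array(lb), np.array(ub)

    def model(theta):
        if fix_nH is not None:
            lec, f0, df = theta
            nh = fix_nH
        else:
            lec, nh, f0, df = theta
        # x^n/(x^n+EC50^n) as a logistic in log[H+]; overflow-safe
        frac = expit(nh * (np.log(x) - lec * math.log(10.0)))
        return f0 + df * frac

    sol = _multi_start(lambda t: model(t) - y, build_theta, x, fix_nH)
    if fix_nH is not None:
        lec, f0, df = sol.x
        nh = float(fix_nH)
    else:
        lec, nh, f0, df = sol.x
    notes = []
    if fix_nH is not None:
        notes.append(f"nH fixed at {fix_nH:g}")
    if nH_upper_bound is not None:
        notes.append(f"nH bounded above by {nH_upper_bound:g}")
    if n_excluded:
        notes.append(f"{n_excluded} point(s) below pH {exclude_below_ph:g} excluded")
    return HillFit(
        EC50=10.0**lec,
        nH=float(nh),
        F0=float(f0),
        dF_signed=float(df),
        Imax=None,
        rss=float(np.sum(sol.fun**2)),
        n_points=int(x.size),
        constraints="; ".join(notes),
    )


def fit_hill_current(
    series: TitrationSeries,
    fix_nH: float | None = None,
    nH_upper_bound: float | None = None,
) -> HillFit:
    """Least-squares Hill fit of a rundown-corrected, normalized current series."""
    if series.modality != "current":
        raise ValueError("expected a current series")
    x, y, _ = _hill_x(series, None)
    if float(np.max(np.abs(y))) <= 0.0:
        raise HillFitError("all responses are zero: non-functional construct")

    nh_hi = nH_upper_bound if nH_upper_bound is not None else 10.0
    imax_guess = max(float(np.max(y)), 1e-6)

    def build_theta(lec, nh0):
        if fix_nH is not None:
            theta0 = [lec, imax_guess]
            lb = [-12.0, 1e-12]
            ub = [0.0, np.inf]
        else:
            theta0 = [lec, min(nh0, nh_hi * 0.95), imax_guess]
            lb = [-12.0, 0.05, 1e-12]
            ub = [0.0, nh_hi, np.inf]
        return np.array(theta0), np.array(lb), np.array(ub)

    def model(theta):
        if fix_nH is not None:
            lec, imax = theta
            nh = fix_nH
        else:
            lec, nh, imax = theta
        return imax * expit(nh * (np.log(x) - lec * math.log(10.0)))

    sol = _multi_start(lambda t: model(t) - y, build_theta, x, fix_nH)
    if fix_nH is not None:
        lec, imax = sol.x
        nh = float(fix_nH)
    else:
        lec, nh, imax = sol.x
    notes = []
    if fix_nH is not None:
        notes.append(f"nH fixed at {fix_nH:g}")
    if nH_upper_bound is not None:
        notes.append(f"nH bounded above by {nH_upper_bound:g}")
    return HillFit(
        EC50=10.0**lec,
        nH=float(nh),
        F0=None,
        dF_signed=None,
        Imax=float(imax),
        rss=float(np.sum(sol.fun**2)),
        n_points=int(x.size),
        constraints="; ".join(notes),
    )


def delta_ph50(fit_a: HillFit, fit_b: HillFit) -> float:
    """Signed midpoint shift fit_a.pH50 - fit_b.pH50 (mutant minus parent)."""
    return fit_a.pH50 - fit_b.pH50


def significance_stars(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return "ND"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(
    panel: dict,
    design: str = "vs-parent",
    reference: str | None = None,
) -> pd.DataFrame:
    """Compare per-replicate pH50 groups.

    ``design='vs-parent'``: ``panel`` maps construct -> array of per-replicate
    pH50s; every group is tested against the ``reference`` group (default:
    first key) by Welch's t-test, with Holm adjustment across the family.

    ``design='fluor-vs-electro'``: ``panel`` maps construct -> mapping with
    keys ``fluorescence`` and ``current``; unpaired Welch two-tailed tests
    per construct, no family adjustment.

    Groups with a single replicate get their difference reported and the
    test marked ND.  The Welch+Holm procedure is a documented stand-in for
    ANOVA with Dunnett's multiple comparisons.
    """
    rows = []
    if design == "vs-parent":
        keys = list(panel.keys())
        if reference is None:
            reference = keys[0]
        ref = np.asarray(panel[reference], dtype=float)
        p_raw, testable = [], []
        for name in keys:
            if name == reference:
                continue
            grp = np.asarray(panel[name], dtype=float)
            delta = float(np.mean(grp) - np.mean(ref))
            if grp.size >= 2 and ref.size >= 2:
                p = float(stats.ttest_ind(grp, ref, equal_var=False).pvalue)
                testable.append(len(rows))
                p_raw.append(p)
            else:
                p = None
            rows.append(
                {
                    "group": name,
                    "vs": reference,
                    "n": int(grp.size),
                    "mean": float(np.mean(grp)),
                    "sd": float(np.std(grp, ddof=1)) if grp.size > 1 else np.nan,
                    "delta": delta,
                    "p_raw": p if p is not None else np.nan,
                    "p_adj": np.nan,
                }
            )
        if p_raw:
            adj = multipletests(p_raw, method="holm")[1]
            for i, idx in enumerate(testable):
                rows[idx]["p_adj"] = float(adj[i])
        df = pd.DataFrame(rows)
        df["stars"] = [
            significance_stars(p if np.isfinite(p) else None) for p in df["p_adj"]
        ]
    elif design == "fluor-vs-electro":
        for name, groups in panel.items():
            a = np.asarray(groups["fluorescence"], dtype=float)
            b = np.asarray(groups["current"], dtype=float)
            delta = float(np.mean(a) - np.mean(b))
            if a.size >= 2 and b.size >= 2:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                p = None
            rows.append(
                {
                    "group": name,
                    "vs": "current",
                    "n": int(min(a.size, b.size)),
                    "mean": float(np.mean(a)),
                    "sd": float(np.std(a, ddof=1)) if a.size > 1 else np.nan,
                    "delta": delta,
                    "p_raw": p if p is not None else np.nan,
                    "p_adj": p if p is not None else np.nan,
                }
            )
        df = pd.DataFrame(rows)
        df["stars"] = [
            significance_stars(p if np.isfinite(p) else None) for p in df["p_adj"]
        ]
    else:
        raise ValueError(f"unknown design {design!r}")
    df.attrs["method"] = (
        "Welch two-sample t-tests; Holm adjustment for the vs-parent family "
        "(stand-in for one-way ANOVA with Dunnett's multiple comparisons)"
    )
    return df


def hill_table(
    fits: dict[tuple[str, str], list[HillFit]],
    parent: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Summary table of per-replicate Hill fits, one row per construct/modality.

    ``fits`` maps (construct, modality) -> list of per-replicate fits;
    ``parent`` maps construct -> parent construct for the dpH50 column.
    """
    rows = []
    means = {
        key: float(np.mean([f.pH50 for f in group])) for key, group in fits.items()
    }
    for (construct, modality), group in fits.items():
        ph50s = np.array([f.pH50 for f in group])
        nhs = np.array([f.nH for f in group])
        row = {
            "construct": construct,
            "modality": modality,
            "pH50_mean": float(np.mean(ph50s)),
            "pH50_sd": float(np.std(ph50s, ddof=1)) if ph50s.size > 1 else np.nan,
            "nH_mean": float(np.mean(nhs)),
            "nH_sd": float(np.std(nhs, ddof=1)) if nhs.size > 1 else np.nan,
            "n": int(len(group)),
        }
        if modality == "fluorescence":
            row["F0"] = float(np.mean([f.F0 for f in group]))
            row["dF_max"] = float(np.mean([f.dF_max for f in group]))
        else:
            row["F0"] = np.nan
            row["dF_max"] = np.nan
        parent_name = (parent or {}).get(construct)
        if parent_name is not None and (parent_name, modality) in means:
            row["dpH50_vs_parent"] = row["pH50_mean"] - means[(parent_name, modality)]
        else:
            row["dpH50_vs_parent"] = np.nan
        other = "current" if modality == "fluorescence" else "fluorescence"
        if modality == "fluorescence" and (construct, other) in means:
            row["dpH50_fluor_vs_electro"] = row["pH50_mean"] - means[(construct, other)]
        else:
            row["dpH50_fluor_vs_electro"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
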