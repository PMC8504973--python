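"""Seeded generator of synthetic titration panels.

Emulates the statistical structure of the study's raw data so that every
pipeline stage is testable without measurements: per-replicate fluorescence
series on a pH 8 -> 3 grid with additive Gaussian noise around a Hill or
MWC truth (raw counts scaled by a per-replicate F_SDS), and oocyte current
recordings with interleaved reference applications and multiplicative
rundown.

Randomness: one seed per panel; each series draws from an independent
stream keyed by a CRC of its (construct, modality, replicate) label, so
generated values do not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .allosteric import (
    TWO_STATE_LA,
    MWCParameters,
    SensorOptics,
    current_response,
    fluorescence_response,
)
from .titration import TitrationSeries

__all__ = [
    "HillTruth",
    "GeneratorSpec",
    "generate_fluorescence_panel",
    "generate_current_recording",
    "generate_current_panel",
    "generate_mutant_panel",
    "NON_FUNCTIONAL",
]

#: Sentinel multiplier marking a construct with no measurable current.
NON_FUNCTIONAL = float("inf")


@dataclass(frozen=True)
class HillTruth:
    """Hill-equation ground truth; [H+] is the dose variable."""

    pH50: float
    nH: float
    F0: float = 0.70
    dF_signed: float = -0.40
    Imax: float = 1.0

    def fluorescence(self, ph: np.ndarray) -> np.ndarray:
        frac = self._frac(ph)
        return self.F0 + self.dF_signed * frac

    def current(self, ph: np.ndarray) -> np.ndarray:
        return self.Imax * self._frac(ph)

    def _frac(self, ph: np.ndarray) -> np.ndarray:
        z = self.nH * (self.pH50 - np.asarray(ph, dtype=float)) * np.log(10.0)
        return 1.0 / (1.0 + np.exp(-z))


def default_ph_grid() -> np.ndarray:
    """The study-like 11-point grid from pH 8.0 to 3.0."""
    return np.linspace(8.0, 3.0, 11)


@dataclass
class GeneratorSpec:
    """Conditions of a synthetic titration experiment.

    ``truth`` selects the ground-truth model: a :class:`HillTruth` or an
    (MWCParameters, SensorOptics) pair via ``params``/``optics``.  Noise is
    additive Gaussian on the normalized scale.  Current-mode extras follow
    the recording protocol: a reference pH applied at both ends and every
    ``reference_every`` test applications, and a linear multiplicative
    rundown reaching ``1 - rundown_total`` by the last application.
    ``artifact_amplitude`` adds an opposite-direction deviation to points
    below pH 3.5, to exercise the fitting exclusion rule.
    """

    truth: str = "mwc"  # "hill" | "mwc"
    hill: HillTruth | None = None
    params: MWCParameters | None = None
    optics: SensorOptics | None = None
    ph_grid: np.ndarray = field(default_factory=default_ph_grid)
    sigma: float = 0.02
    replicates: int = 3
    seed: int = 0
    f_sds: float = 1200.0
    rep_scale_sd: float = 0.05
    artifact_amplitude: float = 0.0
    rundown_total: float = 0.2
    reference_ph: float = 5.0
    reference_every: int = 3
    current_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.truth not in ("hill", "mwc"):
            raise ValueError(f"unknown truth model {self.truth!r}")
        if self.truth == "hill" and self.hill is None:
            raise ValueError("truth='hill' requires a HillTruth")
        if self.truth == "mwc" and self.params is None:
            raise ValueError("truth='mwc' requires MWCParameters")
        if not 0 <= self.rundown_total < 1:
            raise ValueError("rundown_total must lie in [0, 1)")
        if self.reference_every < 1:
            raise ValueError("reference_every must be >= 1")

    # -- ground truth on the normalized scale -------------------------------
    def truth_fluorescence(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        if self.truth == "hill":
            return self.hill.fluorescence(ph)
        if self.optics is None:
            raise ValueError("MWC fluorescence truth requires optics")
        return fluorescence_response(self.params, self.optics, ph).values

    def truth_current(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        if self.truth == "hill":
            return self.hill.current(ph)
        # evaluate normalization on a wide grid so single-point queries are
        # on the same scale as full curves
        wide = np.linspace(9.0, 0.0, 181)
        curve = current_response(self.params, wide, normalization="max")
        return np.interp(ph, wide[::-1], curve.values[::-1])


def _series_rng(spec: GeneratorSpec, construct: str, modality: str, replicate: str):
    key = zlib.crc32(f"{construct}|{modality}|{replicate}".encode())
    return np.random.default_rng([spec.seed, key])


def _artifact(spec: GeneratorSpec, ph: np.ndarray, truth: np.ndarray) -> np.ndarray:
    if spec.artifact_amplitude == 0:
        return np.zeros_like(truth)
    direction = -np.sign(truth[-1] - truth[0]) if truth[-1] != truth[0] else 1.0
    out = np.zeros_like(truth)
    out[ph < 3.5] = direction * spec.artifact_amplitude
    return out


def generate_fluorescence_panel(spec: GeneratorSpec, construct: str = "sensor") -> list[TitrationSeries]:
    """Per-replicate raw fluorescence series (counts; F_SDS recorded).

    The per-replicate scale factor (protein amount) multiplies counts and
    F_SDS alike, so normalization recovers the noisy normalized truth; with
    sigma = 0 the normalized output equals the truth model exactly.
    """
    ph = np.asarray(spec.ph_grid, dtype=float)
    truth = spec.truth_fluorescence(ph) + _artifact(spec, ph, spec.truth_fluorescence(ph))
    out = []
    for r in range(spec.replicates):
        replicate = f"rep{r + 1}"
        rng = _series_rng(spec, construct, "fluorescence", replicate)
        scale = spec.f_sds * float(np.exp(rng.normal(0.0, spec.rep_scale_sd)))
        noisy = truth + rng.normal(0.0, spec.sigma, size=ph.size) if spec.sigma > 0 else truth
        out.append(
            TitrationSeries(
                construct=construct,
                modality="fluorescence",
                replicate=replicate,
                order=np.arange(ph.size),
                ph=ph,
                response=noisy * scale,
                is_reference=np.zeros(ph.size, dtype=bool),
                f_sds=scale,
                provenance=[f"synthetic ({spec.truth} truth, sigma={spec.sigma:g}, seed={spec.seed})"],
            )
        )
    return out


def generate_current_recording(
    spec: GeneratorSpec, construct: str = "sensor", replicate: str = "rep1"
) -> TitrationSeries:
    """One oocyte recording: interleaved references, multiplicative rundown.

    Applications run reference-first, a reference every
    ``reference_every`` test applications, and a closing reference; the
    rundown factor declines linearly from 1 at the first application to
    ``1 - rundown_total`` at the last.
    """
    test_ph = np.asarray(spec.ph_grid, dtype=float)
    if spec.reference_every > test_ph.size:
        raise ValueError(
            f"reference spacing {spec.reference_every} exceeds the number of "
            f"test applications {test_ph.size}"
        )
    ph_seq, ref_seq = [spec.reference_ph], [True]
    for i, p in enumerate(test_ph):
        ph_seq.append(float(p))
        ref_seq.append(False)
        if (i + 1) % spec.reference_every == 0 and i != test_ph.size - 1:
            ph_seq.append(spec.reference_ph)
            ref_seq.append(True)
    ph_seq.append(spec.reference_ph)
    ref_seq.append(True)
    ph_arr = np.array(ph_seq)
    ref_arr = np.array(ref_seq)
    n_app = ph_arr.size
    factor = 1.0 - spec.rundown_total * np.arange(n_app) / (n_app - 1)
    truth = spec.truth_current(ph_arr)
    rng = _series_rng(spec, construct, "current", replicate)
    noise = rng.normal(0.0, spec.sigma, size=n_app) if spec.sigma > 0 else np.zeros(n_app)
    response = (truth * factor + noise) * spec.current_scale
    return TitrationSeries(
        construct=construct,
        modality="current",
        replicate=replicate,
        order=np.arange(n_app),
        ph=ph_arr,
        response=response,
        is_reference=ref_arr,
        provenance=[
            f"synthetic recording ({spec.truth} truth, rundown={spec.rundown_total:g}, "
            f"ref pH {spec.reference_ph:g} every {spec.reference_every}, seed={spec.seed})"
        ],
    )


def generate_current_panel(spec: GeneratorSpec, construct: str = "sensor") -> list[TitrationSeries]:
    return [
        generate_current_recording(spec, construct, f"rep{r + 1}")
        for r in range(spec.replicates)
    ]


def generate_mutant_panel(
    sensor_params: MWCParameters,
    optics: SensorOptics,
    multiplier_map: Mapping[str, tuple[float, float]],
    spec: GeneratorSpec,
    sensor_name: str = "sensor",
) -> dict[str, list[TitrationSeries]]:
    """Panel of constructs derived from a sensor by L multipliers.

    Each construct's truth is the sensor parameter set with L_pA and L_A
    multiplied by its (f_L_pA, f_L_A); both modalities are emitted.  A
    construct with ``f_L_A = inf`` (NON_FUNCTIONAL sentinel) is generated
    from the two-state reduction in fluorescence and emits pure-noise
    currents around zero.
    """
    panel: dict[str, list[TitrationSeries]] = {}
    entries = {sensor_name: (1.0, 1.0), **dict(multiplier_map)}
    for construct, (f_lpa, f_la) in entries.items():
        if f_lpa <= 0 or (f_la <= 0 and not np.isinf(f_la)):
            raise ValueError(f"{construct}: multipliers must be positive")
        non_functional = np.isinf(f_la)
        if non_functional:
            truth_params = replace(
                sensor_params, L_pA=sensor_params.L_pA * f_lpa, L_A=TWO_STATE_LA
            )
        else:
            truth_params = sensor_params.with_multipliers(f_lpa, f_la)
        sub = replace_spec(spec, truth="mwc", params=truth_params, optics=optics)
        if not non_functional:
            # the recording protocol picks a reference solution in the middle
            # of the construct's response range; emulate by snapping the
            # reference pH to the grid point nearest the half-maximal current
            grid = np.asarray(spec.ph_grid, dtype=float)
            half_gap = np.abs(sub.truth_current(grid) - 0.5)
            sub = replace_spec(sub, reference_ph=float(grid[int(np.argmin(half_gap))]))
        series = generate_fluorescence_panel(sub, construct=construct)
        if non_functional:
            for r in range(spec.replicates):
                replicate = f"rep{r + 1}"
                rng = _series_rng(spec, construct, "current", replicate)
                ph = np.asarray(spec.ph_grid, dtype=float)
                noise = rng.normal(0.0, spec.sigma, size=ph.size) if spec.sigma > 0 else np.zeros(ph.size)
                series.append(
                    TitrationSeries(
                        construct=construct,
                        modality="current",
                        replicate=replicate,
                        order=np.arange(ph.size),
                        ph=ph,
                        response=noise * spec.current_scale,
                        is_reference=np.zeros(ph.size, dtype=bool),
                        provenance=["synthetic non-functional construct (zero current + noise)"],
                    )
                )
        else:
            series.extend(generate_current_panel(sub, construct=construct))
        panel[construct] = series
    return panel


def replace_spec(spec: GeneratorSpec, **kwargs) -> GeneratorSpec:
    """Dataclass replace that tolerates the mutable default grid."""
    return replace(spec, **kwargs)
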