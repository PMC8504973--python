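"""Normalization and correction of raw titration data.

Three corrections bring raw recordings onto the scales the models are
fitted on:

* fluorescence is divided by the denatured-protein value F_SDS,
* oocyte peak currents are corrected for rundown using interleaved
  reference applications,
* a construct whose resting-state fluorescence is itself altered can be
  affinely re-mapped onto its parent sensor's fitted plateau range.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .titration import TitrationSeries

__all__ = ["normalize_fluorescence", "rundown_correct", "renormalize_to_reference"]


def normalize_fluorescence(series: TitrationSeries) -> TitrationSeries:
    """Divide raw fluorescence by F_SDS, yielding the F/F_SDS scale."""
    if series.modality != "fluorescence":
        raise ValueError("normalize_fluorescence applies to fluorescence series only")
    if series.normalized:
        raise ValueError("series is already normalized (idempotence guard)")
    if series.f_sds is None or series.f_sds <= 0:
        raise ValueError("F_SDS must be present and positive")
    out = replace(
        series,
        response=series.response / series.f_sds,
        normalized=True,
        provenance=list(series.provenance) + [f"normalized by F_SDS={series.f_sds:g}"],
    )
    return out


def rundown_correct(series: TitrationSeries, interpolation: str = "linear") -> TitrationSeries:
    """Correct peak currents for rundown using reference applications.

    Each reference response, expressed relative to the first reference,
    gives the rundown factor at its application index; the factor at test
    applications is interpolated in application index, piecewise-linearly
    by default or exponentially (linear in log factor) behind a flag.
    Test responses are divided by the factor; references are dropped from
    the output.
    """
    if series.modality != "current":
        raise ValueError("rundown_correct applies to current series only")
    if interpolation not in ("linear", "exponential"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    ref_mask = series.is_reference
    ref_idx = series.order[ref_mask]
    ref_resp = series.response[ref_mask]
    if ref_idx.size < 2:
        raise ValueError("need at least 2 reference applications to interpolate rundown")
    if np.any(ref_resp <= 0):
        raise ValueError("reference responses must be positive")
    test_idx = series.order[~ref_mask]
    if test_idx.min() < ref_idx.min() or test_idx.max() > ref_idx.max():
        raise ValueError("reference applications must bracket all test applications")
    factors = ref_resp / ref_resp[0]
    if interpolation == "linear":
        interp = np.interp(test_idx, ref_idx, factors)
    else:
        interp = np.exp(np.interp(test_idx, ref_idx, np.log(factors)))
    keep = ~ref_mask
    out = replace(
        series,
        order=series.order[keep],
        ph=series.ph[keep],
        response=series.response[keep] / interp,
        is_reference=series.is_reference[keep],
        provenance=list(series.provenance)
        + [f"rundown-corrected ({interpolation}) using {ref_idx.size} references"],
    )
    return out


def renormalize_to_reference(target: TitrationSeries, reference: TitrationSeries):
    """Affinely map a series onto its parent's fitted plateau range.

    Both series are Hill-fitted; the target response is mapped by
    ``y -> a*y + b`` with ``a = dF_ref/dF_target`` and ``b`` matching the
    baseline plateaus, so the target's plateau-to-plateau range overlays
    the reference's.  Used for constructs whose resting-state fluorescence
    is itself altered by the mutation.  Returns the remapped series; the
    coefficients are recorded in its provenance.
    """
    from .hill import fit_hill_fluorescence  # deferred: hill does not import prep

    if target.modality != reference.modality:
        raise ValueError("target and reference must share a modality")
    fit_t = fit_hill_fluorescence(target)
    fit_r = fit_hill_fluorescence(reference)
    if fit_r.dF_signed == 0:
        raise ValueError("reference has zero fitted amplitude; renormalization degenerate")
    if fit_t.dF_signed == 0:
        raise ValueError("target has zero fitted amplitude; renormalization degenerate")
    a = fit_r.dF_signed / fit_t.dF_signed
    b = fit_r.F0 - a * fit_t.F0
    out = replace(
        target,
        response=a * target.response + b,
        provenance=list(target.provenance)
        + [
            f"renormalized to {reference.construct}: y -> {a:.6g}*y + {b:.6g} "
            "(fitted plateau-to-plateau match)"
        ],
    )
    return out
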