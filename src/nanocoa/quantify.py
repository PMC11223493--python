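"""From classified event counts to composition, yield, and LC-MS estimates.

Event rates differ between cOA classes at equal concentration, so raw
event counts are not abundances. Class-specific correction factors
``CF_x`` (events/s/uM), estimated from monodisperse calibration traces,
convert counts to abundances:

    abundance_x  ~  count_x / (recording time * CF_x)

Fractions are those abundances normalized to 1. The absolute enzymatic
yield per CRISPR complex follows from the observed total event rate r_e,
the class fractions, the correction factors, the dilution factor d
between the reaction and the flow cell, and the complex concentration:

    molecules per complex = (r_e * fraction_x / CF_x) * d / [complex]

All uncertainties use first-order propagation with independent Gaussian
input errors. LC-MS concentrations are ratios of extracted-ion
chromatogram peak areas against monodisperse calibration standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

#: Printed calibration constants of the workflow, events/s/uM (value, sd).
DEFAULT_CORRECTION_FACTORS = {
    "cA3/4": (0.17, 0.05),
    "cA5": (0.62, 0.7),
    "cA6": (0.12, 0.3),
}


@dataclass
class CorrectionFactors:
    """Per-class event-rate constants CF_x in events/s/uM, with uncertainty."""

    values: dict[str, float]
    uncertainties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cf in self.values.items():
            if not cf > 0:
                raise ValueError(f"correction factor for {name!r} must be positive")
        for name in self.values:
            self.uncertainties.setdefault(name, 0.0)

    @classmethod
    def default(cls) -> "CorrectionFactors":
        return cls(
            values={k: v for k, (v, _) in DEFAULT_CORRECTION_FACTORS.items()},
            uncertainties={k: s for k, (_, s) in DEFAULT_CORRECTION_FACTORS.items()},
        )


def estimate_correction_factors(records: list[dict]) -> CorrectionFactors:
    """Estimate CF_x from monodisperse calibration traces.

    Each record describes one trace: ``{"label", "n_events",
    "duration_s", "concentration_uM"}``. Per class, CF = total events /
    sum(concentration * time) pooled over that class's traces; the
    uncertainty is the SD over per-trace estimates (for a single trace, a
    Poisson sqrt(N)-based error).
    """
    by_class: dict[str, list[dict]] = {}
    for rec in records:
        if not rec["concentration_uM"] > 0:
            raise ValueError("concentration must be positive")
        if not rec["duration_s"] > 0:
            raise ValueError("recording time must be positive")
        by_class.setdefault(rec["label"], []).append(rec)
    values, uncertainties = {}, {}
    for label, recs in by_class.items():
        exposure = sum(r["concentration_uM"] * r["duration_s"] for r in recs)
        total = sum(r["n_events"] for r in recs)
        values[label] = total / exposure
        per_trace = [r["n_events"] / (r["concentration_uM"] * r["duration_s"]) for r in recs]
        if len(recs) > 1:
            uncertainties[label] = float(np.std(per_trace, ddof=1))
        else:
            uncertainties[label] = float(np.sqrt(max(total, 1)) / exposure)
    return CorrectionFactors(values=values, uncertainties=uncertainties)


@dataclass
class CompositionEstimate:
    """Per-class abundance fractions of a cOA mixture."""

    fractions: dict[str, float]
    event_rate: float  # r_e, total events/s
    counts: dict[str, int]
    recording_time: float  # s
    intervals: dict[str, tuple[float, float]] | None = None  # 95% prediction intervals


def estimate_composition(
    counts: dict[str, int],
    recording_time: float,
    correction_factors: CorrectionFactors,
) -> CompositionEstimate:
    """Rate-corrected abundance fractions from classified event counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no classified events: cannot estimate composition")
    if not recording_time > 0:
        raise ValueError("recording time must be positive")
    abundances = {c: counts[c] / (recording_time * correction_factors.values[c]) for c in counts}
    norm = sum(abundances.values())
    return CompositionEstimate(
        fractions={c: a / norm for c, a in abundances.items()},
        event_rate=total / recording_time,
        counts=dict(counts),
        recording_time=recording_time,
    )


def prediction_interval(
    fold_fractions: list[dict[str, float]],
    confidence: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """95% prediction interval per class from per-fold composition estimates.

    Interval = mean +- t_{(1+confidence)/2, k-1} * SD over the k
    cross-validation fold estimates; it expresses the uncertainty
    introduced by training-data variability.
    """
    k = len(fold_fractions)
    if k < 3:
        raise ValueError("need at least 3 fold estimates for a prediction interval")
    classes = fold_fractions[0].keys()
    tcrit = spstats.t.ppf((1 + confidence) / 2, df=k - 1)
    out = {}
    for c in classes:
        vals = np.array([f[c] for f in fold_fractions])
        center, spread = float(np.mean(vals)), float(np.std(vals, ddof=1))
        out[c] = (center - tcrit * spread, center + tcrit * spread)
    return out


@dataclass
class AbsoluteYield:
    """Molecules produced per CRISPR complex, per class and total."""

    per_class: dict[str, float]
    per_class_sd: dict[str, float]
    total: float
    total_sd: float
    inputs: dict


def absolute_yield(
    event_rate: float,
    fractions: dict[str, float],
    correction_factors: CorrectionFactors,
    dilution: float,
    complex_concentration: float,
    event_rate_sd: float = 0.0,
    fraction_sd: dict[str, float] | None = None,
    dilution_sd: float = 0.0,
    complex_concentration_sd: float = 0.0,
) -> AbsoluteYield:
    """Absolute enzymatic yield in molecules per complex.

    Per class: flow-cell concentration r_e * fraction_x / CF_x (uM),
    scaled by the dilution factor *d* to the reaction concentration and
    divided by the complex concentration (uM). Uncertainty by first-order
    propagation over independent Gaussian input errors (the shared event
    rate, dilution and complex terms are propagated through the total's
    partial derivatives, not added per class).
    """
    if not event_rate > 0 or not dilution > 0 or not complex_concentration > 0:
        raise ValueError("event rate, dilution and complex concentration must be positive")
    fsum = sum(fractions.values())
    if fsum > 1 + 1e-6:
        raise ValueError("fractions must sum to at most 1")
    fraction_sd = fraction_sd or {}
    missing = [c for c in fractions if c not in correction_factors.values]
    if missing:
        raise ValueError(f"no correction factor for predicted class(es) {missing}")

    scale = event_rate * dilution / complex_concentration
    per_class, per_var = {}, {}
    shared_rel_var = (
        (event_rate_sd / event_rate) ** 2
        + (dilution_sd / dilution) ** 2
        + (complex_concentration_sd / complex_concentration) ** 2
    )
    for c, frac in fractions.items():
        cf = correction_factors.values[c]
        cf_sd = correction_factors.uncertainties.get(c, 0.0)
        val = scale * frac / cf
        per_class[c] = val
        rel = shared_rel_var + (cf_sd / cf) ** 2
        if frac > 0:
            rel += (fraction_sd.get(c, 0.0) / frac) ** 2
        per_var[c] = val**2 * rel

    total = sum(per_class.values())
    # total: shared inputs differentiate through the sum, class inputs per term
    var_total = total**2 * shared_rel_var
    for c, frac in fractions.items():
        cf = correction_factors.values[c]
        cf_sd = correction_factors.uncertainties.get(c, 0.0)
        var_total += (scale / cf) ** 2 * fraction_sd.get(c, 0.0) ** 2
        var_total += (scale * frac / cf**2) ** 2 * cf_sd**2
    return AbsoluteYield(
        per_class=per_class,
        per_class_sd={c: float(np.sqrt(v)) for c, v in per_var.items()},
        total=total,
        total_sd=float(np.sqrt(var_total)),
        inputs={
            "event_rate": event_rate,
            "fractions": dict(fractions),
            "dilution": dilution,
            "complex_concentration": complex_concentration,
        },
    )


# ---------------------------------------------------------------------------
# LC-MS estimators


def lcms_concentrations(
    areas_mono: dict[str, float],
    areas_mix: dict[str, float],
    calib_concentration: float = 50.0,
    areas_mono_sd: dict[str, float] | None = None,
    areas_mix_sd: dict[str, float] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Mixture concentrations (uM) from EIC peak-area ratios.

    [cAx, mix] = (PA_x,mix / PA_x,mono) * calibration concentration, where
    the monodisperse solutions were measured at *calib_concentration*.
    Returns (concentrations, propagated uncertainties).
    """
    areas_mono_sd = areas_mono_sd or {}
    areas_mix_sd = areas_mix_sd or {}
    conc, conc_sd = {}, {}
    for species, mono in areas_mono.items():
        if not mono > 0:
            raise ValueError(f"zero monodisperse peak area for {species!r}")
        mix = areas_mix[species]
        c = mix / mono * calib_concentration
        conc[species] = c
        rel = 0.0
        if mix > 0:
            rel = (areas_mix_sd.get(species, 0.0) / mix) ** 2 + (areas_mono_sd.get(species, 0.0) / mono) ** 2
        conc_sd[species] = c * float(np.sqrt(rel))
    return conc, conc_sd


def lcms_ratios(
    concentrations: dict[str, float],
    concentration_sd: dict[str, float] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Percentage of each species: [cAx] / sum_y [cAy] * 100.

    Returns (percentages, propagated uncertainties); percentages sum to
    100.
    """
    total = sum(concentrations.values())
    if not total > 0:
        raise ValueError("total concentration must be positive")
    concentration_sd = concentration_sd or {}
    ratios = {s: c / total * 100.0 for s, c in concentrations.items()}
    ratio_sd = {}
    for s, c in concentrations.items():
        # d ratio_s / d c_y: (total - c_s)/total^2 for y = s, -c_s/total^2 otherwise
        var = 0.0
        for y, cy in concentrations.items():
            d = (total - c) / total**2 if y == s else -c / total**2
            var += (d * concentration_sd.get(y, 0.0)) ** 2
        ratio_sd[s] = 100.0 * float(np.sqrt(var))
    return ratios, ratio_sd
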