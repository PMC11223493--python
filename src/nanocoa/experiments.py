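"""Canonical end-to-end reproduction experiments.

These functions package the workflow's self-contained validation runs:
simulate recordings under the calibrated study conditions, push them
through the full processing chain, and measure how well the known inputs
are recovered. They are used by the test suite and by the repository's
reproduction script, and are convenient entry points for sanity-checking
an installation.

Problem sizes are chosen so each experiment runs in seconds to a few
minutes on one CPU core: the event-statistics run uses one 40 s trace at
the full 500 kHz acquisition rate (~600 events); the correction-factor
run covers 600 s of recording in 30 s chunks; classifier experiments run
at a reduced 100 kHz acquisition rate with a 25 kHz digital filter.
"""

from __future__ import annotations


import numpy as np

from . import classify as clf
from . import quantify as qt
from . import sigproc as sp
from .simulate import (
    ClassParams,
    SimulationConfig,
    match_events_to_annotations,
    simulate_trace,
)

#: Printed calibration constants: correction factors (events/s/uM) and the
#: cA6 event statistics (dwell 315 +- 26 us, blockade 400 +- 30 pA).
PRINTED_CFS = {"cA3/4": 0.17, "cA5": 0.62, "cA6": 0.12}
CA6_DWELL = (315e-6, 26e-6)
CA6_BLOCKADE = (400.0, 30.0)

#: Printed enzymatic quantification inputs: event rate r_e (/s), class
#: fractions, dilution factor d, and the 62.5 nM complex concentration.
ENZYMATIC_INPUTS = {
    "type III-A": dict(event_rate=0.47, fractions={"cA3/4": 0.89, "cA5": 0.08, "cA6": 0.03}, dilution=21.0),
    "type III-B": dict(event_rate=1.17, fractions={"cA3/4": 0.81, "cA5": 0.12, "cA6": 0.07}, dilution=27.6),
}
COMPLEX_CONCENTRATION_UM = 0.0625


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def process_trace(trace, filter_cutoff=80e3, decimate_to=80e3, threshold_frac=0.65):
    """Standard chain: low-pass -> median decimation -> 65% threshold."""
    filtered = sp.lowpass_filter(trace, filter_cutoff)
    decimated = sp.decimate_median(filtered, decimate_to)
    open_pore = sp.estimate_open_pore(decimated)
    events = sp.detect_events(decimated, open_pore, threshold_frac=threshold_frac)
    return decimated, open_pore, events


# ---------------------------------------------------------------------------
# event-statistics recovery (cA6-like trace at full acquisition rate)


def ca6_event_recovery(seed: int, duration: float = 40.0, event_rate: float = 15.0) -> dict:
    """Recover the cA6 dwell/blockade statistics through the full chain.

    Simulates a monodisperse cA6-like trace at 500 kHz (dwell log-normal
    315 +- 26 us, blockade normal 400 +- 30 pA, arrival rate
    ``event_rate``), processes it with the 80 kHz filter + decimation +
    65% threshold, and reports the mean extracted duration and blockade.
    """
    dwell_mean, dwell_sd = CA6_DWELL
    blockade_mean, blockade_sd = CA6_BLOCKADE
    cf = PRINTED_CFS["cA6"]
    config = SimulationConfig(
        classes={
            "cA6": ClassParams(event_rate / cf, cf, dwell_mean, dwell_sd, blockade_mean, blockade_sd)
        },
        sampling_rate=500e3,
        duration=duration,
        filter_cutoff=100e3,
        seed=seed,
    )
    trace, annotations = simulate_trace(config)
    _, open_pore, events = process_trace(trace)
    durations = np.array([e.duration for e in events])
    blockades = np.array([e.delta_i for e in events])
    return {
        "n_events": len(events),
        "n_injected": len(annotations),
        "open_pore_pA": open_pore,
        "mean_duration_us": float(1e6 * durations.mean()),
        "mean_blockade_pA": float(blockades.mean()),
        "duration_fit": sp.fit_duration_lognormal(durations),
        "blockade_fit": sp.fit_blockade_normal(blockades),
    }


def correction_factor_recovery(
    seed: int,
    total_time: float = 600.0,
    chunk_duration: float = 30.0,
    concentration: float = 10.0,
    correction_factor: float = 0.17,
) -> dict:
    """Re-estimate a correction factor from simulated monodisperse traces.

    Simulates ``total_time`` seconds of cA3/4-like recording at 10 uM
    (Poisson arrivals at CF x concentration) in chunks, detects events,
    and recomputes CF = events / (concentration x time). The Poisson
    standard error sqrt(N) / (c x T) quantifies the expected deviation.
    """
    n_chunks = int(round(total_time / chunk_duration))
    records = []
    n_total = 0
    for chunk_seed in _child_seeds(seed, n_chunks):
        config = SimulationConfig(
            classes={
                "cA3/4": ClassParams(concentration, correction_factor, 110e-6, 40e-6, 400.0, 30.0)
            },
            sampling_rate=500e3,
            duration=chunk_duration,
            filter_cutoff=100e3,
            seed=chunk_seed,
        )
        trace, _ = simulate_trace(config)
        _, _, events = process_trace(trace)
        n_total += len(events)
        records.append(
            dict(label="cA3/4", n_events=len(events), duration_s=chunk_duration,
                 concentration_uM=concentration)
        )
    estimate = qt.estimate_correction_factors(records)
    exposure = concentration * n_chunks * chunk_duration
    return {
        "cf_true": correction_factor,
        "cf_estimate": estimate.values["cA3/4"],
        "cf_between_trace_sd": estimate.uncertainties["cA3/4"],
        "poisson_sd": float(np.sqrt(max(n_total, 1)) / exposure),
        "n_events": n_total,
        "total_time_s": n_chunks * chunk_duration,
    }


# ---------------------------------------------------------------------------
# printed-input quantification


def enzymatic_yield_examples() -> dict[str, qt.AbsoluteYield]:
    """Absolute yields for both CRISPR complexes from the printed inputs."""
    cfs = qt.CorrectionFactors(values=dict(PRINTED_CFS))
    return {
        label: qt.absolute_yield(
            inputs["event_rate"], inputs["fractions"], cfs,
            inputs["dilution"], COMPLEX_CONCENTRATION_UM,
        )
        for label, inputs in ENZYMATIC_INPUTS.items()
    }


def lcms_pooling_example() -> dict:
    """Noise-free equal-volume pooling of four 50 uM monodisperse stocks."""
    species = ["cA3", "cA4", "cA5", "cA6"]
    response = {s: 900.0 + 75.0 * i for i, s in enumerate(species)}
    mono = {s: response[s] * 50.0 for s in species}
    mix = {s: a / 4.0 for s, a in mono.items()}
    conc, _ = qt.lcms_concentrations(mono, mix, calib_concentration=50.0)
    ratios, _ = qt.lcms_ratios(conc)
    return {"concentrations_uM": conc, "ratios_percent": ratios}


# ---------------------------------------------------------------------------
# classifier experiments (scaled acquisition rate)

SCALED = dict(sampling_rate=100e3, acquisition_filter=30e3, lowpass=25e3, decimate_to=80e3)

#: Three-class construction for mixture experiments: dwell distributions
#: ordered as the cOA classes (with adjacent overlap) plus a weak
#: class-specific in-event ripple, standing in for the shape differences
#: the CNN exploits in measured events.
MIXTURE_CLASSES = {
    "cA3/4": dict(dwell=(95e-6, 25e-6), ripple=(35.0, 5e3)),
    "cA5": dict(dwell=(180e-6, 35e-6), ripple=(35.0, 10e3)),
    "cA6": dict(dwell=(330e-6, 28e-6), ripple=(35.0, 15e3)),
}
MIXTURE_DESIGNS = [(0.8, 0.1, 0.1), (0.5, 0.4, 0.1), (0.5, 0.25, 0.25)]


def _mixture_class(name: str, concentration: float) -> ClassParams:
    params = MIXTURE_CLASSES[name]
    (m, s), (amp, freq) = params["dwell"], params["ripple"]
    return ClassParams(concentration, PRINTED_CFS[name], m, s, 400.0, 30.0,
                       ripple_amplitude=amp, ripple_frequency=freq)


def simulate_labeled_events(classes, duration, seed, trace_id=None):
    """Simulate + process one scaled-rate trace; return truth-labeled events."""
    config = SimulationConfig(
        classes=classes,
        sampling_rate=SCALED["sampling_rate"],
        duration=duration,
        filter_cutoff=SCALED["acquisition_filter"],
        seed=seed,
    )
    trace, annotations = simulate_trace(config)
    filtered = sp.lowpass_filter(trace, SCALED["lowpass"])
    decimated = sp.decimate_median(filtered, SCALED["decimate_to"])
    decimated.trace_id = trace_id
    events = sp.detect_events(decimated, sp.estimate_open_pore(decimated))
    labels = match_events_to_annotations(
        events, annotations,
        coordinate_ratio=SCALED["sampling_rate"] / decimated.sampling_rate,
    )
    keep = [i for i, lab in enumerate(labels) if lab is not None]
    return decimated, [events[i] for i in keep], [labels[i] for i in keep]


def tensorize_labeled(triples, class_order, duration_stats=None):
    """Stack tensors/labels/groups from (trace, events, labels) triples."""
    if duration_stats is None:
        durations = np.hstack([[e.duration for e in events] for _, events, _ in triples])
        duration_stats = sp.log_duration_stats(durations)
    xs, ys, groups = [], [], []
    for trace, events, labels in triples:
        x, kept, _ = sp.events_to_tensors(trace, events, duration_stats=duration_stats)
        xs.append(x)
        kept_ids = {id(e) for e in kept}
        for ev, lab in zip(events, labels):
            if id(ev) in kept_ids:
                ys.append(class_order.index(lab))
                groups.append(trace.trace_id)
    return np.vstack(xs), np.array(ys), np.array(groups), duration_stats


def mixture_recovery(
    seed: int,
    epochs: int = 60,
    restarts: int = 2,
    traces_per_class: int = 3,
    train_duration: float = 12.0,
    mixture_duration: float = 30.0,
) -> dict:
    """Train the CNN on monodisperse traces, quantify three known mixtures.

    The mixture designs mirror the workflow's validation: 80:10:10,
    50:40:10 and 50:25:25 abundance fractions. Returns per-mixture
    estimated fractions, their maximum deviation from truth, and the
    per-mixture confusion against the simulator's ground truth.
    """
    order = tuple(MIXTURE_CLASSES)
    seeds = iter(_child_seeds(seed, traces_per_class * len(order) + len(MIXTURE_DESIGNS) + 1))
    triples = []
    for name in order:
        concentration = 13.0 / PRINTED_CFS[name]  # ~13 events/s per trace
        for _ in range(traces_per_class):
            triples.append(simulate_labeled_events(
                {name: _mixture_class(name, concentration)}, train_duration, next(seeds)
            ))
    x_train, y_train, _, duration_stats = tensorize_labeled(triples, order)
    model = clf.build_classifier(len(order), seed=next(seeds))
    model, log = clf.train(model, x_train, y_train, epochs=epochs,
                           restarts=restarts, seed=seed, class_names=order)
    cfs = qt.CorrectionFactors(values=dict(PRINTED_CFS))
    mixtures = []
    for design in MIXTURE_DESIGNS:
        scale = 20.0 / sum(PRINTED_CFS[n] * f for n, f in zip(order, design))
        classes = {n: _mixture_class(n, f * scale) for n, f in zip(order, design)}
        trace, events, labels = simulate_labeled_events(classes, mixture_duration, next(seeds))
        x, y_true, _, _ = tensorize_labeled([(trace, events, labels)], order, duration_stats)
        y_pred = model.predict(x)
        counts = {n: int((y_pred == i).sum()) for i, n in enumerate(order)}
        composition = qt.estimate_composition(counts, trace.duration, cfs)
        estimated = [composition.fractions[n] for n in order]
        confusion = np.zeros((len(order), len(order)))
        np.add.at(confusion, (y_true, y_pred), 1.0)
        confusion /= np.maximum(confusion.sum(axis=1, keepdims=True), 1.0)
        mixtures.append({
            "target": dict(zip(order, design)),
            "estimated": dict(zip(order, estimated)),
            "max_deviation": float(max(abs(e - t) for e, t in zip(estimated, design))),
            "n_events": int(len(y_pred)),
            "confusion": confusion,
        })
    return {
        "class_order": order,
        "training_accuracy": log["selected_training_accuracy"],
        "n_training_events": int(y_train.size),
        "mixtures": mixtures,
    }


def cnn_vs_knn(
    seed: int,
    epochs: int = 30,
    restarts: int = 2,
    train_duration: float = 40.0,
    test_duration: float = 15.0,
) -> dict:
    """Compare the CNN against the (blockade, log dwell) KNN baseline.

    The two classes share identical dwell-time and blockade-depth
    distributions and differ only in within-event fluctuation structure
    (one carries a 60 pA, 12 kHz ripple), so the 2-D feature space is
    uninformative by construction while the event shape is not.
    """
    base = dict(dwell_mean=200e-6, dwell_sd=50e-6, blockade_mean=400.0, blockade_sd=30.0)
    classes = {
        "flat": ClassParams(50.0, 0.2, **base),
        "ripple": ClassParams(50.0, 0.2, **base, ripple_amplitude=60.0, ripple_frequency=12e3),
    }
    order = ("flat", "ripple")
    s_train, s_test, s_model = _child_seeds(seed, 3)
    train_triple = simulate_labeled_events(classes, train_duration, s_train)
    test_triple = simulate_labeled_events(classes, test_duration, s_test)
    x_train, y_train, _, duration_stats = tensorize_labeled([train_triple], order)
    x_test, y_test, _, _ = tensorize_labeled([test_triple], order, duration_stats)
    model = clf.build_classifier(2, seed=s_model)
    model, _ = clf.train(model, x_train, y_train, epochs=epochs, restarts=restarts,
                         seed=seed, class_names=order)
    cnn_accuracy = model.accuracy(x_test, y_test)

    def features(triple):
        _, events, labels = triple
        f = np.column_stack([
            [e.rel_blockade for e in events],
            np.log10([e.duration for e in events]),
        ])
        y = np.array([order.index(lab) for lab in labels])
        return f, y

    f_train, yk_train = features(train_triple)
    f_test, yk_test = features(test_triple)
    knn_pred = clf.knn_baseline(f_train, yk_train, f_test, k=3)
    return {
        "cnn_accuracy": float(cnn_accuracy),
        "knn_accuracy": float(np.mean(knn_pred == yk_test)),
        "n_train": int(y_train.size),
        "n_test": int(y_test.size),
    }
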