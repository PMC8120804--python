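"""Seeded generators for every raw-input modality.

Each generator emulates one experimental readout with its documented default
kinetics (receptor off/on rates 0.88 and 0.04 /s; calcium cascade k=5,
theta=6.21 s; ppERK half-life 3.0 min; FOS active-fraction half-life 3.1 min;
mRNA half-lives 15-30 min with a 25-min default; output degradation 24 h GFP
/ 14 h CD69) and returns the raw data together with a ground-truth dictionary
so every pipeline stage can be validated by parameter recovery.  All
randomness flows from an explicit seed through ``numpy.random.default_rng``;
identical arguments and seed reproduce identical outputs.

Noise models are Gaussian on the measurement scale (additive for traces and
profiles, on the Ct scale for qPCR) except per-cell heterogeneity, which is
lognormal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    CD69_OUTPUT,
    DEFAULT_CASCADE,
    DEFAULT_GENE,
    DEFAULT_READOUT,
    GFP_OUTPUT,
    CascadeParams,
    StimulusProfile,
    gamma_survival,
    predict_endpoint,
)
from .imaging import TwoChannelStack
from .kinetics_fit import DecayTrace
from .westernquant import LanePair

__all__ = [
    "gen_lovtrap_traces",
    "gen_calcium_events",
    "gen_pperk_samples",
    "gen_western_lanes",
    "gen_ct_table",
    "gen_endpoint_population",
    "gen_plate_measurements",
    "gen_membrane_stack",
    "generate_study",
    "QPCR_GENES",
    "DEFAULT_QPCR_GENE",
]

MINUTE = 60.0


def _bound_fraction(times: np.ndarray, k_off: float, k_on: float, t_on: float, t_off: float) -> np.ndarray:
    """Receptor-bound fraction for an illumination pulse on [t_on, t_off)."""
    b = np.ones_like(times)
    during = (times >= t_on) & (times < t_off)
    b[during] = np.exp(-k_off * (times[during] - t_on))
    b_end = np.exp(-k_off * (t_off - t_on))
    after = times >= t_off
    b[after] = 1.0 - (1.0 - b_end) * np.exp(-k_on * (times[after] - t_off))
    return b


def gen_lovtrap_traces(
    n: int = 12,
    seed: int = 0,
    k_off: float = 0.88,
    k_on: float = 0.04,
    noise_sd: float = 0.02,
    duration: float = 150.0,
    illumination: tuple[float, float] = (25.0, 50.0),
) -> tuple[list[DecayTrace], dict]:
    """Membrane-ratio traces of receptor dissociation/re-association.

    150-s traces at 1 Hz; illumination from 25 to 50 s drives exponential
    dissociation at ``k_off``, then the dark state re-forms at ``k_on``.
    Per-cell amplitude and baseline vary lognormally/normally; additive
    Gaussian noise at ``noise_sd`` (on the normalized ratio scale).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 0.5, 1.0)
    bound = _bound_fraction(times, k_off, k_on, *illumination)
    traces = []
    for i in range(n):
        amplitude = float(np.exp(rng.normal(0.0, 0.15)))
        baseline = float(rng.normal(0.2, 0.03))
        values = baseline + amplitude * bound + rng.normal(0.0, noise_sd * amplitude, times.size)
        traces.append(DecayTrace(times=times, values=values, t_zero=illumination[0], meta={"cell": i}))
    truth = {"k_off": k_off, "k_on": k_on, "noise_sd": noise_sd, "illumination": illumination, "n": n}
    return traces, truth


def gen_calcium_events(
    duration: float = 400.0,
    event_rate: float = 150.0,
    seed: int = 0,
    cascade: CascadeParams = DEFAULT_CASCADE,
    t_dimerizer: float = 60.0,
    t_illumination: float = 240.0,
    conjugate_fraction: float = 0.3,
    rise_tau: float = 30.0,
    ratio_baseline: float = 1.0,
    ratio_amplitude: float = 1.5,
    ratio_noise_sd: float = 0.12,
    backgrounds: tuple[float, float] = (50.0, 50.0),
) -> tuple[pd.DataFrame, dict]:
    """Flow-cytometry event table of an illumination-interrupted calcium flux.

    Conjugated cells (double-positive markers) carry an Indo-1 ratio that sits
    at baseline before dimerizer addition, rises with time constant
    ``rise_tau`` (saturating within ~2 min), and after illumination decays as
    the gamma survival function of the cascade.  Non-conjugated events are
    single-positive and stay at baseline.  Channel intensities include the
    stated additive backgrounds.
    """
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(event_rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n_events))
    is_conj = rng.random(n_events) < conjugate_fraction

    rel = np.zeros(n_events)
    active = times >= t_dimerizer
    rise = 1.0 - np.exp(-(times - t_dimerizer) / rise_tau)
    rel[active] = rise[active]
    post = times >= t_illumination
    plateau = 1.0 - np.exp(-(t_illumination - t_dimerizer) / rise_tau)
    rel[post] = plateau * gamma_survival(times[post] - t_illumination, cascade)
    expected_ratio = ratio_baseline + np.where(is_conj, ratio_amplitude * rel, 0.0)
    ratio = expected_ratio * np.exp(rng.normal(0.0, ratio_noise_sd, n_events))

    indo_485 = np.exp(rng.normal(np.log(200.0), 0.25, n_events))
    indo_405 = ratio * indo_485
    marker_hi = lambda n: np.exp(rng.normal(np.log(5000.0), 0.3, n))
    marker_lo = lambda n: np.exp(rng.normal(np.log(100.0), 0.4, n))
    irfp = np.where(is_conj, marker_hi(n_events), 0.0)
    btag = np.where(is_conj, marker_hi(n_events), 0.0)
    # non-conjugates: single positives of either type
    single_t = (~is_conj) & (rng.random(n_events) < 0.5)
    single_b = (~is_conj) & ~single_t
    irfp[single_t], btag[single_t] = marker_hi(single_t.sum()), marker_lo(single_t.sum())
    irfp[single_b], btag[single_b] = marker_lo(single_b.sum()), marker_hi(single_b.sum())

    events = pd.DataFrame(
        {
            "acquisition_time": times,
            "indo_405": indo_405 + backgrounds[0],
            "indo_485": indo_485 + backgrounds[1],
            "irfp713": irfp,
            "mtagbfp": btag,
            "is_conjugate": is_conj,  # ground-truth label, not used by the pipeline
        }
    )
    truth = {
        "cascade": {"n_steps": cascade.n_steps, "step_scale": cascade.step_scale},
        "half_life_s": 29.0,
        "onset_s": 7.94,
        "t_dimerizer": t_dimerizer,
        "t_illumination": t_illumination,
        "conjugate_fraction": conjugate_fraction,
        "backgrounds": backgrounds,
        "gate_thresholds": {"irfp713": 1000.0, "mtagbfp": 1000.0},
    }
    return events, truth


PPERK_TIMEPOINTS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 10.0, 11.0, 12.0, 15.0)


def gen_pperk_samples(
    timepoints=PPERK_TIMEPOINTS,
    seed: int = 0,
    half_life: float = 3.0,
    t_illumination: float = 5.0,
    activation_tau: float = 0.75,
    n_events: int = 2000,
    background_median: float = 100.0,
    activated_median: float = 2000.0,
    log_sd: float = 0.4,
) -> tuple[dict[float, pd.DataFrame], dict]:
    """Per-timepoint ppERK staining samples with a digital (bimodal) response.

    Activated-mode occupancy rises with ``activation_tau`` after stimulation
    (detectable within 1 min) and decays exponentially with ``half_life``
    after illumination at ``t_illumination`` (all times in minutes).  The
    stain distribution is a two-mode lognormal mixture; the population median
    therefore tracks the activated mode while the occupancy exceeds one half.
    """
    rng = np.random.default_rng(seed)
    samples = {}
    for tp in timepoints:
        p = 0.0 if tp <= 0 else 1.0 - np.exp(-tp / activation_tau)
        if tp > t_illumination:
            p_at = 1.0 - np.exp(-t_illumination / activation_tau)
            p = p_at * 0.5 ** ((tp - t_illumination) / half_life)
        activated = rng.random(n_events) < p
        log_mu = np.where(activated, np.log(activated_median), np.log(background_median))
        samples[float(tp)] = pd.DataFrame({"pperk": np.exp(rng.normal(log_mu, log_sd))})
    truth = {
        "half_life_min": half_life,
        "t_illumination": t_illumination,
        "background_median": background_median,
        "activation_tau": activation_tau,
    }
    return samples, truth


WESTERN_TIMEPOINTS = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0)


def gen_western_lanes(
    timepoints=WESTERN_TIMEPOINTS,
    seed: int = 0,
    active_half_life: float = 3.1,
    shift_jitter_sd: float = 0.015,
    cutoff: float = 0.4,
    start_fraction: float = 0.6,
    condition: str = "light",
    n_points: int = 201,
    band_sd: float = 0.045,
    noise_sd: float = 0.01,
) -> tuple[list[LanePair], dict]:
    """Two-band FOS lane profiles with a shared-jitter TPN loading channel.

    The phospho-shifted (active, higher-mass) band sits below the cutoff
    coordinate and its area fraction decays exponentially with
    ``active_half_life`` after illumination (``condition="light"``); dark
    lanes keep the starting fraction.  Each lane is displaced by a random
    migration jitter applied identically to both channels, which is what the
    TPN-guided alignment must recover.
    """
    rng = np.random.default_rng(seed)
    coord = np.linspace(0.0, 1.0, n_points)
    gauss = lambda c, mu, sd: np.exp(-0.5 * ((c - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    tpn_centers = [(0.2, 0.5), (0.35, 0.8), (0.5, 1.0), (0.65, 0.7), (0.8, 0.4)]
    lanes, true_shifts = [], {}
    for i, tp in enumerate(timepoints):
        shift = float(rng.normal(0.0, shift_jitter_sd)) if i > 0 else 0.0
        frac = start_fraction if condition == "dark" else start_fraction * 0.5 ** (tp / active_half_life)
        c = coord - shift
        fos = frac * gauss(c, 0.30, band_sd) + (1.0 - frac) * gauss(c, 0.50, band_sd)
        fos = fos + 0.05 + 0.02 * coord + rng.normal(0.0, noise_sd, n_points)
        tpn = sum(a * gauss(c, mu, 0.06) for mu, a in tpn_centers)
        tpn = tpn + 0.1 + rng.normal(0.0, noise_sd, n_points)
        lane_id = f"{condition}_{tp:g}min"
        true_shifts[lane_id] = shift
        lanes.append(LanePair(coord, fos, tpn, lane_id=lane_id, timepoint=float(tp), condition=condition))
    truth = {
        "active_half_life_min": active_half_life,
        "start_fraction": start_fraction,
        "cutoff": cutoff,
        "shifts": true_shifts,
    }
    return lanes, truth


QPCR_GENES: dict[str, dict] = {
    "CD69": {"half_life_min": 25.0, "profile": "sustained"},
    "FOS": {"half_life_min": 15.0, "profile": "immediate_early"},
    "CXCL8": {"half_life_min": 20.0, "profile": "early_decline"},
    "IL2": {"half_life_min": 30.0, "profile": "delayed"},
}
DEFAULT_QPCR_GENE = "CD69"
QPCR_TIMEPOINTS = (0, 30, 60, 90, 120, 150, 180, 185, 190, 195, 200, 210, 220, 230, 240)


def _transcription_profile(t: np.ndarray, profile: str) -> np.ndarray:
    """Normalized dark-state transcription rate shapes (t in minutes)."""
    if profile == "sustained":
        return 1.0 - np.exp(-t / 30.0)
    if profile == "immediate_early":
        return (1.0 - np.exp(-t / 10.0)) * np.exp(-t / 180.0)
    if profile == "early_decline":
        return (1.0 - np.exp(-t / 15.0)) * np.exp(-t / 240.0)
    if profile == "delayed":
        return 1.0 / (1.0 + np.exp(-(t - 60.0) / 15.0))
    raise ValueError(f"unknown profile {profile!r}")


def gen_ct_table(
    timepoints=QPCR_TIMEPOINTS,
    seed: int = 0,
    genes: dict[str, dict] | None = None,
    shutoff_delay: float = 5.0,
    ct_noise_sd: float = 0.15,
    loading_sd: float = 0.3,
    t_illumination: float = 180.0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Tidy Ct table for dark and light arms of a transcription-shutoff assay.

    Per-gene mRNA follows dM/dt = beta(t) - gamma*M with the documented
    dark-arm transcription shapes; the light arm halts transcription
    ``shutoff_delay`` minutes after illumination at ``t_illumination`` and
    decays at the gene's first-order rate.  Housekeeping genes (GAPDH, PGK1)
    are constant.  ``n_replicates`` biological replicates (3, matching the
    assay design) each carry their own loading shift on the Ct scale
    (cancelled by cRQ) plus Gaussian Ct noise for the technical duplicate
    mean; assay efficiency is 100% (perfect doubling).
    """
    rng = np.random.default_rng(seed)
    genes = QPCR_GENES if genes is None else genes
    grid = np.arange(0.0, max(timepoints) + 1.0, 1.0)
    quantities: dict[tuple[str, str], np.ndarray] = {}
    for gene, cfg in genes.items():
        gamma = np.log(2) / cfg["half_life_min"]
        beta = gamma * _transcription_profile(grid, cfg["profile"])
        for condition in ("dark", "light"):
            b = beta.copy()
            if condition == "light":
                b[grid >= t_illumination + shutoff_delay] = 0.0
            m = np.zeros_like(grid)
            decay = np.exp(-gamma * 1.0)
            for i in range(1, grid.size):
                m[i] = m[i - 1] * decay + (b[i - 1] / gamma) * (1.0 - decay)
            quantities[(gene, condition)] = m + 0.02  # basal expression floor

    ct0 = {"GAPDH": 18.0, "PGK1": 20.0}
    ct0.update({g: 26.0 for g in genes})
    # each biological replicate is a separate sample: its own loading shift
    # per (condition, timepoint); the recorded Ct is the technical-duplicate
    # mean, so its noise is ct_noise_sd / sqrt(2)
    tech_sd = ct_noise_sd / np.sqrt(2)
    rows = []
    for rep in range(1, n_replicates + 1):
        for condition in ("dark", "light"):
            for tp in timepoints:
                loading = rng.normal(0.0, loading_sd)
                for gene in list(genes) + ["GAPDH", "PGK1"]:
                    if gene in ("GAPDH", "PGK1"):
                        q_rel = 1.0
                    else:
                        q = quantities[(gene, condition)]
                        q_rel = q[int(tp)] / q[0]
                    rows.append(
                        {
                            "time_min": float(tp),
                            "condition": condition,
                            "gene": gene,
                            "replicate": rep,
                            "ct": ct0[gene] - np.log2(q_rel) + loading + rng.normal(0.0, tech_sd),
                        }
                    )
    table = pd.DataFrame(rows)
    # noiseless oracle: the light/dark ratio half-life the ratio method should
    # report.  For genes at dark-state plateau it equals the mRNA half-life;
    # for dark arms still declining it is longer by the dark decline rate.
    expected_ratio_hl = {}
    post = grid >= t_illumination + shutoff_delay
    for gene in genes:
        # on the baseline-subtracted scale the basal floor cancels out
        ratio = (quantities[(gene, "light")][post] - 0.02) / (quantities[(gene, "dark")][post] - 0.02)
        slope = np.polyfit(grid[post], np.log(ratio), 1)[0]
        expected_ratio_hl[gene] = float(np.log(2) / -slope)
    truth = {
        "genes": {g: cfg["half_life_min"] for g, cfg in genes.items()},
        "expected_ratio_half_life": expected_ratio_hl,
        "default_gene": DEFAULT_QPCR_GENE,
        "shutoff_delay_min": shutoff_delay,
        "t_illumination_min": t_illumination,
    }
    return table, truth


def gen_endpoint_population(
    stimulus: StimulusProfile,
    seed: int = 0,
    n_cells: int = 500,
    output: str = "gfp",
    threshold_median: float = 0.3,
    threshold_log_sd: float = 0.5,
    expression_log_sd: float = 0.3,
    background_median: float = 50.0,
    dt: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell endpoint outputs under a stimulation protocol.

    The deterministic pathway endpoint P for the protocol is computed once;
    each cell activates if P exceeds its lognormal activation threshold
    (median ``threshold_median`` x the continuous-6-h reference endpoint),
    reproducing the digital single-cell response to graded input.  Activated
    cells express P with lognormal noise on an arbitrary intensity scale;
    others show background only.
    """
    rng = np.random.default_rng(seed)
    out_params = GFP_OUTPUT if output == "gfp" else CD69_OUTPUT
    endpoint = predict_endpoint(stimulus, DEFAULT_CASCADE, DEFAULT_READOUT, DEFAULT_GENE, out_params, dt=dt)
    ref = predict_endpoint(
        StimulusProfile.constant(6 * 3600.0, horizon=stimulus.horizon),
        DEFAULT_CASCADE,
        DEFAULT_READOUT,
        DEFAULT_GENE,
        out_params,
        dt=dt,
    )
    thresholds = np.exp(rng.normal(np.log(threshold_median * ref), threshold_log_sd, n_cells))
    activated = endpoint >= thresholds
    intensity_scale = 1e4 / max(ref, np.finfo(float).tiny)
    expressed = endpoint * intensity_scale * np.exp(rng.normal(0.0, expression_log_sd, n_cells))
    background = np.exp(rng.normal(np.log(background_median), 0.3, n_cells))
    cells = pd.DataFrame({"intensity": np.where(activated, expressed + background, background), "activated": activated})
    truth = {
        "endpoint": endpoint,
        "reference_endpoint": ref,
        "activated_fraction": float(activated.mean()),
        "output": output,
    }
    return cells, truth


def gen_plate_measurements(
    seed: int = 0,
    slope_spread: float = 0.05,
    pwm_levels=(0, 64, 128, 192, 255),
    base_slope: float = 2.0,
    noise_sd: float = 0.5,
    dead_wells: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict]:
    """Per-well LED intensity measurements at several PWM values.

    Well slopes vary by ``slope_spread`` (relative sd) around ``base_slope``
    microW/cm^2 per PWM unit; measurement noise is additive Gaussian.  Wells
    in ``dead_wells`` emit noise only (they must be flagged by calibration).
    """
    from .protocols import WELL_IDS

    rng = np.random.default_rng(seed)
    slopes = base_slope * np.exp(rng.normal(0.0, slope_spread, len(WELL_IDS)))
    # offset spread scales with the slope spread so a zero-spread plate is uniform
    offsets = 1.0 + rng.normal(0.0, 4.0 * slope_spread, len(WELL_IDS))
    rows = []
    for well, slope, offset in zip(WELL_IDS, slopes, offsets):
        for pwm in pwm_levels:
            signal = 0.0 if well in dead_wells else slope * pwm + offset
            rows.append({"well": well, "pwm": float(pwm), "intensity": signal + rng.normal(0.0, noise_sd)})
    truth = {"slopes": dict(zip(WELL_IDS, slopes)), "dead_wells": list(dead_wells)}
    return pd.DataFrame(rows), truth


def gen_membrane_stack(
    seed: int = 0,
    k_off: float = 0.88,
    k_on: float = 0.04,
    n_frames: int = 150,
    shape: tuple[int, int] = (64, 64),
    ring_radius: float = 22.0,
    ring_width: float = 4.0,
    channel_shift: tuple[int, int] = (0, 0),
    noise_sd: float = 3.0,
    bleach_per_frame: float = 0.0,
) -> tuple[TwoChannelStack, dict]:
    """Synthetic two-channel dissociation movie.

    The marker channel is a static membrane ring; the reporter's ring
    intensity follows the receptor-bound fraction (dissociation at ``k_off``
    during the 25-50 s illumination window, recovery at ``k_on``) over a
    constant cytoplasmic pool, so the membrane/cytoplasm ratio decays as a
    clean single exponential.  Optional per-frame bleaching and a rigid
    reporter-channel offset exercise the correction and registration steps.
    The ground-truth membrane mask is included in the truth dict.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h / 2, xx - w / 2)
    ring = np.abs(r - ring_radius) <= ring_width / 2
    inside = r < ring_radius - ring_width
    times = np.arange(n_frames, dtype=float)
    bound = _bound_fraction(times, k_off, k_on, 25.0, 50.0)

    marker = np.where(ring, 300.0, 20.0)[None, :, :] + rng.normal(0.0, noise_sd, (n_frames, h, w))
    reporter = np.full((n_frames, h, w), 10.0)
    reporter[:, inside] = 100.0
    reporter = reporter + np.where(ring, 1.0, 0.0)[None, :, :] * (30.0 + 270.0 * bound)[:, None, None]
    reporter += rng.normal(0.0, noise_sd, (n_frames, h, w))
    if bleach_per_frame > 0:
        fade = (1.0 - bleach_per_frame) ** times
        marker *= fade[:, None, None]
        reporter *= fade[:, None, None]
    if channel_shift != (0, 0):
        reporter = np.roll(reporter, (-channel_shift[0], -channel_shift[1]), axis=(1, 2))
    stack = TwoChannelStack(marker, reporter, frame_interval=1.0, illumination_window=(25.0, 50.0))
    truth = {
        "k_off": k_off,
        "k_on": k_on,
        "mask": ring,
        "cytoplasm_roi": (slice(h // 2 - 6, h // 2 + 6), slice(w // 2 - 6, w // 2 + 6)),
        "background_roi": (slice(0, 6), slice(0, 6)),
        "channel_shift": channel_shift,
    }
    return stack, truth


def generate_study(outdir, seed: int = 0) -> dict:
    """Emit a complete synthetic study directory (CSV tables + truth sidecars).

    Writes the event tables, lane profiles, Ct tables and plate measurements
    with one ``*_truth.json`` sidecar each, plus a manifest listing every
    artifact and the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "artifacts": []}

    def _dump(name: str, frame: pd.DataFrame, truth: dict) -> None:
        frame.to_csv(outdir / f"{name}.csv", index=False)
        clean = {k: v for k, v in truth.items() if not isinstance(v, (np.ndarray, slice, tuple)) or k in ("backgrounds",)}
        (outdir / f"{name}_truth.json").write_text(json.dumps(clean, default=lambda o: list(o) if hasattr(o, "__iter__") else str(o), indent=1))
        manifest["artifacts"].append(name)

    traces, tr_truth = gen_lovtrap_traces(seed=seed)
    trace_frame = pd.concat(
        [pd.DataFrame({"cell": tr.meta["cell"], "time_s": tr.times, "value": tr.values}) for tr in traces],
        ignore_index=True,
    )
    _dump("lovtrap_traces", trace_frame, tr_truth)

    events, ca_truth = gen_calcium_events(seed=seed)
    _dump("calcium_events", events, ca_truth)

    samples, pp_truth = gen_pperk_samples(seed=seed)
    pperk_frame = pd.concat(
        [df.assign(time_min=tp) for tp, df in samples.items()], ignore_index=True
    )
    _dump("pperk_samples", pperk_frame, pp_truth)

    lanes, ln_truth = gen_western_lanes(seed=seed)
    lane_frame = pd.concat(
        [
            pd.DataFrame(
                {
                    "lane_id": lane.lane_id,
                    "channel": channel,
                    "coordinate": lane.coordinate,
                    "intensity": getattr(lane, f"{channel}_intensity"),
                }
            )
            for lane in lanes
            for channel in ("fos", "tpn")
        ],
        ignore_index=True,
    )
    _dump("western_lanes", lane_frame, ln_truth)

    ct, ct_truth = gen_ct_table(seed=seed)
    _dump("ct_table", ct, ct_truth)

    plate, plate_truth = gen_plate_measurements(seed=seed)
    _dump("plate_measurements", plate, {"dead_wells": plate_truth["dead_wells"]})

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
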