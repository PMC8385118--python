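"""Synthetic cohorts: agents, physiological signals and cortisol profiles.

No public recording of the validation cohort exists, so every pipeline stage
is exercised on generated data whose statistical structure matches what the
task is known to elicit: in the stress group, heart rate, respiration rate
and skin-conductance response rate rise during the four test blocks, while
heart-rate variability falls, most strongly in the second half of the test
(after the mid-test forced restart); cortisol declines linearly through the
session with a stress-dependent bump peaking shortly after the test.

A single effect multiplier ``theta`` scales all group differences: theta = 0
yields a null cohort in which the two groups are distributionally identical.
Every generator records its programmed ground truth in a manifest so that
extraction error can be measured directly.

Generators are deliberately phenomenological: beat intervals are
mean-reverting AR(1) noise with low- and high-frequency sinusoidal modulation
(an ECG rendering with Gaussian QRS complexes is available for detector
tests), EDA is a tonic drift plus Poisson-timed Bateman impulses, and
respiration is a rate-modulated oscillation.  They exist to exercise the
pipeline, not to simulate human physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_features import (
    BLOCKS,
    NNSeries,
    RawSignal,
    build_feature_table,
    extract_block_features,
)
from .task_engine import AgentSpec

__all__ = [
    "EffectProfile",
    "DEFAULT_PROFILE",
    "gen_agent_population",
    "gen_participant_signals",
    "render_ecg",
    "gen_cortisol_profiles",
    "gen_cohort",
    "block_schedule",
]


@dataclass
class EffectProfile:
    """Programmed group/block physiology targets; theta scales all effects."""

    # control-group baselines (all blocks)
    hr_bpm: float = 70.0
    sdnn_ms: float = 50.0
    resp_cpm: float = 15.0
    scr_per_min: float = 4.0
    tonic_us: float = 2.0
    # additive stress effects per block (applied to the stress group x theta)
    hr_delta: dict = field(default_factory=lambda: {
        "BL1": 0.0, "BL2": 1.0, "training": 2.0,
        "T1": 10.0, "T2": 7.0, "T3": 12.0, "T4": 12.0, "Tpost": 3.0,
    })
    resp_delta: dict = field(default_factory=lambda: {
        "BL1": 0.0, "BL2": 0.5, "training": 1.0,
        "T1": 3.5, "T2": 2.5, "T3": 4.0, "T4": 4.0, "Tpost": 1.0,
    })
    scr_delta: dict = field(default_factory=lambda: {
        "BL1": 0.0, "BL2": 0.5, "training": 1.0,
        "T1": 4.0, "T2": 3.0, "T3": 5.0, "T4": 5.0, "Tpost": 1.5,
    })
    tonic_delta: dict = field(default_factory=lambda: {
        "BL1": 0.0, "BL2": 0.1, "training": 0.2,
        "T1": 0.5, "T2": 0.4, "T3": 0.6, "T4": 0.6, "Tpost": 0.2,
    })
    # multiplicative HRV suppression (1 = none); strongest in the second half
    sdnn_mult: dict = field(default_factory=lambda: {
        "BL1": 1.0, "BL2": 1.0, "training": 0.95,
        "T1": 0.85, "T2": 0.90, "T3": 0.70, "T4": 0.70, "Tpost": 0.95,
    })
    # fraction of modulated variance in the HF band (vagal tone); lower under
    # stress in the second half -> higher lf/hf
    hf_frac: dict = field(default_factory=lambda: {
        "BL1": 0.5, "BL2": 0.5, "training": 0.5,
        "T1": 0.40, "T2": 0.45, "T3": 0.30, "T4": 0.30, "Tpost": 0.45,
    })
    # cortisol (nmol/L): session baseline, circadian slope, stress bump
    cortisol_baseline: float = 12.0
    cortisol_slope_per_min: float = -0.03
    cortisol_bump: float = 4.0
    cortisol_noise_sd: float = 0.10  # lognormal sigma
    # between-participant and measurement noise
    hr_between_sd: float = 4.0
    resp_between_sd: float = 1.2
    scr_between_sd: float = 0.8
    tonic_between_sd: float = 0.3
    signal_noise: float = 1.0  # global multiplier on measurement noise
    theta: float = 1.0

    def block_targets(self, group: str, block: str, theta: float | None = None) -> dict:
        th = self.theta if theta is None else theta
        stress = 1.0 if group == "stress" else 0.0
        e = stress * th
        return {
            "hr": self.hr_bpm + e * self.hr_delta[block],
            "sdnn": self.sdnn_ms * (1.0 + e * (self.sdnn_mult[block] - 1.0)),
            "resp": self.resp_cpm + e * self.resp_delta[block],
            "scr": self.scr_per_min + e * self.scr_delta[block],
            "tonic": self.tonic_us + e * self.tonic_delta[block],
            "hf_frac": 0.5 + e * (self.hf_frac[block] - 0.5),
        }


DEFAULT_PROFILE = EffectProfile()

BLOCK_DURATION = 150.0


def block_schedule(start: float = 0.0, duration: float = BLOCK_DURATION) -> list[tuple[str, float, float]]:
    """Contiguous 8-block schedule (BL1..Tpost), 150 s each by default."""
    return [(b, start + i * duration, start + (i + 1) * duration) for i, b in enumerate(BLOCKS)]


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------


def gen_agent_population(
    n: int,
    ability_range: tuple[float, float] = (0.3, 0.95),
    rng: np.random.Generator | int | None = None,
) -> list[AgentSpec]:
    """Agents whose arithmetic ability spans the requested accuracy range.

    Abilities (P(correct) at the 2.5 s reference display time) are evenly
    spaced over ``ability_range``; movement is a random walk.
    """
    if n < 1:
        raise ValueError("need n >= 1 agents")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    lo, hi = ability_range
    abilities = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    return [
        AgentSpec(ability=float(a), move_speed=float(rng.uniform(0.2, 0.5)))
        for a in abilities
    ]


# ---------------------------------------------------------------------------
# Physiological signals
# ---------------------------------------------------------------------------


def _gen_block_nn(
    target: dict, duration: float, start: float, rng: np.random.Generator, noise: float
) -> tuple[NNSeries, dict]:
    """Mean-reverting NN intervals with LF (0.1 Hz) / HF (0.3 Hz) modulation."""
    mean_nn = 60000.0 / target["hr"]
    sdnn = target["sdnn"]
    hf_frac = min(max(target["hf_frac"], 0.05), 0.95)
    # split programmed variance: half broadband AR(1), half sinusoidal LF/HF
    var_total = sdnn**2
    var_ar = 0.5 * var_total
    var_mod = 0.5 * var_total
    a_hf = np.sqrt(2.0 * var_mod * hf_frac)
    a_lf = np.sqrt(2.0 * var_mod * (1.0 - hf_frac))
    phi = 0.9
    eps_sd = np.sqrt(var_ar * (1 - phi**2)) * noise if noise > 0 else np.sqrt(var_ar * (1 - phi**2))

    n_max = int(duration / (mean_nn / 1000.0) * 1.5) + 10
    x = 0.0
    t = start
    beat_times = [t]
    nn = []
    ph_lf = rng.uniform(0, 2 * np.pi)
    ph_hf = rng.uniform(0, 2 * np.pi)
    for _ in range(n_max):
        x = phi * x + rng.normal(0.0, eps_sd)
        interval = mean_nn + x + a_lf * np.sin(2 * np.pi * 0.10 * t + ph_lf) + a_hf * np.sin(
            2 * np.pi * 0.30 * t + ph_hf
        )
        interval = max(interval, 300.0)
        t += interval / 1000.0
        if t >= start + duration:
            break
        beat_times.append(t)
        nn.append(interval)
    series = NNSeries(np.array(beat_times), np.array(nn))
    truth = {"hr": target["hr"], "sdnn": sdnn, "mean_nn": mean_nn, "hf_frac": hf_frac}
    return series, truth


def _gen_block_eda(
    target: dict, duration: float, start: float, fs: float, rng: np.random.Generator,
    noise: float, taus: tuple[float, float] = (1.0, 3.75),
) -> tuple[RawSignal, dict]:
    """Tonic drift plus Poisson-timed Bateman SCR impulses."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    tonic = target["tonic"] + 0.05 * np.sin(2 * np.pi * t / duration + rng.uniform(0, 2 * np.pi))
    tonic = tonic + rng.uniform(-0.02, 0.02) * t / duration
    n_scr = rng.poisson(target["scr"] * duration / 60.0)
    # keep events clear of the edges so every response is recoverable
    event_times = np.sort(rng.uniform(5.0, duration - 15.0, size=n_scr))
    # enforce a refractory gap so trough-to-peak counting can resolve them
    # (overlapping responses merge under trough-to-peak analysis)
    if len(event_times) > 1:
        keep = [0]
        for i in range(1, len(event_times)):
            if event_times[i] - event_times[keep[-1]] >= 4.0:
                keep.append(i)
        event_times = event_times[keep]
    amps = rng.lognormal(mean=np.log(0.3), sigma=0.3, size=len(event_times))
    tau1, tau2 = taus
    tk = np.arange(0, 6 * tau2, 1 / fs)
    kernel = np.exp(-tk / tau2) - np.exp(-tk / tau1)
    kernel /= kernel.max()  # unit-amplitude response per event
    phasic = np.zeros(n)
    for et, a in zip(event_times, amps):
        i = int(et * fs)
        seg = min(len(kernel), n - i)
        phasic[i : i + seg] += a * kernel[:seg]
    y = tonic + phasic + rng.normal(0, 0.004 * noise, size=n)
    sig = RawSignal("eda", fs, y, start)
    truth = {
        "scr_rate": len(event_times) * 60.0 / duration,
        "n_scr": int(len(event_times)),
        "tonic_mean": float(np.mean(tonic)),
        "event_times": (start + event_times).tolist(),
    }
    return sig, truth


def _gen_block_resp(
    target: dict, duration: float, start: float, fs: float, rng: np.random.Generator, noise: float
) -> tuple[RawSignal, dict]:
    """Rate-modulated breathing oscillation with additive noise."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    f0 = target["resp"] / 60.0
    # slow rate wobble (5% of the target)
    wob = 0.05 * f0 * np.sin(2 * np.pi * t / 60.0 + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f0 + wob) / fs
    amp = 1.0 + 0.1 * np.sin(2 * np.pi * t / 45.0 + rng.uniform(0, 2 * np.pi))
    y = amp * np.sin(phase + rng.uniform(0, 2 * np.pi)) + rng.normal(0, 0.05 * noise, size=n)
    sig = RawSignal("resp", fs, y, start)
    return sig, {"resp_cpm": target["resp"]}


def gen_participant_signals(
    group: str,
    profile: EffectProfile = DEFAULT_PROFILE,
    rng: np.random.Generator | int | None = None,
    fs_eda: float = 20.0,
    fs_resp: float = 20.0,
    theta: float | None = None,
) -> tuple[dict, dict]:
    """Eight blocks of NN / EDA / respiration plus the ground-truth manifest.

    Between-participant variation is drawn once and applied to every block;
    stress effects follow the profile's block pattern scaled by theta.
    Returns ({block: {"nn", "eda", "resp"}}, manifest).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    # participant-level offsets (identical in distribution for both groups)
    offs = {
        "hr": rng.normal(0, profile.hr_between_sd),
        "resp": rng.normal(0, profile.resp_between_sd),
        "scr": rng.normal(0, profile.scr_between_sd),
        "tonic": rng.normal(0, profile.tonic_between_sd),
        "sdnn": rng.normal(1.0, 0.08),
    }
    blocks: dict = {}
    manifest: dict = {}
    for label, start, end in block_schedule():
        tgt = profile.block_targets(group, label, theta)
        tgt = dict(tgt)
        tgt["hr"] = max(tgt["hr"] + offs["hr"], 40.0)
        tgt["resp"] = max(tgt["resp"] + offs["resp"], 6.0)
        tgt["scr"] = max(tgt["scr"] + offs["scr"], 0.2)
        tgt["tonic"] = max(tgt["tonic"] + offs["tonic"], 0.3)
        tgt["sdnn"] = max(tgt["sdnn"] * offs["sdnn"], 5.0)
        nn, nn_truth = _gen_block_nn(tgt, end - start, start, rng, profile.signal_noise)
        eda, eda_truth = _gen_block_eda(tgt, end - start, start, fs_eda, rng, profile.signal_noise)
        resp, resp_truth = _gen_block_resp(tgt, end - start, start, fs_resp, rng, profile.signal_noise)
        blocks[label] = {"nn": nn, "eda": eda, "resp": resp}
        manifest[label] = {**nn_truth, **eda_truth, **resp_truth}
    return blocks, manifest


def render_ecg(
    nn: NNSeries,
    fs: float = 1000.0,
    snr_db: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> RawSignal:
    """Render an NN series as a synthetic ECG with Gaussian QRS complexes.

    Intended for R-peak detector tests: the true beat times are the Gaussian
    centers.  ``snr_db`` adds white noise at the requested signal-to-noise
    ratio (None = noise-free).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    # pad half a second either side so no QRS is truncated at the edges
    t0 = (nn.beat_times[0] if len(nn.beat_times) else 0.0) - 0.5
    t_end = nn.beat_times[-1] if len(nn.beat_times) else 1.0
    n = int((t_end - t0) * fs) + int(0.5 * fs)
    t = t0 + np.arange(n) / fs
    y = np.zeros(n)
    width = 0.012  # s, QRS Gaussian sigma
    for bt in nn.beat_times:
        m = np.abs(t - bt) < 6 * width
        y[m] += np.exp(-0.5 * ((t[m] - bt) / width) ** 2)
        # small T-wave so the trace is not a pure spike train
        m2 = np.abs(t - bt - 0.25) < 0.3
        y[m2] += 0.25 * np.exp(-0.5 * ((t[m2] - bt - 0.25) / 0.06) ** 2)
    if snr_db is not None:
        p_sig = float(np.mean(y**2))
        p_noise = p_sig / (10 ** (snr_db / 10.0))
        y = y + rng.normal(0, np.sqrt(p_noise), size=n)
    return RawSignal("ecg", fs, y, t0)


# ---------------------------------------------------------------------------
# Cortisol
# ---------------------------------------------------------------------------

#: default clock minutes of s1..s4 (arrival; test end; +20; +40)
CORTISOL_TIMES = (0.0, 45.0, 65.0, 85.0)


def gen_cortisol_profiles(
    group: str,
    profile: EffectProfile = DEFAULT_PROFILE,
    rng: np.random.Generator | int | None = None,
    times: tuple[float, float, float, float] = CORTISOL_TIMES,
    theta: float | None = None,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """One participant's four-sample cortisol profile (values, times).

    Linear circadian decline, a stress bump weighted (0, 0.7, 1, 0) over the
    four samples (peaking between the immediate and +20 min post-test
    samples), multiplicative lognormal noise.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    th = profile.theta if theta is None else theta
    bump = profile.cortisol_bump * th if group == "stress" else 0.0
    weights = (0.0, 0.7, 1.0, 0.0)
    base = profile.cortisol_baseline + rng.normal(0, 1.5)
    vals = []
    for t, w in zip(times, weights):
        v = base + profile.cortisol_slope_per_min * t + w * bump
        v *= np.exp(rng.normal(0, profile.cortisol_noise_sd))
        vals.append(max(v, 0.1))
    return tuple(vals), tuple(times)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    features: pd.DataFrame
    cortisol: pd.DataFrame
    manifest: dict


def gen_cohort(
    n_control: int,
    n_stress: int,
    theta: float = 1.0,
    seed: int = 0,
    profile: EffectProfile = DEFAULT_PROFILE,
    fs_eda: float = 20.0,
    fs_resp: float = 20.0,
) -> Cohort:
    """End-to-end synthetic dataset: extracted feature table + cortisol + manifest.

    Signals are generated per participant, run through the actual feature
    extraction pipeline, and discarded; the manifest retains every programmed
    ground-truth value.
    """
    if n_control < 2 or n_stress < 2:
        raise ValueError("need >= 2 participants per group")
    rng = np.random.default_rng(seed)
    profile = replace(profile, theta=theta)
    participants: dict = {}
    manifest: dict = {"theta": theta, "seed": seed, "participants": {}}
    cort_rows = []
    for group, count in (("control", n_control), ("stress", n_stress)):
        for k in range(count):
            pid = f"{group[0].upper()}{k:03d}"
            sub_rng = np.random.default_rng(rng.integers(2**31))
            blocks, truth = gen_participant_signals(
                group, profile, sub_rng, fs_eda=fs_eda, fs_resp=fs_resp
            )
            fb = {
                label: extract_block_features(
                    nn=data["nn"], eda=data["eda"], resp=data["resp"], block=label
                )
                for label, data in blocks.items()
            }
            participants[pid] = (group, fb)
            manifest["participants"][pid] = {"group": group, "blocks": truth}
            vals, times = gen_cortisol_profiles(group, profile, sub_rng)
            cort_rows.append(
                {"participant_id": pid, "group": group,
                 **{f"s{i+1}": vals[i] for i in range(4)},
                 **{f"t{i+1}": times[i] for i in range(4)}}
            )
    features = build_feature_table(participants)
    cortisol = pd.DataFrame(cort_rows)
    return Cohort(features=features, cortisol=cortisol, manifest=manifest)
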