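"""Synthetic cohorts with known ground truth.

Three generators give every downstream analysis stage a planted truth to
recover:

* a coupled phase oscillator that "whispers" along with a 4.5 Hz syllable
  stream — its coupling strength and detuning control whether it behaves
  like a high synchronizer (phase-locks to the stimulus) or a low one;
* a binomial logit mixed model that emits two-alternative forced-choice
  learning responses with Condition (passive listening vs articulatory
  suppression) and Group (high vs low synchronizer) effects and participant
  random intercepts;
* a block-design BOLD generator that places spatial networks on a voxel
  grid and drives them with HRF-convolved condition regressors plus white
  Gaussian noise.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .sync import ANALYSIS_RATE_HZ, EnvelopeSignal, PhaseSeries, compute_plv, extract_phase

DT_S = 0.01  # Euler-Maruyama step, matches the 100 Hz analysis rate
TR_S = 1.5


# ---------------------------------------------------------------------------
# coupled-oscillator speech producer


@dataclass(frozen=True)
class ProducerParams:
    """Phase-oscillator model of concurrent whispered production.

    ``coupling`` (kappa, rad/s) pulls the produced phase toward the stimulus
    phase; ``natural_rate_hz`` is the speaker's spontaneous syllable rate;
    ``phase_noise_sd`` is diffusion in rad/sqrt(s).
    """

    natural_rate_hz: float = 4.5
    coupling: float = 0.0
    phase_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")
        if self.natural_rate_hz <= 0:
            raise ValueError("natural rate must be positive")


def stimulus_phase(duration_s: float, rate_hz: float = 4.5,
                   sample_rate_hz: float = ANALYSIS_RATE_HZ) -> PhaseSeries:
    """Ideal isochronous stimulus phase ramp at the given syllable rate."""
    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    theta = np.angle(np.exp(1j * 2 * np.pi * rate_hz * t))
    return PhaseSeries(theta=theta, rate_hz=sample_rate_hz)


def simulate_producer(stimulus: PhaseSeries, params: ProducerParams) -> EnvelopeSignal:
    """Integrate  d(theta) = [omega + kappa sin(theta_stim - theta)] dt + sigma dW.

    Euler-Maruyama at 10 ms; the produced envelope is (1 + cos theta)/2,
    i.e. scaled to [0, 1] with one peak per produced syllable.
    """
    if stimulus.rate_hz != 1.0 / DT_S:
        raise ValueError("stimulus must be sampled at 100 Hz")
    rng = np.random.default_rng(params.seed)
    theta_s = np.unwrap(np.asarray(stimulus.theta, float))
    n = len(theta_s)
    omega = 2 * np.pi * params.natural_rate_hz
    theta = np.empty(n)
    theta[0] = rng.uniform(-np.pi, np.pi)
    noise = params.phase_noise_sd * np.sqrt(DT_S) * rng.standard_normal(n - 1)
    for i in range(n - 1):
        drift = omega + params.coupling * np.sin(theta_s[i] - theta[i])
        theta[i + 1] = theta[i] + drift * DT_S + noise[i]
    env = 0.5 * (1.0 + np.cos(theta))
    return EnvelopeSignal(samples=env, rate_hz=1.0 / DT_S)


def producer_plv(stimulus: PhaseSeries, params: ProducerParams,
                 filtered: bool = False) -> float:
    """Convenience: produced-envelope vs stimulus PLV for one simulated speaker.

    With ``filtered`` the produced envelope goes through the full analysis
    path (resample/band-pass/Hilbert); otherwise the oscillator phase is
    compared directly to the stimulus phase, which is exact for this model.
    """
    env = simulate_producer(stimulus, params)
    if filtered:
        prod_phase = extract_phase(env)
        stim_env = EnvelopeSignal(
            samples=0.5 * (1 + np.cos(np.asarray(stimulus.theta))),
            rate_hz=stimulus.rate_hz,
        )
        stim_phase = extract_phase(stim_env)
        n = min(len(prod_phase.theta), len(stim_phase.theta))
        return compute_plv(
            PhaseSeries(prod_phase.theta[:n]), PhaseSeries(stim_phase.theta[:n])
        ).mean_plv
    # invert env = (1+cos theta)/2 is ambiguous; re-derive phase via Hilbert of env
    prod_phase = extract_phase(env)
    n = min(len(prod_phase.theta), len(stimulus.theta))
    return compute_plv(
        PhaseSeries(prod_phase.theta[:n]),
        PhaseSeries(np.asarray(stimulus.theta)[:n]),
    ).mean_plv


@dataclass(frozen=True)
class GroupOscillatorParams:
    """Per-group oscillator settings for cohort simulation."""

    coupling: float
    natural_rate_hz: float = 4.5
    phase_noise_sd: float = 0.7


HIGH_OSC = GroupOscillatorParams(coupling=8.0, natural_rate_hz=4.5, phase_noise_sd=0.7)
LOW_OSC = GroupOscillatorParams(coupling=0.0, natural_rate_hz=4.2, phase_noise_sd=0.7)


def simulate_cohort_plvs(
    n_high: int,
    n_low: int,
    seed: int,
    high: GroupOscillatorParams = HIGH_OSC,
    low: GroupOscillatorParams = LOW_OSC,
    duration_s: float = 60.0,
    stimulus_rate_hz: float = 4.5,
) -> tuple[np.ndarray, list[str]]:
    """One synchronization-test PLV per simulated participant.

    High synchronizers phase-lock through strong coupling; lows are detuned
    and uncoupled, so across a cohort the PLVs form the bimodal distribution
    seen empirically.  Returns (plvs, true_group_labels).
    """
    stim = stimulus_phase(duration_s, stimulus_rate_hz)
    rng = np.random.default_rng(seed)
    plvs, labels = [], []
    for grp, n, p in (("high", n_high, high), ("low", n_low, low)):
        for _ in range(n):
            params = ProducerParams(
                natural_rate_hz=p.natural_rate_hz,
                coupling=p.coupling,
                phase_noise_sd=p.phase_noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            plvs.append(producer_plv(stim, params))
            labels.append(grp)
    return np.asarray(plvs), labels


# ---------------------------------------------------------------------------
# behavioral 2AFC generator


@dataclass(frozen=True)
class BehaviorGenParams:
    """Generative binomial logit mixed model.

    Condition and Group are coded sum-to-zero at +/- 0.5 (PL = +0.5,
    AS = -0.5; High = +0.5, Low = -0.5), so ``beta_condition`` is directly
    the PL-AS logit difference averaged over groups, ``beta_group`` the
    High-Low difference, and ``beta_interaction`` the difference of the
    within-group PL-AS differences.  Defaults plant the empirically observed
    pattern: a condition effect carried almost entirely by the high group.
    """

    beta_intercept: float = 0.78
    beta_condition: float = 0.475
    beta_group: float = 0.525
    beta_interaction: float = 0.85
    re_sd: float = 0.5
    n_high: int = 23
    n_low: int = 32
    trials_per_condition: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.re_sd < 0:
            raise ValueError("random-effect sd must be nonnegative")
        if self.n_high < 0 or self.n_low < 0 or self.trials_per_condition <= 0:
            raise ValueError("counts must be positive")


def _code(level: str) -> float:
    return {"PL": 0.5, "AS": -0.5, "high": 0.5, "low": -0.5}[level]


def cell_logit(p: BehaviorGenParams, condition: str, group: str) -> float:
    c, g = _code(condition), _code(group)
    return (
        p.beta_intercept
        + c * p.beta_condition
        + g * p.beta_group
        + c * g * p.beta_interaction
    )


def simulate_behavior(params: BehaviorGenParams) -> tuple[pd.DataFrame, dict]:
    """Long-format 2AFC trials plus ground truth.

    Each participant receives ``trials_per_condition`` trials per condition,
    organized as blocks of 8 (one block per pseudo-language, conditions
    interleaved).  Returns (dataframe, ground_truth) where ground truth holds
    the generating coefficients and each participant's random intercept.
    """
    rng = np.random.default_rng(params.seed)
    n_blocks = max(1, params.trials_per_condition // 8)
    rows = []
    intercepts = {}
    pid = 0
    for group, n in (("high", params.n_high), ("low", params.n_low)):
        for _ in range(n):
            pid += 1
            name = f"P{pid:03d}"
            b_i = rng.normal(0.0, params.re_sd) if params.re_sd > 0 else 0.0
            intercepts[name] = b_i
            block_order = 0
            for condition in ("PL", "AS"):
                eta = cell_logit(params, condition, group) + b_i
                p_correct = expit(eta)
                for blk in range(n_blocks):
                    block_order += 1
                    lang = f"L{block_order}"
                    k = params.trials_per_condition // n_blocks
                    correct = rng.random(k) < p_correct
                    for t in range(k):
                        rows.append(
                            {
                                "participant": name,
                                "group": group,
                                "condition": condition,
                                "language": lang,
                                "block_order": block_order,
                                "trial": t + 1,
                                "correct": int(correct[t]),
                            }
                        )
    df = pd.DataFrame(rows)
    truth = {
        "beta": {
            "intercept": params.beta_intercept,
            "condition": params.beta_condition,
            "group": params.beta_group,
            "interaction": params.beta_interaction,
        },
        "re_sd": params.re_sd,
        "random_intercepts": intercepts,
    }
    return df, truth


# ---------------------------------------------------------------------------
# block-design BOLD generator


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak."""
    t = np.asarray(t, float)
    a1, a2, b = peak, undershoot, 1.0
    g1 = np.exp((a1 - 1) * np.log(np.maximum(t, 1e-12)) - b * t - gammaln(a1))
    g2 = np.exp((a2 - 1) * np.log(np.maximum(t, 1e-12)) - b * t - gammaln(a2))
    h = g1 - g2 / ratio
    h[t < 0] = 0.0
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


def default_block_design(test_duration_s: float = 24.0) -> pd.DataFrame:
    """Two-run block schedule: rest before each learning block, a self-paced
    test after it, and a speech-motor control closing each run."""
    rows = []
    t = 0.0
    for run in (1, 2):
        for cond, dur in (
            ("rest", 60.0),
            ("PL", 120.0),
            ("test", test_duration_s),
            ("rest", 60.0),
            ("AS", 120.0),
            ("test", test_duration_s),
            ("speech_motor", 120.0),
        ):
            rows.append({"run": run, "condition": cond, "onset_s": t, "duration_s": dur})
            t += dur
    return pd.DataFrame(rows)


def make_blob_map(grid_shape: tuple[int, int, int], center: tuple[float, ...],
                  radius: float) -> np.ndarray:
    """Smooth spherical activation blob (Gaussian falloff, unit peak)."""
    zz = np.indices(grid_shape).astype(float)
    d2 = sum((zz[i] - center[i]) ** 2 for i in range(3))
    return np.exp(-d2 / (2 * radius**2))


@dataclass(frozen=True)
class NetworkSpec:
    """A planted network: spatial map plus per-group, per-condition amplitudes."""

    name: str
    center: tuple[float, float, float]
    radius: float
    amplitudes: dict  # {group: {condition: amplitude}}
    subject_amp_sd: float = 0.0


def default_networks(grid_shape: tuple[int, int, int]) -> list[NetworkSpec]:
    """Two networks mirroring the empirical dissociation: an auditory network
    engaged by both groups during listening, and a frontoparietal network
    engaged only by high synchronizers during passive listening."""
    gx, gy, gz = grid_shape
    return [
        NetworkSpec(
            name="auditory",
            center=(gx * 0.3, gy * 0.3, gz * 0.5),
            radius=min(grid_shape) * 0.12,
            amplitudes={
                "high": {"PL": 1.2, "AS": 1.0},
                "low": {"PL": 1.2, "AS": 1.0},
            },
            subject_amp_sd=0.25,
        ),
        NetworkSpec(
            name="frontoparietal",
            center=(gx * 0.7, gy * 0.7, gz * 0.5),
            radius=min(grid_shape) * 0.12,
            amplitudes={
                "high": {"PL": 1.0, "AS": 0.7},
                "low": {"PL": 0.0, "AS": 0.0},
            },
            subject_amp_sd=0.25,
        ),
    ]


@dataclass
class BoldGenParams:
    """Parameters of the synthetic BOLD cohort."""

    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    tr_s: float = TR_S
    block_design: pd.DataFrame | None = None
    networks: list[NetworkSpec] | None = None
    group_labels: list[str] | None = None  # per subject, "high"/"low"
    noise_sd: float = 0.5
    baseline: float = 100.0
    motion_sd: float = 0.05
    seed: int = 0


@dataclass
class BoldDataset:
    """Per-subject 4-D BOLD arrays on a shared grid with block timing."""

    data: list[np.ndarray]  # each (x, y, z, time)
    tr_s: float
    block_timing: pd.DataFrame
    motion: list[np.ndarray]  # each (time, 6)
    mask: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.data)


def condition_regressors(
    block_timing: pd.DataFrame,
    n_trs: int,
    tr_s: float = TR_S,
    conditions: tuple[str, ...] = ("rest", "PL", "AS", "speech_motor", "test"),
    dt: float = 0.1,
) -> pd.DataFrame:
    """HRF-convolved condition boxcars sampled at TR times."""
    total_s = n_trs * tr_s
    t_hi = np.arange(0, total_s + 32.0, dt)
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt))
    out = {}
    for cond in conditions:
        box = np.zeros_like(t_hi)
        sel = block_timing[block_timing["condition"] == cond]
        for _, row in sel.iterrows():
            box[(t_hi >= row["onset_s"]) & (t_hi < row["onset_s"] + row["duration_s"])] = 1.0
        conv = np.convolve(box, hrf)[: len(t_hi)] * dt
        tr_times = np.arange(n_trs) * tr_s
        out[cond] = np.interp(tr_times, t_hi, conv)
    return pd.DataFrame(out)


def simulate_bold(params: BoldGenParams) -> tuple[BoldDataset, dict]:
    """Planted-network block-design BOLD.

    Per subject:  data(v, t) = baseline + sum_k map_k(v) * tc_k(t) + noise,
    where tc_k is the sum over conditions of the subject's amplitude for that
    condition times the HRF-convolved condition boxcar.  Returns the dataset
    and a ground-truth dict (maps, time courses, amplitudes, group labels).
    """
    rng = np.random.default_rng(params.seed)
    timing = params.block_design if params.block_design is not None else default_block_design()
    total_s = (timing["onset_s"] + timing["duration_s"]).max()
    if not np.isclose(timing["duration_s"].sum(), total_s - timing["onset_s"].min()):
        raise ValueError("block schedule must tile the run without gaps")
    n_trs = int(round(total_s / params.tr_s))
    networks = params.networks if params.networks is not None else default_networks(params.grid_shape)
    groups = params.group_labels
    if groups is None:
        half = params.n_subjects // 2
        groups = ["high"] * half + ["low"] * (params.n_subjects - half)
    if len(groups) != params.n_subjects:
        raise ValueError("one group label per subject required")

    regs = condition_regressors(timing, n_trs, params.tr_s)
    maps = [make_blob_map(params.grid_shape, nw.center, nw.radius) for nw in networks]

    data, motion, true_tcs, true_amps = [], [], [], []
    for s in range(params.n_subjects):
        vol = np.full(params.grid_shape + (n_trs,), params.baseline, float)
        subj_tcs, subj_amps = [], []
        for k, nw in enumerate(networks):
            amps = dict(nw.amplitudes.get(groups[s], {}))
            if nw.subject_amp_sd > 0:
                jitter = rng.normal(0.0, nw.subject_amp_sd)
                amps = {c: a + jitter if a != 0 else a for c, a in amps.items()}
            tc = np.zeros(n_trs)
            for cond, amp in amps.items():
                if cond in regs:
                    tc += amp * regs[cond].to_numpy()
            vol += maps[k][..., None] * tc[None, None, None, :]
            subj_tcs.append(tc)
            subj_amps.append(amps)
        if params.noise_sd > 0:
            vol += rng.normal(0.0, params.noise_sd, vol.shape)
        data.append(vol)
        true_tcs.append(np.asarray(subj_tcs))
        true_amps.append(subj_amps)
        # small AR(1) nuisance series standing in for head motion
        m = np.zeros((n_trs, 6))
        if params.motion_sd > 0:
            eps = rng.normal(0.0, params.motion_sd, (n_trs, 6))
            for t in range(1, n_trs):
                m[t] = 0.95 * m[t - 1] + eps[t]
        motion.append(m)

    dataset = BoldDataset(
        data=data, tr_s=params.tr_s, block_timing=timing, motion=motion,
        mask=np.ones(params.grid_shape, bool),
    )
    truth = {
        "true_maps": np.asarray([m.ravel() for m in maps]),
        "network_names": [nw.name for nw in networks],
        "true_timecourses": true_tcs,
        "true_amplitudes": true_amps,
        "true_group_labels": list(groups),
        "condition_regressors": regs,
    }
    return dataset, truth


def write_bold_nifti(dataset: BoldDataset, outdir, prefix: str = "sub") -> list:
    """One 4-D NIfTI per subject plus a block-timing CSV."""
    import nibabel as nib
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, vol in enumerate(dataset.data):
        img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
        p = outdir / f"{prefix}-{i + 1:02d}_bold.nii"
        nib.save(img, p)
        paths.append(p)
    dataset.block_timing.to_csv(outdir / "block_timing.csv", index=False)
    return paths


def read_bold_nifti(paths, timing_csv, tr_s: float = TR_S) -> BoldDataset:
    import nibabel as nib

    data = [np.asarray(nib.load(str(p)).dataobj, dtype=float) for p in paths]
    timing = pd.read_csv(timing_csv)
    n_trs = data[0].shape[-1]
    motion = [np.zeros((n_trs, 6)) for _ in data]
    return BoldDataset(data=data, tr_s=tr_s, block_timing=timing, motion=motion)
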