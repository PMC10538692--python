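"""Synthetic speech-like signals with known nested-AM structure.

The generator emulates the amplitude-modulation hierarchy of conversational
speech: a prosodic oscillation (1-4 Hz) whose envelope multiplies a syllabic
oscillation (4-12 Hz), which in turn multiplies a phonetic oscillation
(12-40 Hz), all riding on a fast carrier (> 40 Hz content).  Each level is a
jittered oscillation (phase random walk) rather than a pure sinusoid, so the
envelopes have realistic bandwidth.

Directed slow->fast coupling is implemented as phase-gated depth: with
coupling ``kappa`` the syllabic modulation depth follows the prosodic phase
through the gate ``1 - kappa + kappa * (1 + s_p(t)) / 2`` (RMS-normalized so
coupling strength does not alter the level's modulation power), and the
phonetic depth follows the syllabic phase analogously.  This is the
cascade-style dependence in which slower oscillators modulate faster ones,
and it is what directed transfer-entropy analysis should detect.

Cohorts come in two presets: an "NT-like" preset with strong prosodic depth
and coupling, and an "AUT-like" preset with both weakened; syllabic and
phonetic depths are matched across presets.  Questioner (partner-directed)
samples inherit a prosody depth linearly tied to their respondent's depth,
which induces the dyadic questioner-respondent correlation the group
statistics are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import SpeechSample, direction_label

#: Default grid for stored ground-truth envelopes (Hz).
DEFAULT_ENV_GRID_HZ = 160.0


@dataclass(frozen=True)
class LevelSpec:
    """One AM level: nominal oscillation rate (Hz) and modulation depth."""

    rate_hz: float
    depth: float


@dataclass(frozen=True)
class SynthSpec:
    """Full parameterization of one synthetic nested-AM signal."""

    duration_s: float = 10.0
    rate_hz: float = 8000.0
    prosody: LevelSpec = LevelSpec(2.0, 0.8)
    syllable: LevelSpec = LevelSpec(6.0, 0.6)
    phoneme: LevelSpec = LevelSpec(20.0, 0.4)
    coupling_kappa: float = 0.0
    jitter_sd: float = 0.1
    carrier: str = "white_noise"  # or "bandpass_noise_above_40hz"
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self):
        for name, lv, (lo, hi) in (
            ("prosody", self.prosody, (1.0, 4.0)),
            ("syllable", self.syllable, (4.0, 12.0)),
            ("phoneme", self.phoneme, (12.0, 40.0)),
        ):
            if not lo <= lv.rate_hz <= hi:
                raise ValueError(f"{name} rate {lv.rate_hz} Hz outside [{lo}, {hi}]")
            if not 0.0 <= lv.depth < 1.0:
                raise ValueError(f"{name} depth {lv.depth} outside [0, 1)")
        if not 0.0 <= self.coupling_kappa <= 1.0:
            raise ValueError("coupling_kappa must be in [0, 1]")
        if self.carrier not in ("white_noise", "bandpass_noise_above_40hz"):
            raise ValueError(f"unknown carrier {self.carrier!r}")

    def replace(self, **kw) -> "SynthSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class SynthSample:
    """A generated sample with its ground truth.

    ``truth`` maps band names (delta, theta_alpha, beta_gamma and a constant
    low_delta) to the true envelopes on the ``env_grid_hz`` grid;
    ``clean_waveform`` is the pre-noise product and equals
    product-of-envelopes x carrier exactly on the signal grid.
    """

    sample: SpeechSample
    truth: dict
    spec: SynthSpec
    env_grid_hz: float
    clean_waveform: np.ndarray
    carrier_waveform: np.ndarray


def _jittered_oscillation(rate_hz, n, fs, jitter_sd, rng):
    """Unit sinusoid with a slowly wandering instantaneous rate.

    The relative rate deviation is white noise low-passed at the oscillation
    rate (one cycle coherence), scaled to sd ``jitter_sd``.
    """
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    if jitter_sd <= 0:
        t = np.arange(n) / fs
        return np.sin(2.0 * np.pi * rate_hz * t + phase0)
    w = rng.standard_normal(n)
    # one-pole low-pass with cutoff ~ rate_hz
    alpha = np.exp(-2.0 * np.pi * rate_hz / fs)
    dev = sps.lfilter([1.0 - alpha], [1.0, -alpha], w)
    sd = dev.std()
    if sd > 0:
        dev = dev / sd * jitter_sd
    f_inst = rate_hz * np.clip(1.0 + dev, 0.1, None)
    phase = phase0 + 2.0 * np.pi * np.cumsum(f_inst) / fs
    return np.sin(phase)


def _phase_gate(slow_osc, kappa):
    """Depth-gating factor driven by the slower level's phase.

    ``g = 1 - kappa + kappa * (1 + s) / 2`` tracks the slow oscillation, but
    its raw mean square depends on ``kappa``; it is normalized to unit RMS so
    the gated level's modulation *power* is independent of the coupling
    strength (the groups differ in coupling without a band-power confound).
    """
    g = 1.0 - kappa + kappa * (1.0 + slow_osc) / 2.0
    rms = np.sqrt(np.mean(g**2))
    return g / rms if rms > 0 else g


def _make_carrier(kind, n, fs, rng):
    c = rng.standard_normal(n)
    if kind == "bandpass_noise_above_40hz":
        sos = sps.butter(4, 40.0, btype="highpass", fs=fs, output="sos")
        c = sps.sosfiltfilt(sos, c)
        c /= c.std()
    return c


def _to_env_grid(x, fs, env_grid_hz):
    """Anti-aliased resample of a slow envelope onto the envelope grid."""
    up = int(round(env_grid_hz))
    down = int(round(fs))
    from math import gcd

    g = gcd(up, down)
    # linear edge extension avoids roll-off artifacts at the sample ends
    return sps.resample_poly(x, up // g, down // g, padtype="line")


def generate(spec: SynthSpec, env_grid_hz: float = DEFAULT_ENV_GRID_HZ,
             meta: dict | None = None) -> SynthSample:
    """Generate one nested-AM sample with ground-truth envelopes.

    The clean waveform is ``e_p(t) * e_s(t) * e_f(t) * carrier(t)`` with
    ``e_x = 1 + d_x(t) * s_x(t)``; white noise is added at ``snr_db``.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.rate_hz
    n = int(round(spec.duration_s * fs))
    kappa = spec.coupling_kappa

    s_p = _jittered_oscillation(spec.prosody.rate_hz, n, fs, spec.jitter_sd, rng)
    s_s = _jittered_oscillation(spec.syllable.rate_hz, n, fs, spec.jitter_sd, rng)
    s_f = _jittered_oscillation(spec.phoneme.rate_hz, n, fs, spec.jitter_sd, rng)

    d_p = spec.prosody.depth
    # clip keeps every instantaneous depth < 1 (strict envelope positivity)
    d_s = np.clip(spec.syllable.depth * _phase_gate(s_p, kappa), 0.0, 0.98)
    d_f = np.clip(spec.phoneme.depth * _phase_gate(s_s, kappa), 0.0, 0.98)

    e_p = 1.0 + d_p * s_p
    e_s = 1.0 + d_s * s_s
    e_f = 1.0 + d_f * s_f

    carrier = _make_carrier(spec.carrier, n, fs, rng)
    clean = e_p * e_s * e_f * carrier
    noise_sd = np.sqrt(np.mean(clean**2)) * 10.0 ** (-spec.snr_db / 20.0)
    waveform = clean + noise_sd * rng.standard_normal(n)

    truth = {
        "low_delta": np.ones(_to_env_grid(e_p, fs, env_grid_hz).size),
        "delta": _to_env_grid(e_p, fs, env_grid_hz),
        "theta_alpha": _to_env_grid(e_s, fs, env_grid_hz),
        "beta_gamma": _to_env_grid(e_f, fs, env_grid_hz),
    }

    meta = dict(meta or {})
    sample = SpeechSample(
        sample_id=meta.get("sample_id", f"synth-{spec.seed}"),
        waveform=waveform,
        rate_hz=fs,
        role=meta.get("role", "respondent"),
        group=meta.get("group", "NT"),
        direction_label=meta.get("direction_label", "NT_speech"),
        dyad_id=meta.get("dyad_id", "d00"),
        topic=meta.get("topic", "synthetic"),
    )
    return SynthSample(
        sample=sample,
        truth=truth,
        spec=spec,
        env_grid_hz=env_grid_hz,
        clean_waveform=clean,
        carrier_waveform=carrier,
    )


#: Group presets: strong prosody/coupling for NT-like speech, weak for
#: AUT-like.  Syllabic and phonetic depths are matched across groups.
PRESETS = {
    "NT": {"prosody_beta": (7.0, 3.0), "kappa": 0.7},   # depth mean 0.7
    "AUT": {"prosody_beta": (2.0, 8.0), "kappa": 0.2},  # depth mean 0.2
}

#: Dyadic tie: questioner prosody depth = alpha + beta * respondent depth
#: + Gaussian noise, inducing a positive questioner-respondent correlation.
DYAD_ALPHA = 0.05
DYAD_BETA = 1.0
DYAD_NOISE_SD = 0.05

_DEPTH_CLIP = (0.02, 0.95)


def _draw_rates(rng):
    return {
        "prosody": rng.uniform(1.5, 3.5),
        "syllable": rng.uniform(5.0, 9.0),
        "phoneme": rng.uniform(15.0, 30.0),
    }


def generate_cohort(
    n_per_group: int,
    preset_overrides: dict | None = None,
    seed: int = 0,
    rate_hz: float = 8000.0,
    duration_range_s: tuple[float, float] = (10.0, 30.0),
    env_grid_hz: float = DEFAULT_ENV_GRID_HZ,
    n_dyads_per_group: int | None = None,
    waveforms: bool = True,
):
    """Generate a four-group cohort with dyadic structure.

    With ``waveforms=False`` only the manifest is produced (``samples`` is
    empty); the drawn speaker depths, rates and durations are identical
    either way, which makes depth-level simulation studies cheap.

    Returns ``(manifest, samples)`` where the manifest is a DataFrame in the
    audio-manifest dialect (plus direction_label) and ``samples`` is a list
    of SynthSample.  Groups: AUT_speech and NT_speech (respondents) and the
    matched AUT_directed and NT_directed questioner samples; each dyad pairs
    one respondent with one of two questioners.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    overrides = dict(preset_overrides or {})
    dyad_beta = overrides.get("dyad_beta", DYAD_BETA)
    dyad_noise_sd = overrides.get("dyad_noise_sd", DYAD_NOISE_SD)
    syl_depth = overrides.get("syllable_depth", 0.6)
    pho_depth = overrides.get("phoneme_depth", 0.4)
    kappa_override = overrides.get("kappa")  # applies to both groups if set

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_dyads = n_dyads_per_group or max(2, min(n_per_group, 8))

    # per-dyad speaker characteristics
    dyads = []
    for grp in ("AUT", "NT"):
        preset = PRESETS[grp]
        a, b = preset["prosody_beta"]
        for k in range(n_dyads):
            resp_depth = float(np.clip(rng.beta(a, b), *_DEPTH_CLIP))
            quest_depth = float(
                np.clip(
                    DYAD_ALPHA + dyad_beta * resp_depth + rng.normal(0.0, dyad_noise_sd),
                    *_DEPTH_CLIP,
                )
            )
            kappa = kappa_override if kappa_override is not None else preset["kappa"]
            # syllabic and phonetic depths vary across speakers but follow
            # the same distribution in every group (no group difference)
            dyads.append(
                {
                    "dyad_id": f"d{grp}{k:02d}",
                    "group": grp,
                    "questioner_id": f"Q{k % 2 + 1}",
                    "respondent_id": f"R{grp}{k:02d}",
                    "resp_depth": resp_depth,
                    "quest_depth": quest_depth,
                    "syl_depth": float(np.clip(rng.normal(syl_depth, 0.12), *_DEPTH_CLIP)),
                    "pho_depth": float(np.clip(rng.normal(pho_depth, 0.08), *_DEPTH_CLIP)),
                    "kappa": float(kappa),
                }
            )

    samples, rows = [], []
    child_seeds = iter(ss.generate_state(4 * n_per_group * 4).tolist())
    for grp in ("AUT", "NT"):
        grp_dyads = [d for d in dyads if d["group"] == grp]
        for role in ("respondent", "questioner"):
            for i in range(n_per_group):
                dy = grp_dyads[i % len(grp_dyads)]
                depth = dy["resp_depth"] if role == "respondent" else dy["quest_depth"]
                depth = float(np.clip(depth + rng.normal(0.0, 0.03), *_DEPTH_CLIP))
                rates = _draw_rates(rng)
                dur = rng.uniform(*duration_range_s)
                label = direction_label(role, grp if role == "respondent" else "NT", grp)
                sid = f"{label}-{i:03d}"
                spec = SynthSpec(
                    duration_s=float(dur),
                    rate_hz=rate_hz,
                    prosody=LevelSpec(rates["prosody"], depth),
                    syllable=LevelSpec(
                        rates["syllable"],
                        float(np.clip(dy["syl_depth"] + rng.normal(0.0, 0.03),
                                      *_DEPTH_CLIP)),
                    ),
                    phoneme=LevelSpec(
                        rates["phoneme"],
                        float(np.clip(dy["pho_depth"] + rng.normal(0.0, 0.03),
                                      *_DEPTH_CLIP)),
                    ),
                    coupling_kappa=dy["kappa"],
                    seed=int(next(child_seeds) % (2**31)),
                )
                meta = {
                    "sample_id": sid,
                    "role": role,
                    "group": grp if role == "respondent" else "NT",
                    "direction_label": label,
                    "dyad_id": dy["dyad_id"],
                    "topic": f"topic{i % 12:02d}",
                }
                if waveforms:
                    samples.append(generate(spec, env_grid_hz=env_grid_hz, meta=meta))
                rows.append(
                    {
                        "file": f"{sid}.wav",
                        "sample_id": sid,
                        "role": role,
                        "group": meta["group"],
                        "dyad_id": dy["dyad_id"],
                        "topic": meta["topic"],
                        "direction_label": label,
                        "speaker_id": dy["respondent_id"]
                        if role == "respondent"
                        else dy["questioner_id"],
                        "prosody_depth_truth": depth,
                        "kappa_truth": dy["kappa"],
                    }
                )
    manifest = pd.DataFrame(rows)
    return manifest, samples


def dyad_depth_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad table of questioner vs respondent true prosody depths."""
    resp = (
        manifest[manifest.role == "respondent"]
        .groupby("dyad_id")["prosody_depth_truth"]
        .mean()
        .rename("respondent_depth")
    )
    quest = (
        manifest[manifest.role == "questioner"]
        .groupby("dyad_id")["prosody_depth_truth"]
        .mean()
        .rename("questioner_depth")
    )
    return pd.concat([resp, quest], axis=1).dropna().reset_index()
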