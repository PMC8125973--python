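"""Synthetic stand-in for a phasic-pain facial-expression study.

The real study data — frontal-face videos of 127 participants receiving
heat and electrical stimuli at three calibrated intensities, cut into 7-s
stimulus-locked samples — is restricted.  This module generates data with
the same statistical skeleton so every downstream stage (descriptors,
classifiers, weighting, cross-validation) can be exercised and tested:

* per-subject expressiveness and response probabilities (many pain samples
  show *no* facial response, which acts as label noise);
* smooth stimulus-locked activation bumps on pain-related action units,
  with earlier onset and steeper rise for electrical than for heat stimuli;
* schematic parametric face frames deformed by the AU values, standing in
  for real video so the image branch of the pipeline is testable.

All generators are pure functions of their seed and configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AU_NAMES, N_AUS, PAIN_AUS, class_of

__all__ = [
    "SyntheticConfig",
    "SubjectProfile",
    "StimulusSpec",
    "AUSeriesSample",
    "SyntheticDataset",
    "make_subjects",
    "generate_sample",
    "render_frames",
    "render_frame",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Tunable parameters of the generator.

    Response probabilities and amplitudes are chosen so that, as in the
    study population, a substantial fraction of pain samples carries no
    observable facial reaction: with the default means (0.45, 0.60, 0.75)
    about 40% of pain samples are expression-free noise.
    """

    fps: float = 25.0
    duration_s: float = 7.0
    #: mean probability of any facial response at intensities 1, 2, 3
    response_prob_means: tuple[float, float, float] = (0.45, 0.60, 0.75)
    #: between-subject spread of the common response-probability offset
    response_prob_subject_sd: float = 0.15
    response_prob_intensity_sd: float = 0.05
    #: fraction of subjects with expressiveness 0 (never any facial response)
    nonresponder_frac: float = 0.05
    #: log-sd of the lognormal expressiveness distribution (median 1)
    expressiveness_sigma: float = 0.4
    baseline_noise_sd_range: tuple[float, float] = (0.10, 0.30)
    #: resting AU intensity level (mean of the half-normal offset)
    baseline_offset: float = 0.15
    noise_smooth_window: int = 5
    #: peak bump amplitude per unit intensity and unit expressiveness
    amplitude_per_intensity: float = 1.0
    amplitude_jitter_sigma: float = 0.25
    #: response-onset delay after stimulus start, seconds
    heat_onset_s: float = 3.0
    electrical_onset_s: float = 1.0
    #: onset-latency jitter (sd, seconds): thermal responses are loosely
    #: time-locked (slow ramp to the pain threshold), electrical ones tightly
    heat_onset_jitter_sd: float = 0.8
    electrical_onset_jitter_sd: float = 0.15
    #: fraction of subjects whose thermal stimulation saturates at the
    #: safety temperature cutoff, so their heat responses stop scaling
    #: beyond moderate intensity (electrical stimulation has no such cap)
    heat_cap_frac: float = 0.3
    #: time from onset to bump peak, seconds (electrical rises faster)
    heat_rise_s: float = 1.0
    electrical_rise_s: float = 0.6
    #: gamma-bump shape exponents (larger = steeper flanks)
    heat_shape: float = 2.0
    electrical_shape: float = 3.0
    #: AUs receiving the bump, with relative weights
    pain_aus: tuple[str, ...] = PAIN_AUS
    pain_au_weights: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject latent traits driving facial pain responses.

    ``heat_intensity_cap`` models the safety temperature cutoff: for
    high-tolerance subjects the thermal stimulator saturates, so heat
    stimuli beyond the cap drive the response like the cap itself
    (3 = uncapped; electrical stimulation is never capped).
    """

    subject_id: int
    expressiveness: float
    response_prob: dict[int, float]
    baseline_noise_sd: float
    heat_intensity_cap: int = 3

    def __post_init__(self) -> None:
        if self.expressiveness < 0:
            raise ValueError("expressiveness must be >= 0")
        if self.heat_intensity_cap not in (1, 2, 3):
            raise ValueError("heat_intensity_cap must be 1, 2 or 3")
        probs = [self.response_prob[i] for i in (1, 2, 3)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("response probabilities must lie in [0, 1]")
        if not (probs[0] <= probs[1] <= probs[2]):
            raise ValueError("response probability must be non-decreasing in intensity")


@dataclass(frozen=True)
class StimulusSpec:
    """One phasic stimulus: modality, calibrated intensity, and timing."""

    modality: str  # "none", "heat" or "electrical"
    intensity: int  # 0..3; 0 iff modality "none"
    onset_s: float = 0.0
    duration_s: float = 5.0

    def __post_init__(self) -> None:
        if self.modality not in ("none", "heat", "electrical"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if (self.intensity == 0) != (self.modality == "none"):
            raise ValueError("intensity 0 if and only if modality 'none'")
        if not 0 <= self.intensity <= 3:
            raise ValueError("intensity must be in 0..3")
        if self.onset_s < 0:
            raise ValueError("onset must be >= 0")

    @property
    def class_code(self) -> str:
        mod = {"none": "B", "heat": "H", "electrical": "E"}[self.modality]
        return class_of(mod, self.intensity) if mod != "B" else "B"


@dataclass
class AUSeriesSample:
    """One 7-s sample: 17 AU-intensity time series plus its class label.

    ``response_amplitude`` records the peak of the injected pain bump
    (0 for baseline samples and for pain samples without facial response);
    it is generator metadata, invisible to the classifiers.
    """

    subject_id: int
    label: str
    fps: float
    series: np.ndarray  # (17, T)
    sample_id: str = ""
    response_amplitude: float = 0.0
    frames: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] != N_AUS:
            raise ValueError(f"series must be ({N_AUS}, T), got {self.series.shape}")
        if np.any(self.series < 0):
            raise ValueError("AU intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class SyntheticDataset:
    """In-memory dataset: manifest table plus the samples it indexes."""

    manifest: pd.DataFrame
    samples: dict[str, AUSeriesSample]

    def __len__(self) -> int:
        return len(self.manifest)

    def sample(self, sample_id: str) -> AUSeriesSample:
        return self.samples[sample_id]


def make_subjects(
    n_subjects: int, seed: int, config: SyntheticConfig | None = None
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Expressiveness is lognormal (median 1); a configurable fraction of the
    cohort is forced to expressiveness 0, modelling subjects who never show
    an observable facial reaction.  Response probabilities share a subject-
    level offset and are made monotone in stimulus intensity.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    expr = rng.lognormal(mean=0.0, sigma=cfg.expressiveness_sigma, size=n_subjects)
    nonresp = rng.random(n_subjects) < cfg.nonresponder_frac
    expr[nonresp] = 0.0

    means = np.asarray(cfg.response_prob_means)
    offset = rng.normal(0.0, cfg.response_prob_subject_sd, size=n_subjects)
    eps = rng.normal(0.0, cfg.response_prob_intensity_sd, size=(n_subjects, 3))
    probs = np.clip(means[None, :] + offset[:, None] + eps, 0.0, 1.0)
    probs = np.maximum.accumulate(probs, axis=1)  # monotone in intensity

    lo, hi = cfg.baseline_noise_sd_range
    noise_sd = rng.uniform(lo, hi, size=n_subjects)
    capped = rng.random(n_subjects) < cfg.heat_cap_frac

    return [
        SubjectProfile(
            subject_id=i,
            expressiveness=float(expr[i]),
            response_prob={1: float(probs[i, 0]), 2: float(probs[i, 1]), 3: float(probs[i, 2])},
            baseline_noise_sd=float(noise_sd[i]),
            heat_intensity_cap=2 if capped[i] else 3,
        )
        for i in range(n_subjects)
    ]


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication along the last axis."""
    if window <= 1:
        return x
    half = window // 2
    padded = np.concatenate(
        [np.repeat(x[..., :1], half, axis=-1), x, np.repeat(x[..., -1:], half, axis=-1)],
        axis=-1,
    )
    kernel = np.ones(window) / window
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), -1, padded)


def _bump(t: np.ndarray, onset: float, rise: float, shape: float) -> np.ndarray:
    """Gamma-like unimodal curve: 0 before onset, peak 1 at onset+rise."""
    x = np.clip(t - onset, 0.0, None) / rise
    with np.errstate(invalid="ignore"):
        g = np.where(x > 0, np.power(x, shape) * np.exp(shape * (1.0 - x)), 0.0)
    return g


def generate_sample(
    profile: SubjectProfile,
    stim: StimulusSpec,
    seed: int,
    fps: float | None = None,
    config: SyntheticConfig | None = None,
) -> AUSeriesSample:
    """Generate one 7-s sample of 17 AU-intensity time series.

    The series is smoothed, zero-clipped baseline noise; with probability
    ``response_prob[intensity]`` a gamma-shaped activation bump is added to
    the pain-related AUs, with amplitude proportional to stimulus intensity
    and subject expressiveness.  Electrical stimuli produce earlier-onset,
    steeper bumps than heat stimuli.
    """
    cfg = config or SyntheticConfig()
    fps = cfg.fps if fps is None else float(fps)
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    n_t = int(round(cfg.duration_s * fps))
    t = np.arange(n_t) / fps

    offsets = np.abs(rng.normal(cfg.baseline_offset, cfg.baseline_offset / 2, size=(N_AUS, 1)))
    noise = rng.normal(0.0, profile.baseline_noise_sd, size=(N_AUS, n_t))
    series = offsets + _moving_average(noise, cfg.noise_smooth_window)

    amplitude = 0.0
    if stim.modality != "none":
        # the felt heat intensity saturates at the subject's temperature cap;
        # the label still records the nominal stimulus intensity
        felt = stim.intensity
        if stim.modality == "heat":
            felt = min(felt, profile.heat_intensity_cap)
        responded = rng.random() < profile.response_prob[felt]
        if responded and profile.expressiveness > 0:
            if stim.modality == "electrical":
                onset = stim.onset_s + cfg.electrical_onset_s
                onset += rng.normal(0.0, cfg.electrical_onset_jitter_sd)
                rise, shape = cfg.electrical_rise_s, cfg.electrical_shape
            else:
                onset = stim.onset_s + cfg.heat_onset_s
                onset += rng.normal(0.0, cfg.heat_onset_jitter_sd)
                rise, shape = cfg.heat_rise_s, cfg.heat_shape
            onset = max(onset, stim.onset_s)
            jitter = rng.lognormal(0.0, cfg.amplitude_jitter_sigma)
            amplitude = (
                cfg.amplitude_per_intensity * felt * profile.expressiveness * jitter
            )
            curve = amplitude * _bump(t, onset, rise, shape)
            au_index = {au: i for i, au in enumerate(AU_NAMES)}
            for au, w in zip(cfg.pain_aus, cfg.pain_au_weights):
                series[au_index[au]] += w * curve

    return AUSeriesSample(
        subject_id=profile.subject_id,
        label=stim.class_code,
        fps=fps,
        series=np.clip(series, 0.0, None),
        response_amplitude=float(amplitude),
    )


# ---------------------------------------------------------------------------
# schematic face renderer
# ---------------------------------------------------------------------------

def _draw_segment(img, x0, y0, x1, y1, width, value):
    """Darken pixels within ``width`` of the segment (coords in [-1, 1])."""
    size = img.shape[0]
    ax = np.linspace(-1.0, 1.0, size)
    gx, gy = np.meshgrid(ax, ax)
    dx, dy = x1 - x0, y1 - y0
    denom = dx * dx + dy * dy
    if denom == 0:
        tproj = np.zeros_like(gx)
    else:
        tproj = np.clip(((gx - x0) * dx + (gy - y0) * dy) / denom, 0.0, 1.0)
    dist = np.hypot(gx - (x0 + tproj * dx), gy - (y0 + tproj * dy))
    mask = np.clip(1.0 - dist / width, 0.0, 1.0)
    img -= value * mask


def _draw_ellipse(img, cx, cy, rx, ry, value, ring=None):
    size = img.shape[0]
    ax = np.linspace(-1.0, 1.0, size)
    gx, gy = np.meshgrid(ax, ax)
    ry = max(ry, 1e-3)
    d = np.hypot((gx - cx) / rx, (gy - cy) / ry)
    if ring is None:
        mask = np.clip(1.0 - np.clip(d - 1.0, 0.0, None) / 0.15, 0.0, 1.0)
    else:
        mask = np.clip(1.0 - np.abs(d - 1.0) / ring, 0.0, 1.0)
    img -= value * mask


def render_frame(au: np.ndarray, size: int = 96) -> np.ndarray:
    """Render one schematic grayscale face from a 17-vector of AU intensities.

    Brow height and knit, eye aperture, nasolabial lines and mouth shape are
    driven by the corresponding AUs (intensities on the usual 0-5 scale).
    Deterministic; values in [0, 1], dark features on a light face.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    au = np.asarray(au, dtype=float)
    if au.shape != (N_AUS,):
        raise ValueError(f"expected {N_AUS} AU intensities, got shape {au.shape}")
    a = {name: min(au[i] / 5.0, 1.0) for i, name in enumerate(AU_NAMES)}

    img = np.ones((size, size), dtype=float)
    _draw_ellipse(img, 0.0, 0.0, 0.85, 0.95, 0.35, ring=0.05)

    # brows: raised by AU1/AU2, lowered and knit by AU4
    brow_y = -0.42 - 0.18 * (a["AU01"] + a["AU02"]) / 2 + 0.22 * a["AU04"]
    knit = 0.12 * a["AU04"]
    for s in (-1, 1):
        x_in, x_out = s * (0.12 + 0.04 * a["AU04"] - knit), s * 0.52
        y_in = brow_y + 0.10 * a["AU04"] - 0.08 * a["AU01"]
        _draw_segment(img, x_in, y_in, x_out, brow_y + 0.04, 0.05, 0.8)

    # eyes: aperture widened by AU5, narrowed by AU6/AU7, closed by AU45
    aperture = 0.10 * (1.0 + 0.6 * a["AU05"]) * (1.0 - 0.85 * a["AU45"])
    aperture *= 1.0 - 0.5 * max(a["AU06"], a["AU07"])
    for s in (-1, 1):
        _draw_ellipse(img, s * 0.32, -0.22, 0.16, max(aperture, 0.012), 0.7)

    # nose wrinkle / nasolabial furrow from AU9 and AU10
    naso = 0.9 * max(a["AU09"], a["AU10"])
    if naso > 1e-3:
        for s in (-1, 1):
            _draw_segment(img, s * 0.14, 0.10, s * 0.30, 0.34, 0.04, naso)
    _draw_segment(img, -0.06, 0.12, 0.06, 0.12, 0.05, 0.3 + 0.5 * a["AU09"])

    # mouth: opening from AU25/AU26, corners from AU12 (up) and AU15 (down)
    mouth_open = 0.03 + 0.10 * a["AU25"] + 0.16 * a["AU26"]
    corner = 0.10 * a["AU12"] - 0.10 * a["AU15"]
    width = 0.26 * (1.0 + 0.4 * a["AU12"] + 0.2 * a["AU20"])
    _draw_ellipse(img, 0.0, 0.52, width, mouth_open, 0.7)
    for s in (-1, 1):
        _draw_segment(img, s * width, 0.52 - corner, s * (width + 0.06), 0.52 - 2 * corner,
                      0.04, 0.4 * abs(corner) / 0.10 if corner else 0.0)

    return np.clip(img, 0.0, 1.0)


def render_frames(
    sample: AUSeriesSample, size: int = 96, indices: list[int] | None = None
) -> list[np.ndarray]:
    """Render schematic face frames for a sample (all frames by default).

    ``indices`` restricts rendering to the requested frame positions, which
    keeps image-branch pipelines cheap when only a few key frames are needed.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    idx = range(sample.n_frames) if indices is None else indices
    return [render_frame(sample.series[:, i], size=size) for i in idx]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

_CLASS_STIMULI: dict[str, StimulusSpec] = {
    "B": StimulusSpec("none", 0),
    **{f"H{i}": StimulusSpec("heat", i) for i in (1, 2, 3)},
    **{f"E{i}": StimulusSpec("electrical", i) for i in (1, 2, 3)},
}


def generate_dataset(
    n_subjects: int,
    reps_per_class: int,
    seed: int,
    fps: float | None = None,
    config: SyntheticConfig | None = None,
    outdir: str | Path | None = None,
    write_frames: bool = False,
    frame_size: int = 96,
) -> SyntheticDataset:
    """Generate a balanced cohort dataset: ``reps_per_class`` samples of each
    of the 7 classes per subject.

    With ``outdir`` set, per-sample AU CSVs (OpenFace dialect), optional
    frame PNGs and a manifest CSV are written to disk; otherwise the dataset
    stays in memory.  Deterministic: two calls with the same arguments yield
    identical manifests and samples.
    """
    if reps_per_class < 1:
        raise ValueError("reps_per_class must be >= 1")
    cfg = config or SyntheticConfig()
    if fps is not None:
        cfg = dataclasses.replace(cfg, fps=float(fps))

    subjects = make_subjects(n_subjects, seed, cfg)
    root = np.random.SeedSequence(seed)
    # one child seed per (subject, class, rep), drawn in a fixed order
    n_per_subject = 7 * reps_per_class
    child_seeds = root.generate_state(n_subjects * n_per_subject + 1)[1:] % (2**31)

    rows = []
    samples: dict[str, AUSeriesSample] = {}
    k = 0
    for prof in subjects:
        for cls, stim in _CLASS_STIMULI.items():
            for rep in range(reps_per_class):
                sid = f"s{prof.subject_id:03d}_{cls}_{rep:02d}"
                sample = generate_sample(prof, stim, int(child_seeds[k]), config=cfg)
                sample.sample_id = sid
                samples[sid] = sample
                rows.append({"sample_id": sid, "subject_id": prof.subject_id,
                             "class": cls, "au_csv": "", "frames_dir": ""})
                k += 1
    manifest = pd.DataFrame(rows)

    if outdir is not None:
        from . import io as pio

        outdir = Path(outdir)
        (outdir / "au").mkdir(parents=True, exist_ok=True)
        for row in rows:
            sid = row["sample_id"]
            au_path = outdir / "au" / f"{sid}.csv"
            pio.write_au_csv(samples[sid], au_path)
            row["au_csv"] = str(au_path)
            if write_frames:
                fdir = outdir / "frames" / sid
                fdir.mkdir(parents=True, exist_ok=True)
                pio.write_frame_pngs(render_frames(samples[sid], size=frame_size), fdir)
                row["frames_dir"] = str(fdir)
        manifest = pd.DataFrame(rows)
        pio.write_manifest(manifest, outdir / "manifest.csv")

    return SyntheticDataset(manifest=manifest, samples=samples)
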