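"""Synthetic infant-movement cohorts with known complexity and coupling.

No public recording of the kind of supine infant video this pipeline targets
exists, so validation rests on a generator with known ground truth.  Each
synthetic infant is built in three layers:

1. **Angle trajectories.**  Each angle-bearing joint follows a quasi-periodic
   oscillation around a midline:  theta(t) = midline + A * z(t)  with the
   standardized drive  z proportional to (1 - lambda) * sin(2 pi f t + phi)
   + lambda * s(t),  where s(t) is a smoothed first-order autoregressive
   process and the irregularity lambda in [0, 1] mixes the deterministic and
   stochastic components at constant amplitude.  Because the sample-entropy
   tolerance scales with the series sd, holding amplitude fixed lets lambda
   tune measured complexity directly.  Inter-joint coupling kappa mixes
   standardized drives (corr(z_a, z_b) ~= kappa); by default the ipsilateral
   hip and knee are strongly coupled, as real infant kicking is.

2. **Skeleton projection.**  A 2D supine skeleton with fixed segment lengths
   places the 12 keypoints by forward kinematics so that the pipeline's
   angle definitions recover each scripted angle exactly; pixel-level
   Gaussian jitter and a temporally clustered low-confidence (occlusion)
   model are then applied.  Left-side rotations mirror right-side ones, so a
   bilaterally identical script yields exactly reflected tracks.

3. **Outcome model.**  HINE = a + b * lambda + noise, clipped to [0, 78] and
   rounded; per-infant lambda comes from a two-component mixture so low-
   irregularity infants receive systematically lower scores, mirroring the
   association between reduced movement complexity and neurological risk.

Pipeline stages never read the ground truth; it exists only for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats as _sstats
from scipy.signal import lfilter

from .errors import ConfigError
from .joints import ANGLE_JOINTS, JOINTS, Joint
from .keypoint_io import KeypointSeries, write_keypoints

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "InfantTruth",
    "generate_angle_trajectory",
    "project_skeleton",
    "simulate_infant",
    "generate_cohort",
    "Cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters for a synthetic cohort.

    Defaults emulate the target study design: 65 infants, 3-minute
    recordings at 30 fps, a two-component irregularity mixture whose
    low/high modes map through the outcome model onto HINE group means of
    about 51 and 69 with a roughly 16/49 split at the cut of 60.
    """

    n_infants: int = 65
    duration_s: float = 180.0
    frame_rate: float = 30.0
    seed: int = 0

    # oscillation: per-joint frequency drawn uniformly from this range (Hz);
    # amplitude is the RMS excursion in degrees around the midline.  The
    # oscillation is slow relative to the stochastic component so that the
    # irregular content is also the relatively fast, jerky content and
    # measured sample entropy increases monotonically with lambda.
    freq_range_hz: tuple[float, float] = (0.03, 0.06)
    amplitude_deg: float = 18.0
    midline_deg: float = 90.0

    # irregularity mixture (lambda in [0, 1])
    lambda_low: float = 0.20
    lambda_high: float = 0.75
    lambda_sd: float = 0.05
    low_fraction: float = 16 / 65

    # stochastic component: AR(1) time constant and post-smoothing (seconds)
    ar_timescale_s: float = 0.5
    ar_smooth_s: float = 0.2

    # inter-joint coupling: target correlation per joint pair
    coupling: tuple[tuple[str, str, float], ...] = (
        ("right_hip", "right_knee", 0.9),
        ("left_hip", "left_knee", 0.9),
    )

    # detection noise: pixel jitter sd and confidence/occlusion model
    jitter_px: float = 1.0
    dropout: float = 0.05  # target fraction of observations with conf < 0.5
    occlusion_mean_s: float = 0.4  # mean occluded-run length
    conf_clear: tuple[float, float] = (8.0, 2.0)  # Beta params, clear state
    conf_occluded: tuple[float, float] = (2.0, 8.0)  # Beta params, occluded

    # outcome model: HINE = intercept + slope * lambda + N(0, noise_sd);
    # with the default lambda mixture the group means land near 51 and 69
    hine_intercept: float = 44.5
    hine_slope: float = 33.0
    hine_noise_sd: float = 5.5
    corrected_age_mean: float = 3.75  # months at examination
    corrected_age_sd: float = 0.3

    # torso geometry (pixels, image y-down): segment lengths and widths
    shoulder_halfwidth_px: float = 30.0
    hip_halfwidth_px: float = 25.0
    torso_length_px: float = 80.0
    upper_arm_px: float = 40.0
    forearm_px: float = 35.0
    thigh_px: float = 45.0
    shank_px: float = 40.0
    center_px: tuple[float, float] = (160.0, 120.0)

    def __post_init__(self) -> None:
        if self.n_infants < 1 or self.duration_s <= 0 or self.frame_rate <= 0:
            raise ConfigError("n_infants, duration_s and frame_rate must be positive")
        for name, val in (
            ("lambda_low", self.lambda_low),
            ("lambda_high", self.lambda_high),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        for k in (
            self.upper_arm_px,
            self.forearm_px,
            self.thigh_px,
            self.shank_px,
            self.shoulder_halfwidth_px,
            self.hip_halfwidth_px,
            self.torso_length_px,
        ):
            if k <= 0:
                raise ConfigError("skeleton segment lengths must be > 0")
        for a, b, kappa in self.coupling:
            Joint(a), Joint(b)
            if not 0.0 <= kappa <= 1.0:
                raise ConfigError(f"coupling kappa must be in [0, 1], got {kappa}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass
class InfantTruth:
    """Ground truth for one synthetic infant (never read by pipeline stages)."""

    infant_id: str
    lam: float
    component: str  # "low" or "high" irregularity mixture component
    coupling: dict[tuple[str, str], float]
    hine_global: int
    hine_latent: float
    clean_angles: dict[Joint, np.ndarray]


@dataclass
class GroundTruth:
    infants: list[InfantTruth] = field(default_factory=list)

    def lam(self) -> np.ndarray:
        return np.array([i.lam for i in self.infants])


@dataclass
class Cohort:
    """In-memory synthetic cohort: keypoints, outcomes table rows, truth."""

    config: SynthConfig
    series: list[KeypointSeries]
    outcomes: "object"  # pandas.DataFrame (kept loose to avoid import cycles)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# angle trajectories


def _ar_noise(n: int, dt: float, timescale_s: float, smooth_s: float, rng) -> np.ndarray:
    """Standardized smoothed AR(1) process with a frame-rate-free time scale."""
    rho = float(np.exp(-dt / timescale_s))
    eps = rng.standard_normal(n)
    s = lfilter([np.sqrt(1.0 - rho * rho)], [1.0, -rho], eps)
    k = max(1, int(round(smooth_s / dt)))
    if k > 1:
        kernel = np.ones(k) / k
        s = np.convolve(s, kernel, mode="same")
    sd = s.std()
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


def _standardize(z: np.ndarray) -> np.ndarray:
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def _drive(config: SynthConfig, lam: float, freq: float, phase: float, rng) -> np.ndarray:
    n = config.n_frames
    dt = 1.0 / config.frame_rate
    t = np.arange(n) * dt
    det = np.sin(2.0 * np.pi * freq * t + phase)
    sto = _ar_noise(n, dt, config.ar_timescale_s, config.ar_smooth_s, rng)
    return _standardize((1.0 - lam) * det + lam * sto)


def generate_angle_trajectory(
    config: SynthConfig,
    joint: Joint,
    rng: np.random.Generator,
    lam: float | None = None,
    freq: float | None = None,
    phase: float | None = None,
    warn_clip_fraction: float = 0.10,
) -> np.ndarray:
    """Clean (noise-free at the keypoint level) angle trajectory, degrees.

    theta(t) = midline + amplitude * z(t) clipped to [0, 180], with the
    standardized drive z described in the module docstring.  lambda = 0 gives
    a pure sinusoid, amplitude 0 a constant midline.  Warns (via
    :class:`ConfigError` message in the warning) when clipping affects more
    than ``warn_clip_fraction`` of frames.
    """
    if joint not in ANGLE_JOINTS:
        raise ConfigError(f"{joint.value} does not carry an angle")
    if lam is None:
        lam = config.lambda_high
    if not 0.0 <= lam <= 1.0:
        raise ConfigError(f"lambda must be in [0, 1], got {lam}")
    if freq is None:
        freq = float(rng.uniform(*config.freq_range_hz))
    if phase is None:
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
    if config.amplitude_deg == 0.0:
        return np.full(config.n_frames, config.midline_deg)
    z = _drive(config, lam, freq, phase, rng)
    theta = config.midline_deg + config.amplitude_deg * z
    clipped = (theta < 0.0) | (theta > 180.0)
    if clipped.mean() > warn_clip_fraction:
        import warnings

        warnings.warn(
            f"{joint.value}: amplitude {config.amplitude_deg} deg drives clipping on "
            f"{100 * clipped.mean():.1f}% of frames",
            stacklevel=2,
        )
    return np.clip(theta, 0.0, 180.0)


def _infant_angles(
    config: SynthConfig, lam: float, rng: np.random.Generator
) -> dict[Joint, np.ndarray]:
    """Eight coupled angle trajectories for one infant."""
    drives: dict[Joint, np.ndarray] = {}
    for j in ANGLE_JOINTS:
        freq = float(rng.uniform(*config.freq_range_hz))
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        drives[j] = _drive(config, lam, freq, phase, rng)
    for a_name, b_name, kappa in config.coupling:
        a, b = Joint(a_name), Joint(b_name)
        drives[b] = _standardize(
            kappa * drives[a] + np.sqrt(max(0.0, 1.0 - kappa * kappa)) * drives[b]
        )
    return {
        j: np.clip(config.midline_deg + config.amplitude_deg * z, 0.0, 180.0)
        for j, z in drives.items()
    }


# ---------------------------------------------------------------------------
# skeleton projection


def _rot(theta_deg: np.ndarray, sign: float) -> tuple[np.ndarray, np.ndarray]:
    th = np.radians(theta_deg) * sign
    return np.cos(th), np.sin(th)


def _place(
    origin_x, origin_y, toward_x, toward_y, length: float, theta_deg: np.ndarray, sign: float
):
    """Point at ``length`` from origin, rotated theta from the ray origin->toward."""
    ux = toward_x - origin_x
    uy = toward_y - origin_y
    norm = np.hypot(ux, uy)
    ux, uy = ux / norm, uy / norm
    c, s = _rot(theta_deg, sign)
    rx = ux * c - uy * s
    ry = ux * s + uy * c
    return origin_x + length * rx, origin_y + length * ry


def _occlusion_states(n: int, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean occluded-state sequence from a two-state Markov chain.

    Target: the marginal probability of confidence < 0.5 equals
    ``config.dropout``.  Occluded runs have geometric lengths with mean
    ``occlusion_mean_s``; the clear-state mean run length is set to give the
    required occupancy.
    """
    if config.dropout == 0.0:
        return np.zeros(n, dtype=bool)
    p_lo_below = float(_sstats.beta.cdf(0.5, *config.conf_occluded))
    p_hi_below = float(_sstats.beta.cdf(0.5, *config.conf_clear))
    if not p_hi_below <= config.dropout <= p_lo_below:
        raise ConfigError(
            f"dropout {config.dropout} unreachable with confidence Beta models "
            f"(attainable range [{p_hi_below:.3f}, {p_lo_below:.3f}])"
        )
    occupancy = (config.dropout - p_hi_below) / (p_lo_below - p_hi_below)
    mean_occ = max(1.0, config.occlusion_mean_s * config.frame_rate)
    p_exit = 1.0 / mean_occ
    mean_clear = mean_occ * (1.0 - occupancy) / occupancy
    p_enter = 1.0 / mean_clear
    states = np.zeros(n, dtype=bool)
    u = rng.random(n)
    state = bool(rng.random() < occupancy)
    for i in range(n):
        states[i] = state
        if state:
            state = not (u[i] < p_exit)
        else:
            state = u[i] < p_enter
    return states


def project_skeleton(
    angles: dict[Joint, np.ndarray],
    config: SynthConfig,
    rng: np.random.Generator,
    infant_id: str = "synthetic",
) -> KeypointSeries:
    """Forward-kinematic 2D projection of scripted angles onto 12 keypoints.

    The torso (shoulders and hips) is static and bilaterally symmetric about
    the image center; elbows, wrists, knees and ankles are placed so that the
    pipeline's interior-angle definitions recover each scripted angle exactly
    (before noise).  Gaussian pixel jitter and the clustered low-confidence
    occlusion model are then applied per joint.
    """
    n = config.n_frames
    cx, cy = config.center_px
    pos: dict[Joint, tuple[np.ndarray, np.ndarray]] = {}
    ones = np.ones(n)
    # static torso, y-down: shoulders above hips in image coordinates
    pos[Joint.RIGHT_SHOULDER] = (ones * (cx - config.shoulder_halfwidth_px), ones * (cy - config.torso_length_px / 2))
    pos[Joint.LEFT_SHOULDER] = (ones * (cx + config.shoulder_halfwidth_px), ones * (cy - config.torso_length_px / 2))
    pos[Joint.RIGHT_HIP] = (ones * (cx - config.hip_halfwidth_px), ones * (cy + config.torso_length_px / 2))
    pos[Joint.LEFT_HIP] = (ones * (cx + config.hip_halfwidth_px), ones * (cy + config.torso_length_px / 2))

    def side_sign(j: Joint) -> float:
        # mirror-symmetric rotation convention: right rotates +, left -
        return 1.0 if j.side == "right" else -1.0

    for side in ("right", "left"):
        sh = Joint(f"{side}_shoulder")
        el = Joint(f"{side}_elbow")
        wr = Joint(f"{side}_wrist")
        hp = Joint(f"{side}_hip")
        kn = Joint(f"{side}_knee")
        an = Joint(f"{side}_ankle")
        sgn = side_sign(sh)
        sx, sy = pos[sh]
        ox, oy = pos[sh.mirror]
        ex, ey = _place(sx, sy, ox, oy, config.upper_arm_px, angles[sh], sgn)
        pos[el] = (ex, ey)
        wx, wy = _place(ex, ey, sx, sy, config.forearm_px, angles[el], sgn)
        pos[wr] = (wx, wy)
        hx, hy = pos[hp]
        mx, my = pos[hp.mirror]
        kx, ky = _place(hx, hy, mx, my, config.thigh_px, angles[hp], sgn)
        pos[kn] = (kx, ky)
        axx, ayy = _place(kx, ky, hx, hy, config.shank_px, angles[kn], sgn)
        pos[an] = (axx, ayy)

    x = np.empty((n, len(JOINTS)))
    y = np.empty((n, len(JOINTS)))
    conf = np.empty((n, len(JOINTS)))
    lo_a, lo_b = config.conf_occluded
    hi_a, hi_b = config.conf_clear
    for c, j in enumerate(JOINTS):
        jx, jy = pos[j]
        if config.jitter_px > 0:
            jx = jx + rng.normal(0.0, config.jitter_px, n)
            jy = jy + rng.normal(0.0, config.jitter_px, n)
        occluded = _occlusion_states(n, config, rng)
        cvals = np.where(
            occluded,
            rng.beta(lo_a, lo_b, n),
            rng.beta(hi_a, hi_b, n),
        )
        x[:, c], y[:, c], conf[:, c] = jx, jy, cvals
    return KeypointSeries(
        infant_id=infant_id,
        frame_rate=config.frame_rate,
        frames=np.arange(n, dtype=np.int64),
        x=x,
        y=y,
        confidence=conf,
    )


# ---------------------------------------------------------------------------
# cohort generation


def simulate_infant(
    config: SynthConfig,
    rng: np.random.Generator,
    infant_id: str,
    lam: float | None = None,
    component: str | None = None,
) -> tuple[KeypointSeries, InfantTruth]:
    """One synthetic infant: keypoint series plus ground truth."""
    if lam is None:
        if component is None:
            component = "low" if rng.random() < config.low_fraction else "high"
        mean = config.lambda_low if component == "low" else config.lambda_high
        lam = float(np.clip(rng.normal(mean, config.lambda_sd), 0.0, 1.0))
    elif component is None:
        mid = 0.5 * (config.lambda_low + config.lambda_high)
        component = "low" if lam < mid else "high"
    clean = _infant_angles(config, lam, rng)
    series = project_skeleton(clean, config, rng, infant_id=infant_id)
    latent = config.hine_intercept + config.hine_slope * lam + rng.normal(
        0.0, config.hine_noise_sd
    )
    hine = int(np.clip(round(latent), 0, 78))
    truth = InfantTruth(
        infant_id=infant_id,
        lam=lam,
        component=component,
        coupling={(a, b): k for a, b, k in config.coupling},
        hine_global=hine,
        hine_latent=float(latent),
        clean_angles=clean,
    )
    return series, truth


def generate_cohort(
    config: SynthConfig,
    out_dir: str | Path | None = None,
    file_format: str = "csv",
) -> Cohort:
    """Generate a full cohort; optionally write keypoint + outcome files.

    Mixture-component counts are fixed at ``round(low_fraction * n)`` low-
    irregularity infants (infants are then shuffled), so the expected HINE
    group split matches the design.  Fully reproducible from ``config.seed``:
    per-infant generators are spawned from one seed sequence, and files are
    written with deterministic formatting.

    When ``out_dir`` is given, writes ``infant_<k>.<ext>`` per infant in the
    requested dialect (``csv`` or ``pose-json``) plus ``outcomes.csv`` with
    columns infant_id, hine_global, corrected_age_months, sex_female,
    multiple_gestations.
    """
    import pandas as pd

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_infants + 1)
    master = np.random.default_rng(child_seeds[0])
    n_low = int(round(config.low_fraction * config.n_infants))
    components = np.array(["low"] * n_low + ["high"] * (config.n_infants - n_low))
    master.shuffle(components)

    series_list: list[KeypointSeries] = []
    truth = GroundTruth()
    rows = []
    for k in range(config.n_infants):
        rng = np.random.default_rng(child_seeds[k + 1])
        infant_id = f"infant_{k:03d}"
        series, itruth = simulate_infant(
            config, rng, infant_id, component=str(components[k])
        )
        series_list.append(series)
        truth.infants.append(itruth)
        age = float(rng.normal(config.corrected_age_mean, config.corrected_age_sd))
        # covariate rates differ by mixture component, emulating the cohort
        # structure in which multiple gestations were commoner in the
        # higher-scoring group
        p_multi = 0.31 if itruth.component == "low" else 0.735
        rows.append(
            {
                "infant_id": infant_id,
                "hine_global": itruth.hine_global,
                "corrected_age_months": round(age, 2),
                "sex_female": int(rng.random() < 0.40),
                "multiple_gestations": int(rng.random() < p_multi),
            }
        )
    outcomes = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = "csv" if file_format == "csv" else "json"
        for series in series_list:
            write_keypoints(series, out_dir / f"{series.infant_id}.{ext}", format=file_format)
        outcomes.to_csv(out_dir / "outcomes.csv", index=False)
        meta = {
            "n_infants": config.n_infants,
            "duration_s": config.duration_s,
            "frame_rate": config.frame_rate,
            "seed": config.seed,
            "file_format": file_format,
        }
        (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return Cohort(config=config, series=series_list, outcomes=outcomes, truth=truth)
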