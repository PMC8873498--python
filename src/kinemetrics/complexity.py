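"""Sample-entropy complexity indices for angle and angular-velocity series.

Sample entropy (SampEn) measures the irregularity of a time series: the
negative log conditional probability that two subsequences that match for m
consecutive points also match for m+1 points.  With N points, form the
N - m template vectors of length m and, over the same start indices, of
length m + 1; count the unordered pairs (i < j, self-matches excluded) whose
Chebyshev distance is at most the tolerance r:

    SampEn(m, r, N) = -ln(A / B)

where B is the length-m pair count and A the length-(m+1) pair count.  Lower
values indicate a more regular, more predictable signal; in this pipeline a
reduced SampEn of joint-angle or angular-velocity series quantifies the
reduced movement complexity associated with neurodevelopmental risk.

Defaults m = 2 and r = 0.2 x sd(series) follow the established convention
for physiological series; with a relative tolerance SampEn is invariant to
rescaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError
from .joints import ANGLE_JOINTS, Joint
from .kinematics import AngleSeries, VelocitySeries

__all__ = ["SampEnParams", "ComplexityIndices", "sample_entropy", "complexity_indices"]

#: Above this length the pairwise distance matrix would be large; count
#: matches lag-by-lag instead (identical result, bounded memory).
_CDIST_MAX_N = 1500

try:  # compiled kernel: same counts, ~100x faster on long series
    from numba import njit

    @njit(cache=True)
    def _count_jit(x, m, r):  # pragma: no cover - exercised via sample_entropy
        n = x.shape[0]
        nv = n - m
        a = 0
        b = 0
        for i in range(nv - 1):
            for j in range(i + 1, nv):
                ok = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: template length m and tolerance factor.

    The effective tolerance is ``r_factor * sd(series)`` (population sd)
    unless an absolute ``r`` is passed to :func:`sample_entropy` directly.
    """

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ValueError(f"r_factor must be > 0, got {self.r_factor}")


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Pairs (i < j) of templates within Chebyshev distance r, lengths m and m+1.

    Both counts run over the first N - m start indices (so the conditional
    probability A/B is well defined).
    """
    n = len(x)
    nv = n - m  # number of template start indices
    if _HAVE_NUMBA:
        a, b = _count_jit(np.ascontiguousarray(x, dtype=np.float64), m, float(r))
        return int(a), int(b)
    w = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n - m, m + 1)
    if nv <= _CDIST_MAX_N:
        d_m = cdist(w[:, :m], w[:, :m], metric="chebyshev")
        d_m1 = cdist(w, w, metric="chebyshev")
        iu = np.triu_indices(nv, k=1)
        b = int((d_m[iu] <= r).sum())
        a = int((d_m1[iu] <= r).sum())
        return a, b
    a = 0
    b = 0
    for lag in range(1, nv):
        d = np.abs(w[:-lag] - w[lag:])
        b += int((d[:, :m].max(axis=1) <= r).sum())
        a += int((d.max(axis=1) <= r).sum())
    return a, b


def sample_entropy(
    series: np.ndarray,
    params: SampEnParams = SampEnParams(),
    r: float | None = None,
) -> float:
    """SampEn(m, r) of a gap-free numeric series; NaN when undefined.

    Parameters
    ----------
    series
        1-D sequence without missing values, length >= m + 2.
    params
        Template length m and relative tolerance factor.
    r
        Absolute tolerance overriding ``params.r_factor * sd(series)``.

    A constant series (sd = 0, hence r = 0) returns 0 with a degenerate-input
    warning: every template matches at every length.  If no length-m or no
    length-(m+1) pair matches, the estimate is undefined and NaN is returned
    (with a warning), never an exception.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must not contain missing/non-finite values")
    m = params.m
    if len(x) < m + 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} points, got {len(x)}")
    if r is None:
        if np.ptp(x) == 0.0:
            warnings.warn("constant series: sample entropy degenerately 0", stacklevel=2)
            return 0.0
        r = params.r_factor * float(np.std(x))
    a, b = _match_counts(x, m, r)
    if b == 0 or a == 0:
        warnings.warn(
            f"sample entropy undefined: template matches A={a}, B={b}", stacklevel=2
        )
        return float("nan")
    return float(-np.log(a / b))


@dataclass
class ComplexityIndices:
    """Per-infant SampEn of each joint's angle and velocity series.

    Undefined entries (invalid joint, no template matches) are NaN.
    """

    infant_id: str
    params: SampEnParams
    angle: dict[Joint, float] = field(default_factory=dict)
    velocity: dict[Joint, float] = field(default_factory=dict)

    def as_features(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for j in ANGLE_JOINTS:
            out[f"se_angle_{j.value}"] = self.angle.get(j, float("nan"))
        for j in ANGLE_JOINTS:
            out[f"se_vel_{j.value}"] = self.velocity.get(j, float("nan"))
        return out


def complexity_indices(
    angles: dict[Joint, AngleSeries],
    velocities: dict[Joint, VelocitySeries],
    params: SampEnParams = SampEnParams(),
    infant_id: str = "",
    max_length: int | None = None,
) -> ComplexityIndices:
    """SampEn for each of the 8 angle-bearing joints' smoothed angle and velocity.

    Velocity endpoint NaNs are dropped before computation.  A joint whose
    smoothed series is unavailable yields NaN for its entries; the others are
    still computed.  ``max_length`` optionally decimates very long series
    uniformly before computation (off by default).
    """
    out = ComplexityIndices(infant_id=infant_id, params=params)
    for j in ANGLE_JOINTS:
        ang = angles.get(j)
        if ang is None or ang.smoothed is None:
            out.angle[j] = float("nan")
        else:
            out.angle[j] = _se_or_nan(ang.smoothed, params, max_length)
        vel = velocities.get(j)
        if vel is None:
            out.velocity[j] = float("nan")
        else:
            om = vel.omega[np.isfinite(vel.omega)]
            out.velocity[j] = _se_or_nan(om, params, max_length)
    return out


def _se_or_nan(x: np.ndarray, params: SampEnParams, max_length: int | None) -> float:
    x = np.asarray(x, dtype=float)
    if max_length is not None and len(x) > max_length:
        idx = np.linspace(0, len(x) - 1, max_length).round().astype(int)
        x = x[idx]
    if len(x) < params.m + 2 or not np.all(np.isfinite(x)):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sample_entropy(x, params)
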