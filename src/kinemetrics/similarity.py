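"""Inter- and intra-limb similarity via Pearson correlation of joint series.

Simultaneous flexion/extension across limbs — the hallmark of
cramped-synchronized movements — shows up as linear association between two
joints' angle (or angular-velocity) series.  The similarity index between two
joints is the Pearson product-moment correlation over frames observed in both
series (pairwise deletion).  The 8 angle-bearing joints give a symmetric 8x8
matrix with unit diagonal, i.e. 28 distinct anatomical pairs per signal kind.

Narrative strength labels follow the conventional |rho| bands: < 0.20 very
weak, 0.20-0.39 weak, 0.40-0.59 moderate, 0.60-0.79 strong, >= 0.80 very
strong (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .joints import ANGLE_JOINTS, Joint

__all__ = [
    "SimilarityMatrix",
    "pearson",
    "similarity_matrix",
    "strength_label",
    "STRENGTH_BANDS",
]

#: (upper bound on |rho|, label); the last band is open-ended.
STRENGTH_BANDS: tuple[tuple[float, str], ...] = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (np.inf, "very strong"),
)


def strength_label(rho: float, bands=STRENGTH_BANDS) -> str:
    """Narrative label for a correlation magnitude."""
    if not np.isfinite(rho):
        return "undefined"
    for upper, label in bands:
        if abs(rho) < upper:
            return label
    return bands[-1][1]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with pairwise deletion of missing frames.

    Requires at least 3 complete pairs; returns NaN (undefined) when either
    series has zero variance over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


@dataclass
class SimilarityMatrix:
    """Symmetric 8x8 Pearson-correlation table over the angle-bearing joints."""

    kind: str  # "angle" or "velocity"
    values: pd.DataFrame  # 8x8, index/columns = joint names, diagonal 1
    n_pairs: pd.DataFrame  # complete-pair counts used per entry
    infant_id: str = ""
    bands: tuple = field(default=STRENGTH_BANDS, repr=False)

    def rho(self, a: Joint, b: Joint) -> float:
        return float(self.values.loc[a.value, b.value])

    def to_long(self) -> pd.DataFrame:
        """One row per unordered joint pair: rho, n_pairs, strength label."""
        rows = []
        joints = list(ANGLE_JOINTS)
        for i, a in enumerate(joints):
            for b in joints[i + 1 :]:
                r = self.rho(a, b)
                rows.append(
                    {
                        "infant_id": self.infant_id,
                        "kind": self.kind,
                        "joint_a": a.value,
                        "joint_b": b.value,
                        "rho": r,
                        "n_pairs": int(self.n_pairs.loc[a.value, b.value]),
                        "strength_label": strength_label(r, self.bands),
                    }
                )
        return pd.DataFrame(rows)

    def as_features(self) -> dict[str, float]:
        out: dict[str, float] = {}
        joints = list(ANGLE_JOINTS)
        for i, a in enumerate(joints):
            for b in joints[i + 1 :]:
                out[f"rho_{self.kind}_{a.value}__{b.value}"] = self.rho(a, b)
        return out


def similarity_matrix(
    series: dict[Joint, np.ndarray],
    kind: str,
    infant_id: str = "",
    min_pairs: int = 3,
) -> SimilarityMatrix:
    """All 28 pairwise Pearson correlations among the 8 angle-bearing joints.

    ``series`` maps each angle-bearing joint to its per-frame signal on a
    common frame index (NaN = missing; frames missing in either member of a
    pair are dropped for that pair only).  Entries with fewer than
    ``min_pairs`` complete pairs, or zero variance, are NaN.
    """
    if kind not in ("angle", "velocity"):
        raise ValueError(f"kind must be 'angle' or 'velocity', got {kind!r}")
    joints = list(ANGLE_JOINTS)
    names = [j.value for j in joints]
    k = len(joints)
    sig = []
    for j in joints:
        if j not in series:
            raise ValueError(f"missing series for {j.value}")
        sig.append(np.asarray(series[j], dtype=float))
    vals = np.eye(k)
    npair = np.zeros((k, k), dtype=int)
    finite = [np.isfinite(x) for x in sig]
    for i in range(k):
        npair[i, i] = int(finite[i].sum())
        if npair[i, i] == 0:
            vals[i, i] = np.nan
    for i in range(k):
        for jdx in range(i + 1, k):
            ok = finite[i] & finite[jdx]
            n = int(ok.sum())
            npair[i, jdx] = npair[jdx, i] = n
            if n < min_pairs:
                r = float("nan")
            else:
                xs, ys = sig[i][ok], sig[jdx][ok]
                if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
                    r = float("nan")
                else:
                    r = float(np.corrcoef(xs, ys)[0, 1])
            vals[i, jdx] = vals[jdx, i] = r
    return SimilarityMatrix(
        kind=kind,
        values=pd.DataFrame(vals, index=names, columns=names),
        n_pairs=pd.DataFrame(npair, index=names, columns=names),
        infant_id=infant_id,
    )
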