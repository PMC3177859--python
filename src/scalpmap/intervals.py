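"""Decomposition of the brain-to-scalp gap into tissue intervals.

Along an in-plane ray from a cortical point L outward, four boundary
points are identified on the T1-like intensity profile:

* **A** — inner margin of the cranial bone marrow (first bright band),
* **B** — outer margin of the marrow,
* **C** — inner margin of the cutis (second bright band),
* **D** — outer margin of the cutis (head/air boundary of soft tissue).

The interval L-A contains the CSF, meninges and inner table (all dark and
mutually indistinguishable on T1), A-B the fatty marrow, B-C the outer
table, C-D the cutis.  Measurements are made in a single plane (axial,
coronal or sagittal) at 0.1 mm resolution; being in-plane they are an
upper bound on the true perpendicular thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Volume

__all__ = [
    "Profile",
    "IntervalSet",
    "INTERVAL_NAMES",
    "PLANE_FOR_LANDMARK",
    "intensity_profile",
    "detect_boundaries",
    "interval_lengths",
    "compare_interval_groups",
]

INTERVAL_NAMES = ("csf_inner_table", "marrow", "outer_table", "cutis")

#: Measurement plane per landmark: axial for the poles, coronal for the
#: vertex, sagittal for the parietal landmarks.  Temporal/frontal-lateral
#: landmarks are not decomposed (in vivo, the temporalis muscle defeats
#: marrow/cutis identification there).
PLANE_FOR_LANDMARK = {
    "occipital_pole": "axial",
    "frontal_pole": "axial",
    "vertex": "coronal",
    "parietal_POS": "sagittal",
}

DEFAULT_STEP = 0.1  # mm, the marking resolution


@dataclass
class Profile:
    """Intensity profile sampled at fixed steps along a ray from L."""

    positions: np.ndarray   # mm from L, strictly increasing, constant step
    intensities: np.ndarray
    start: np.ndarray       # world mm of L
    direction: np.ndarray   # unit vector

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.intensities = np.asarray(self.intensities, float)
        steps = np.diff(self.positions)
        if len(steps) == 0 or np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise ValueError("positions must increase with a constant step")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class IntervalSet:
    """The points L, A, B, C, D and the four interval lengths (mm).

    Lengths are in-plane measurements and therefore upper bounds on the
    perpendicular tissue thicknesses (``two_dimensional`` stays True).
    """

    points: dict         # name -> world mm (keys L, A, B, C, D)
    lengths: dict        # interval name -> mm
    plane: str
    two_dimensional: bool = True

    def __post_init__(self) -> None:
        order = ["L", "A", "B", "C", "D"]
        pts = np.asarray([self.points[k] for k in order], float)
        chords = pts[1:] - pts[:-1]
        seg = np.linalg.norm(chords, axis=1)
        if np.any(seg < -1e-12):
            raise ValueError("points out of order")
        total = np.linalg.norm(pts[-1] - pts[0])
        if abs(sum(self.lengths.values()) - total) > 1e-6:
            raise ValueError("interval lengths do not sum to |L-D|")
        # collinearity: each chord parallel to L->D
        ld = pts[-1] - pts[0]
        ld_n = np.linalg.norm(ld)
        if ld_n > 0:
            for c, s in zip(chords, seg):
                if s > 0 and np.linalg.norm(np.cross(c / s, ld / ld_n)) > 1e-6:
                    raise ValueError("points are not collinear")

    @property
    def total(self) -> float:
        return float(sum(self.lengths.values()))


def intensity_profile(volume: Volume, start, direction, length: float,
                      step: float = DEFAULT_STEP) -> Profile:
    """Linearly interpolated intensities along a ray from ``start``.

    ``direction`` must be a unit-normalisable vector lying in the chosen
    measurement plane; sampling runs from 0 to ``length`` mm in ``step``
    increments.  Raises if the ray leaves the volume before ``length``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    start = np.asarray(start, float)
    direction = np.asarray(direction, float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("zero direction")
    direction = direction / nrm
    positions = np.arange(0.0, length + step / 2, step)
    pts = start[None, :] + positions[:, None] * direction[None, :]
    idx = volume.world_to_index(pts)
    upper = np.asarray(volume.shape, float) - 1.0
    if np.any(idx < -1e-9) or np.any(idx > upper + 1e-9):
        raise ValueError(
            f"profile ray exits the volume before reaching {length} mm"
        )
    intensities = volume.sample(pts, order=1)
    return Profile(positions=positions, intensities=intensities,
                   start=start, direction=direction)


def _bright_bands(profile: Profile, threshold: float) -> list[tuple[int, int]]:
    above = profile.intensities > threshold
    # runs of consecutive supra-threshold samples
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
    return list(zip(starts, ends))


def detect_boundaries(profile: Profile, bright_threshold: float
                      ) -> dict[str, np.ndarray]:
    """Locate A, B, C, D on a profile with exactly two bright bands.

    The marrow and the cutis are the only hyperintense bands between brain
    and air on a T1-like profile; A/B are the edges of the first band and
    C/D of the second, each taken at the nearest profile sample to the
    threshold crossing (0.1 mm marking precision, no sub-sample fit).
    Profiles without two clean bands (e.g. bands merged because a dark
    layer vanished, or muscle in the way) are rejected.
    """
    bands = _bright_bands(profile, bright_threshold)
    if len(bands) != 2:
        raise ValueError(
            f"cannot identify marrow/cutis: expected 2 bright bands, found "
            f"{len(bands)}"
        )
    (a_i, b_i), (c_i, d_i) = bands
    pos = profile.positions

    def edge(inner: int, outer_side: str) -> float:
        # crossing lies between sample inner-1/inner (rising) or inner/inner+1
        # (falling); pick the nearer sample to the interpolated crossing.
        i = inner
        if outer_side == "rising":
            j = max(i - 1, 0)
        else:
            j = min(i + 1, len(pos) - 1)
        y0, y1 = profile.intensities[j], profile.intensities[i]
        if y1 == y0:
            return pos[i]
        frac = (bright_threshold - y0) / (y1 - y0)
        crossing = pos[j] + frac * (pos[i] - pos[j])
        return pos[int(round((crossing - pos[0]) / profile.step))]

    points = {
        "A": edge(a_i, "rising"),
        "B": edge(b_i, "falling"),
        "C": edge(c_i, "rising"),
        "D": edge(d_i, "falling"),
    }
    out = {}
    for name, s in points.items():
        out[name] = profile.start + s * profile.direction
    return out


def interval_lengths(points: dict, plane: str = "axial") -> IntervalSet:
    """Build an IntervalSet from the five collinear ordered points.

    ``points`` maps L, A, B, C, D to world-mm coordinates.  Lengths are
    Euclidean distances between consecutive points; the set is flagged as
    a 2D in-plane measurement (an upper bound on 3D thickness).
    """
    order = ["L", "A", "B", "C", "D"]
    missing = [k for k in order if k not in points]
    if missing:
        raise ValueError(f"missing points {missing}")
    pts = np.asarray([points[k] for k in order], float)
    ld = pts[-1] - pts[0]
    ld_n = np.linalg.norm(ld)
    if ld_n > 0:
        proj = (pts - pts[0]) @ (ld / ld_n)
        if np.any(np.diff(proj) < -1e-9):
            raise ValueError("points out of order along the L->D ray")
    lengths = {
        name: float(np.linalg.norm(pts[i + 1] - pts[i]))
        for i, name in enumerate(INTERVAL_NAMES)
    }
    return IntervalSet(points={k: pts[i] for i, k in enumerate(order)},
                       lengths=lengths, plane=plane)


def compare_interval_groups(sets_by_group: dict[str, list[IntervalSet]]
                            ) -> pd.DataFrame:
    """Unpaired two-sample t-test per interval between two groups.

    Pooled-variance t with df = n1 + n2 - 2, two-sided p.  Degenerate
    zero-variance comparisons with equal means report t = 0, p = 1.
    """
    if len(sets_by_group) != 2:
        raise ValueError("exactly two groups required")
    (g1, sets1), (g2, sets2) = sets_by_group.items()
    if len(sets1) < 2 or len(sets2) < 2:
        raise ValueError("need >= 2 interval sets per group")
    rows = []
    for interval in INTERVAL_NAMES:
        x = np.asarray([s.lengths[interval] for s in sets1], float)
        y = np.asarray([s.lengths[interval] for s in sets2], float)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append({
            "interval": interval,
            f"mean_{g1}": x.mean(), f"sd_{g1}": x.std(ddof=1),
            f"mean_{g2}": y.mean(), f"sd_{g2}": y.std(ddof=1),
            "t": float(t), "df": len(x) + len(y) - 2, "p": float(p),
        })
    return pd.DataFrame(rows)
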