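"""Multi-layer head phantoms and simulated developmental cohorts.

The phantom is a nested-ellipsoid head: a brain ellipsoid wrapped by four
tissue shells matching what T1-weighted MRI can distinguish between brain
and air — (1) CSF plus the inner table of the cranium (dark), (2) cranial
bone marrow (bright, fatty diploe), (3) outer table (dark compact bone),
(4) cutis, i.e. skin and subcutaneous fat (bright).  Layer boundaries are
ellipsoids whose semiaxes grow by the cumulative shell thickness; for
equal semiaxes (concentric spheres) the shell thickness along every radius
is exact, which is where tests require analytic truth.  Voxel intensities
ramp linearly across one voxel at each boundary, emulating partial-volume
averaging.

Simulated cohorts follow the linear growth model D = a*t + b per landmark
and hemisphere, with Gaussian residuals, so the statistics stage can be
validated against known generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (CANONICAL_LANDMARKS, Landmark, LandmarkSet, Volume,
                         validate_cohort)

__all__ = [
    "LayerParams",
    "PhantomTruth",
    "GrowthParams",
    "LANDMARK_DIRECTIONS",
    "default_layer_params",
    "default_growth_params",
    "make_layered_head",
    "phantom_landmarks",
    "simulate_cohort",
]

#: T1-like layer intensities (arbitrary units): fat-rich marrow and cutis
#: bright; CSF/compact bone dark but above air; air exactly zero.
DEFAULT_INTENSITIES = {
    "brain": 100.0,
    "csf_it": 30.0,
    "marrow": 180.0,
    "outer": 30.0,
    "cutis": 180.0,
    "air": 0.0,
}

LAYER_ORDER = ("csf_it", "marrow", "outer", "cutis")


@dataclass(frozen=True)
class LayerParams:
    """Geometry and intensities of the four head shells around the brain.

    Thicknesses in mm: ``t_csf_it`` (CSF + inner table, interval L-A),
    ``t_marrow`` (A-B), ``t_outer`` (outer table, B-C), ``t_cutis`` (C-D).
    """

    brain_semiaxes: tuple[float, float, float] = (50.0, 50.0, 50.0)
    t_csf_it: float = 3.4
    t_marrow: float = 2.2
    t_outer: float = 0.8
    t_cutis: float = 1.2
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.brain_semiaxes):
            raise ValueError("brain semiaxes must be positive")
        for t in self.thicknesses:
            if t < 0:
                raise ValueError("layer thicknesses must be >= 0")
        inten = self.intensities
        if inten["air"] != 0:
            raise ValueError("air intensity must be 0")
        if not (inten["marrow"] > inten["csf_it"] and inten["marrow"] > inten["outer"]
                and inten["cutis"] > inten["csf_it"] and inten["cutis"] > inten["outer"]):
            raise ValueError(
                "T1-like contrast requires marrow and cutis brighter than "
                "csf_it and outer table"
            )

    @property
    def thicknesses(self) -> tuple[float, float, float, float]:
        return (self.t_csf_it, self.t_marrow, self.t_outer, self.t_cutis)

    @property
    def total_gap(self) -> float:
        return float(sum(self.thicknesses))


#: Printed group-mean shell thicknesses (mm) for the two age groups the
#: interval analysis distinguishes.
GROUP_THICKNESSES = {
    "newborn": (3.4, 2.2, 0.8, 1.2),
    "child": (7.0, 2.8, 1.5, 1.5),
}


def default_layer_params(group: str) -> LayerParams:
    """Shell thicknesses for ``"newborn"`` or ``"child"`` head phantoms."""
    try:
        t = GROUP_THICKNESSES[group]
    except KeyError:
        raise ValueError(
            f"unknown group {group!r}; expected one of {sorted(GROUP_THICKNESSES)}"
        ) from None
    semiaxes = (50.0, 50.0, 50.0) if group == "newborn" else (65.0, 65.0, 65.0)
    return LayerParams(brain_semiaxes=semiaxes, t_csf_it=t[0], t_marrow=t[1],
                       t_outer=t[2], t_cutis=t[3])


@dataclass
class PhantomTruth:
    """Analytic ground truth for a layered-head phantom.

    ``boundary_semiaxes`` lists the five nested boundary ellipsoids (brain
    surface then the outer surface of each shell).  ``true_distance``
    evaluates the brain-to-scalp gap along the outward normal at the brain
    surface point in a given direction; exact for the nested-ellipsoid
    geometry.
    """

    boundary_semiaxes: list[tuple[float, float, float]]
    layer_thicknesses: tuple[float, float, float, float]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        semi = np.asarray(self.boundary_semiaxes, float)
        if np.any(np.diff(semi, axis=0) < -1e-12):
            raise ValueError("boundary ellipsoids must be nested")

    @property
    def brain_semiaxes(self) -> np.ndarray:
        return np.asarray(self.boundary_semiaxes[0], float)

    @property
    def scalp_semiaxes(self) -> np.ndarray:
        return np.asarray(self.boundary_semiaxes[-1], float)

    def surface_point(self, direction, boundary: int = 0) -> np.ndarray:
        """Intersection of ray t*direction (t>0) with a boundary ellipsoid."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        semi = np.asarray(self.boundary_semiaxes[boundary], float)
        t = 1.0 / np.sqrt(np.sum((d / semi) ** 2))
        return t * d

    def surface_normal(self, point, boundary: int = 0) -> np.ndarray:
        semi = np.asarray(self.boundary_semiaxes[boundary], float)
        n = np.asarray(point, float) / semi**2
        return n / np.linalg.norm(n)

    def true_distance(self, direction) -> float:
        """Brain-to-scalp gap along the outward normal at the brain-surface
        point lying in ``direction`` from the centre."""
        p = self.surface_point(direction, boundary=0)
        n = self.surface_normal(p, boundary=0)
        return self._ray_to_boundary(p, n, boundary=len(self.boundary_semiaxes) - 1)

    def _ray_to_boundary(self, origin, direction, boundary: int) -> float:
        semi = np.asarray(self.boundary_semiaxes[boundary], float)
        o = np.asarray(origin, float) / semi
        d = np.asarray(direction, float) / semi
        # |o + t d|^2 = 1
        a = d @ d
        b = 2.0 * (o @ d)
        c = o @ o - 1.0
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("ray misses the boundary ellipsoid")
        t = (-b + np.sqrt(disc)) / (2 * a)
        return float(t)

    def nearest_scalp_distance(self, point) -> float:
        """Exact minimum distance from an interior point to the scalp
        boundary (numeric minimisation over the ellipsoid surface)."""
        from scipy.optimize import minimize

        semi = self.scalp_semiaxes
        p = np.asarray(point, float)
        if np.allclose(semi, semi[0]):
            return float(semi[0] - np.linalg.norm(p))

        def objective(ang):
            theta, phi = ang
            q = semi * np.array([np.sin(theta) * np.cos(phi),
                                 np.sin(theta) * np.sin(phi),
                                 np.cos(theta)])
            return np.sum((q - p) ** 2)

        theta0 = np.arccos(np.clip(p[2] / (np.linalg.norm(p) + 1e-300), -1, 1))
        phi0 = np.arctan2(p[1], p[0])
        best = min(
            (minimize(objective, [theta0 + dt, phi0 + dp], method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14})
             for dt in (0.0, 0.3, -0.3) for dp in (0.0, 0.3, -0.3)),
            key=lambda r: r.fun,
        )
        return float(np.sqrt(best.fun))


def make_layered_head(params: LayerParams, spacing: float = 0.5,
                      margin: float = 5.0) -> tuple[Volume, PhantomTruth]:
    """Voxelise a nested-ellipsoid head phantom with T1-like intensities.

    Intensities transition linearly over one voxel at each boundary
    (partial-volume emulation), so threshold crossings at the mid-intensity
    recover boundary positions to sub-voxel accuracy.  Raises if ``spacing``
    exceeds the thinnest nonzero shell, which would make that shell vanish
    from the grid.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nonzero = [t for t in params.thicknesses if t > 0]
    if nonzero and spacing > min(nonzero):
        raise ValueError(
            f"spacing {spacing} mm exceeds thinnest nonzero layer "
            f"{min(nonzero)} mm; that layer would vanish"
        )
    semi0 = np.asarray(params.brain_semiaxes, float)
    offsets = np.concatenate([[0.0], np.cumsum(params.thicknesses)])
    boundaries = [tuple(semi0 + off) for off in offsets]

    extent = semi0 + offsets[-1] + margin
    n = np.ceil(2 * extent / spacing).astype(int) + 1
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -(n - 1) / 2.0 * spacing  # grid centred on the origin

    coords = [(-(m - 1) / 2.0 + np.arange(m)) * spacing for m in n]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]

    layer_int = [params.intensities[k] for k in
                 ("brain",) + LAYER_ORDER] + [params.intensities["air"]]
    data = np.full(tuple(n), params.intensities["air"], dtype=np.float32)
    w = spacing  # partial-volume ramp width
    for k, semi in enumerate(boundaries):
        s = np.asarray(semi, float)
        rho = np.sqrt((x / s[0]) ** 2 + (y / s[1]) ** 2 + (z / s[2]) ** 2)
        grad = np.sqrt((x / s[0] ** 2) ** 2 + (y / s[1] ** 2) ** 2
                       + (z / s[2] ** 2) ** 2)
        np.maximum(grad, 1e-12, out=grad)
        dist = (rho - 1.0) / grad  # approx. signed mm to boundary k
        inside = np.clip(0.5 - dist / w, 0.0, 1.0).astype(np.float32)
        data += (layer_int[k] - layer_int[k + 1]) * inside
        del rho, grad, dist, inside

    truth = PhantomTruth(boundary_semiaxes=boundaries,
                         layer_thicknesses=params.thicknesses,
                         spacing=(spacing,) * 3)
    return Volume(data=data, affine=affine), truth


def brain_mask_from_truth(truth: PhantomTruth, volume: Volume) -> Volume:
    """Binary brain mask on the phantom grid (rho <= 1 for the brain
    boundary ellipsoid, evaluated at voxel centres)."""
    idx = np.indices(volume.shape).reshape(3, -1).T
    pts = volume.index_to_world(idx)
    semi = truth.brain_semiaxes
    rho = np.linalg.norm(pts / semi, axis=1)
    return Volume(data=(rho <= 1.0).reshape(volume.shape).astype(np.uint8),
                  affine=volume.affine.copy())


#: Canonical unit directions (RAS) used to place phantom landmarks on the
#: brain boundary.  Poles and vertex sit at coordinate extremes; the
#: parieto-occipital sulcus and inferior frontal gyrus get fixed
#: parasagittal angles since an unfolded ellipsoid has no sulcal anatomy.
LANDMARK_DIRECTIONS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("occipital_pole", "midline"): (0.0, -1.0, 0.0),
    ("frontal_pole", "midline"): (0.0, 1.0, 0.0),
    ("vertex", "midline"): (0.0, 0.0, 1.0),
    ("heschl_gyrus", "left"): (-1.0, 0.0, 0.0),
    ("heschl_gyrus", "right"): (1.0, 0.0, 0.0),
    ("parietal_POS", "left"): (-0.25, -0.65, 0.71),
    ("parietal_POS", "right"): (0.25, -0.65, 0.71),
    ("IFG", "left"): (-0.72, 0.63, -0.29),
    ("IFG", "right"): (0.72, 0.63, -0.29),
}


def phantom_landmarks(truth: PhantomTruth,
                      directions: dict | None = None) -> LandmarkSet:
    """Place the nine canonical landmarks on the phantom brain boundary.

    Each landmark sits where the ray from the centre along its canonical
    direction meets the brain surface — the analytic analogue of picking
    cortical extreme points by hand.
    """
    if np.any(truth.brain_semiaxes <= 0):
        raise ValueError("degenerate brain semiaxes")
    directions = dict(LANDMARK_DIRECTIONS if directions is None else directions)
    entries = []
    for name, hemi in CANONICAL_LANDMARKS:
        d = np.asarray(directions[(name, hemi)], float)
        p = truth.surface_point(d / np.linalg.norm(d), boundary=0)
        entries.append(Landmark(name=name, hemisphere=hemi,
                                position=tuple(float(c) for c in p)))
    return LandmarkSet(entries=entries)


def landmark_true_distances(truth: PhantomTruth,
                            landmarks: LandmarkSet) -> dict[tuple[str, str], float]:
    """Exact nearest brain-to-scalp distance for each phantom landmark."""
    return {
        (lm.name, lm.hemisphere): truth.nearest_scalp_distance(lm.position)
        for lm in landmarks
    }


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class GrowthStratum:
    slope: float        # a, mm/month
    intercept: float    # b, mm
    sigma: float        # residual SD, mm

    def __post_init__(self) -> None:
        if self.intercept <= 0:
            raise ValueError("intercept b must be > 0 (distance at birth)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class GrowthParams:
    """Linear growth model D = a*t + b per (landmark, hemisphere).

    ``age_range`` in months; ``right_handed_fraction`` sets the Bernoulli
    handedness mix (no distance effect — handedness is simulated as a null
    factor unless strata are configured asymmetrically).
    """

    strata: dict[tuple[str, str], GrowthStratum]
    age_range: tuple[float, float] = (0.0, 144.0)
    right_handed_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("empty landmark set")
        if self.age_range[0] < 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("invalid age range")
        if not 0 <= self.right_handed_fraction <= 1:
            raise ValueError("right_handed_fraction must be in [0, 1]")


#: Reported per-landmark growth-fit parameters: slope a (mm/month),
#: intercept b (mm), and the fit r^2 the residual SD is back-computed from.
REPORTED_GROWTH_FITS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("occipital_pole", "midline"): (0.038, 4.7, 0.48),
    ("parietal_POS", "left"): (0.028, 9.1, 0.09),
    ("parietal_POS", "right"): (0.029, 9.3, 0.09),
    ("vertex", "midline"): (0.024, 9.1, 0.10),
    ("heschl_gyrus", "left"): (0.013, 7.2, 0.08),
    ("heschl_gyrus", "right"): (0.014, 8.7, 0.06),
    ("IFG", "left"): (0.021, 8.75, 0.10),
    ("IFG", "right"): (0.018, 10.2, 0.07),
    ("frontal_pole", "midline"): (0.010, 10.4, 0.08),
}

#: Pooled mean-across-landmarks fit (a, b, r^2).
REPORTED_MEAN_FIT = (0.021, 8.5, 0.15)


def sigma_from_r2(slope: float, r2: float,
                  age_range: tuple[float, float] = (0.0, 144.0)) -> float:
    """Residual SD giving expected r^2 for ages uniform on ``age_range``.

    With Var(t) = (t1-t0)^2/12 and signal variance a^2 Var(t),
    r^2 = signal / (signal + sigma^2)  =>  sigma = |a| sd(t) sqrt((1-r^2)/r^2).
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    sd_t = (age_range[1] - age_range[0]) / np.sqrt(12.0)
    return float(abs(slope) * sd_t * np.sqrt((1.0 - r2) / r2))


def default_growth_params(age_range: tuple[float, float] = (0.0, 144.0)
                          ) -> GrowthParams:
    """Growth model defaults: per-landmark (a, b) from the reported fits,
    residual SD back-computed from each fit's r^2 for uniform ages.

    The right-vs-left Heschl intercepts differ by +1.5 mm, reproducing the
    reported direction of the temporal-lobe laterality effect.
    """
    strata = {
        key: GrowthStratum(slope=a, intercept=b,
                           sigma=sigma_from_r2(a, r2, age_range))
        for key, (a, b, r2) in REPORTED_GROWTH_FITS.items()
    }
    return GrowthParams(strata=strata, age_range=age_range)


def mean_landmark_growth_params(age_range: tuple[float, float] = (0.0, 144.0)
                                ) -> GrowthParams:
    """Single-stratum model with the pooled mean-across-landmarks fit."""
    a, b, r2 = REPORTED_MEAN_FIT
    stratum = GrowthStratum(slope=a, intercept=b,
                            sigma=sigma_from_r2(a, r2, age_range))
    return GrowthParams(strata={k: stratum for k in CANONICAL_LANDMARKS},
                        age_range=age_range)


def simulate_cohort(params: GrowthParams, n_subjects: int,
                    seed: int) -> pd.DataFrame:
    """Simulate a cross-sectional cohort table.

    One row per (subject, landmark, hemisphere): age uniform on the age
    range, distance = a*t + b + N(0, sigma), redrawn in the rare case a
    draw is non-positive (distances are physical lengths).  Deterministic
    under a fixed seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(params.age_range[0], params.age_range[1], n_subjects)
    handed = np.where(rng.random(n_subjects) < params.right_handed_fraction,
                      "right", "left")
    rows = []
    for i in range(n_subjects):
        for (name, hemi), st in params.strata.items():
            mean = st.slope * ages[i] + st.intercept
            d = mean + st.sigma * rng.standard_normal()
            while d <= 0:  # truncate at zero: distances are lengths
                d = mean + st.sigma * rng.standard_normal()
            rows.append({
                "subject": f"S{i:04d}",
                "age_months": ages[i],
                "handedness": handed[i],
                "landmark": name,
                "hemisphere": hemi,
                "distance_mm": d,
            })
    return validate_cohort(pd.DataFrame(rows))
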