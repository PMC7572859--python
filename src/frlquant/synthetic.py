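"""Synthetic SDS-FRL scenes and pre-embedding profiles with ground truth.

No public raw data exist for the immunogold study this package models,
so the pipeline ships a generator that reproduces the *statistical*
structure of the published measurements and serves as ground truth for
the quantification pipeline:

* per-synapse postsynaptic (PSD) areas: lognormal, moment-matched to
  mean 0.046 um^2, SD 0.018 um^2 (wild-type spines, 12 months);
* per-synapse immunogold density: lognormal with the published group
  mean and a coefficient of variation derived from the published SEM
  and n for each genotype x age x compartment cell;
* two gold size classes: 10 nm for the pan-AMPAR channel, 5 nm for the
  GluN1 co-label;
* non-specific background at 2.3 particles/um^2 on the surrounding
  P-face;
* complete and fracture-truncated ("incomplete") synapses.

A scene is built by placing intramembrane particles (IMPs) uniformly in
a disk whose radius is calibrated so that the convex hull of the IMPs
has the drawn target area, then scattering receptor gold uniformly
inside that hull at the drawn density.  Because the labeling is strictly
inside the hull and the quantifier uses the hull area as denominator,
the measured density is an unbiased estimate of the generating density;
background on the P-face still exercises rim contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .geometry import (
    NM2_PER_UM2,
    DegenerateGeometryError,
    Point,
    Polygon,
    convex_hull,
)

Genotype = Literal["WT", "APP_PS1"]
Compartment = Literal["spine", "interneuron_shaft"]

GENOTYPES: tuple[str, ...] = ("WT", "APP_PS1")
AGES_MONTHS: tuple[int, ...] = (1, 6, 12)
COMPARTMENTS: tuple[str, ...] = ("spine", "interneuron_shaft")

#: Published per-group statistics of the pan-AMPAR immunogold density
#: (particles/um^2): mean, SEM, number of synapses, and the median and
#: range of raw per-synapse particle counts.
GROUP_TABLE: dict[tuple[str, int, str], dict[str, float]] = {
    ("WT", 1, "spine"): dict(mean=496.01, sem=23.38, n=62, count_median=18.0, count_min=2, count_max=53),
    ("WT", 1, "interneuron_shaft"): dict(mean=637.84, sem=40.58, n=46, count_median=53.5, count_min=8, count_max=165),
    ("WT", 6, "spine"): dict(mean=442.89, sem=53.27, n=53, count_median=10.0, count_min=1, count_max=25),
    ("WT", 6, "interneuron_shaft"): dict(mean=494.09, sem=33.23, n=38, count_median=18.5, count_min=2, count_max=60),
    ("WT", 12, "spine"): dict(mean=459.51, sem=16.01, n=111, count_median=19.0, count_min=2, count_max=81),
    ("WT", 12, "interneuron_shaft"): dict(mean=395.70, sem=13.70, n=135, count_median=22.0, count_min=3, count_max=95),
    ("APP_PS1", 1, "spine"): dict(mean=560.19, sem=22.13, n=66, count_median=13.5, count_min=4, count_max=40),
    ("APP_PS1", 1, "interneuron_shaft"): dict(mean=560.10, sem=28.75, n=34, count_median=20.0, count_min=7, count_max=57),
    ("APP_PS1", 6, "spine"): dict(mean=504.60, sem=53.27, n=62, count_median=12.0, count_min=1, count_max=30),
    ("APP_PS1", 6, "interneuron_shaft"): dict(mean=420.90, sem=27.05, n=37, count_median=16.0, count_min=3, count_max=87),
    ("APP_PS1", 12, "spine"): dict(mean=261.13, sem=13.01, n=109, count_median=6.0, count_min=1, count_max=39),
    ("APP_PS1", 12, "interneuron_shaft"): dict(mean=165.78, sem=6.94, n=173, count_median=10.0, count_min=1, count_max=55),
}

#: Published spine PSD area (um^2): mean +/- SD at 12 months, wild type.
SPINE_AREA_MEAN_UM2 = 0.046
SPINE_AREA_SD_UM2 = 0.018
#: Relative spread kept fixed when an area mean is recalibrated.
AREA_CV = SPINE_AREA_SD_UM2 / SPINE_AREA_MEAN_UM2

#: Published non-specific background on the P-face, particles/um^2.
BACKGROUND_RATE_PER_UM2 = 2.3

#: Default IMP density of the demarcated E-face cluster, IMPs/um^2.
#: The study reports none; this is a typical order of magnitude for
#: E-face PSD IMP clusters.
DEFAULT_IMP_DENSITY_PER_UM2 = 3500.0

#: Mean GluN1 co-label particles per synapse (Poisson): the inclusion
#: rule requires > 2, so a mean of 5 keeps most synapses eligible while
#: exercising the filter.
DEFAULT_GLUN1_RATE = 5.0

#: Default fraction of synapses truncated by the fracture plane.
DEFAULT_INCOMPLETE_FRACTION = 0.2

#: Area means (um^2) recalibrated so that the simulated median particle
#: count reproduces the published median for that cell (see
#: :func:`calibrate_area_to_median`); the study prints PSD areas only
#: for wild-type spines.  Values frozen from the shipped calibration at
#: 200,000 replicates.
_CALIBRATED_AREA_MEAN_UM2: dict[tuple[str, int, str], float] = {
    ("WT", 1, "interneuron_shaft"): 0.0980,
    ("WT", 6, "interneuron_shaft"): 0.0435,
    ("WT", 12, "interneuron_shaft"): 0.0643,
    ("APP_PS1", 1, "interneuron_shaft"): 0.0409,
    ("APP_PS1", 6, "interneuron_shaft"): 0.0448,
    ("APP_PS1", 12, "spine"): 0.0292,
    ("APP_PS1", 12, "interneuron_shaft"): 0.0720,
}


class ConfigurationError(ValueError):
    """Raised for a design cell outside the genotype x age x compartment grid."""


class CalibrationError(RuntimeError):
    """Raised when a generator calibration target is infeasible."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleRecord:
    """One immunogold particle on the replica (positions in nm)."""

    position: Point
    size_class: int  # gold diameter, nm: 5 (GluN1) or 10 (pan-AMPAR)
    channel: str  # "panAMPA" or "GluN1"
    face: str  # "E" or "P"

    def __post_init__(self) -> None:
        if self.channel == "panAMPA" and self.size_class != 10:
            raise ValueError("pan-AMPAR channel carries 10 nm gold")
        if self.channel == "GluN1" and self.size_class != 5:
            raise ValueError("GluN1 channel carries 5 nm gold")
        if self.channel not in ("panAMPA", "GluN1"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.face not in ("E", "P"):
            raise ValueError(f"unknown fracture face {self.face!r}")


@dataclass(frozen=True)
class GroupPreset:
    """Generative parameters for one cell of the study design."""

    genotype: str
    age_months: int
    compartment: str
    mean_density: float  # particles/um^2 (panAMPA, E-face)
    density_cv: float
    area_mean: float  # um^2, target mean of the demarcated hull area
    area_sd: float  # um^2
    imp_density: float = DEFAULT_IMP_DENSITY_PER_UM2  # IMPs/um^2
    background_rate: float = BACKGROUND_RATE_PER_UM2  # particles/um^2, P-face
    glun1_rate: float = DEFAULT_GLUN1_RATE  # mean particles/synapse
    incomplete_fraction: float = DEFAULT_INCOMPLETE_FRACTION
    n_synapses_default: int = 100
    density_sem: float = float("nan")  # published SEM at n_synapses_default

    def __post_init__(self) -> None:
        if self.mean_density < 0 or self.background_rate < 0 or self.glun1_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0.0 <= self.density_cv <= 1.0):
            raise ValueError(f"density_cv must be in [0, 1], got {self.density_cv}")
        if self.area_mean <= 0:
            raise ValueError("area_mean must be > 0")
        if not (0.0 <= self.incomplete_fraction <= 1.0):
            raise ValueError("incomplete_fraction must be a proportion")

    @property
    def name(self) -> str:
        geno = "wt" if self.genotype == "WT" else "app"
        comp = "spine" if self.compartment == "spine" else "shaft"
        return f"{geno}_{comp}_{self.age_months}m"


@dataclass
class SynapseScene:
    """One fractured synapse with ground truth."""

    scene_id: int
    imp_points: np.ndarray  # (n, 2) nm
    true_polygon: Polygon  # hull of the IMPs (post-crop)
    particles: list[ParticleRecord]
    complete: bool
    pface_region: _ShapelyPolygon  # frame around the scene, disjoint from the hull
    genotype: str
    age_months: int
    compartment: str
    animal_id: int = 0
    true_density: float = float("nan")  # generating density, particles/um^2
    meta: dict = field(default_factory=dict)

    @property
    def pface_area_um2(self) -> float:
        return float(self.pface_region.area) / NM2_PER_UM2

    def particles_xy(self, channel: str | None = None, face: str | None = None) -> np.ndarray:
        sel = [
            p
            for p in self.particles
            if (channel is None or p.channel == channel)
            and (face is None or p.face == face)
        ]
        if not sel:
            return np.zeros((0, 2))
        return np.array([[p.position.x, p.position.y] for p in sel])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def make_preset(genotype: str, age_months: int, compartment: str) -> GroupPreset:
    """Built-in preset for one genotype x age x compartment cell.

    The density mean is the published group mean; its CV is derived from
    the published SEM and n (CV = SEM * sqrt(n) / mean).  Spine PSD
    areas use the published mean 0.046 / SD 0.018 um^2; cells without a
    published area (all shafts, and the 12-month APP/PS1 spines whose
    PSDs are smaller) carry an area mean recalibrated so the simulated
    median particle count matches the published median.
    """
    key = (genotype, age_months, compartment)
    if key not in GROUP_TABLE:
        raise ConfigurationError(
            f"unknown design cell {key}; genotypes {GENOTYPES}, "
            f"ages {AGES_MONTHS}, compartments {COMPARTMENTS}"
        )
    row = GROUP_TABLE[key]
    cv = row["sem"] * math.sqrt(row["n"]) / row["mean"]
    area_mean = _CALIBRATED_AREA_MEAN_UM2.get(key, SPINE_AREA_MEAN_UM2)
    return GroupPreset(
        genotype=genotype,
        age_months=age_months,
        compartment=compartment,
        mean_density=row["mean"],
        density_cv=cv,
        area_mean=area_mean,
        area_sd=area_mean * AREA_CV,
        n_synapses_default=int(row["n"]),
        density_sem=row["sem"],
    )


def preset_by_name(name: str) -> GroupPreset:
    """Resolve names like ``wt_spine_12m`` or ``app_shaft_6m``."""
    try:
        geno_tok, comp_tok, age_tok = name.split("_")
        genotype = {"wt": "WT", "app": "APP_PS1"}[geno_tok]
        compartment = {"spine": "spine", "shaft": "interneuron_shaft"}[comp_tok]
        age = int(age_tok.rstrip("m"))
    except (ValueError, KeyError) as exc:
        raise ConfigurationError(f"unparseable preset name {name!r}") from exc
    return make_preset(genotype, age, compartment)


def all_presets() -> list[GroupPreset]:
    return [make_preset(*key) for key in GROUP_TABLE]


# ---------------------------------------------------------------------------
# Hull-area calibration
# ---------------------------------------------------------------------------

def _hull_area_of_uniform_disk(n: int, rng: np.random.Generator) -> float:
    """Area of the convex hull of n uniform points in the unit disk."""
    r = np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * np.pi
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    from scipy.spatial import ConvexHull

    return float(ConvexHull(pts).volume)


def hull_shrinkage(mean_imps: float, reps: int = 400, seed: int = 12345) -> float:
    """Expected (hull area / disk area) for Poisson(mean_imps) uniform points.

    The convex hull of finitely many uniform points undercovers the disk;
    this factor is estimated by Monte Carlo and used to inflate the
    generation disk so the hull hits the target area on average.
    """
    if mean_imps < 3:
        raise CalibrationError(
            f"expected IMP count {mean_imps:.2f} too small for a hull"
        )
    rng = np.random.default_rng(seed)
    tot = 0.0
    kept = 0
    for _ in range(reps):
        n = max(3, rng.poisson(mean_imps))
        tot += _hull_area_of_uniform_disk(n, rng)
        kept += 1
    return tot / kept / np.pi


def calibrate_hull_area(
    target_mean_area_um2: float,
    imp_density_per_um2: float = DEFAULT_IMP_DENSITY_PER_UM2,
    reps: int = 800,
    seed: int = 12345,
) -> float:
    """Disk radius (nm) such that the expected convex-hull area of
    Poisson(imp_density x disk area) uniform points equals the target.

    Solved by fixed-point iteration on the Monte-Carlo shrinkage factor.
    """
    if target_mean_area_um2 <= 0:
        raise CalibrationError("target area must be > 0")
    area_nm2 = target_mean_area_um2 * NM2_PER_UM2
    dens_nm2 = imp_density_per_um2 / NM2_PER_UM2
    disk_nm2 = area_nm2  # initial guess: no shrinkage
    s = 1.0
    for _ in range(6):
        m = dens_nm2 * disk_nm2
        if m < 3:
            raise CalibrationError(
                f"too few expected IMPs ({m:.2f}) for target "
                f"{target_mean_area_um2} um^2 at {imp_density_per_um2}/um^2"
            )
        s_new = hull_shrinkage(m, reps=reps, seed=seed)
        disk_nm2 = area_nm2 / s_new
        if abs(s_new - s) < 1e-3:
            s = s_new
            break
        s = s_new
    return math.sqrt(disk_nm2 / np.pi)


# cache of shrinkage factors keyed by rounded expected IMP count
_SHRINKAGE_CACHE: dict[int, float] = {}


def _cached_shrinkage(mean_imps: float) -> float:
    key = int(round(mean_imps))
    if key not in _SHRINKAGE_CACHE:
        _SHRINKAGE_CACHE[key] = hull_shrinkage(max(key, 4), reps=600)
    return _SHRINKAGE_CACHE[key]


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _uniform_in_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _uniform_in_hull(
    n: int, hull_xy: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a convex polygon by fan triangulation."""
    if n == 0:
        return np.zeros((0, 2))
    v = hull_xy
    a, b, c = v[0], v[1:-1], v[2:]
    tri_areas = 0.5 * np.abs(
        (b[:, 0] - a[0]) * (c[:, 1] - a[1]) - (c[:, 0] - a[0]) * (b[:, 1] - a[1])
    )
    probs = tri_areas / tri_areas.sum()
    idx = rng.choice(len(probs), size=n, p=probs)
    u = rng.random(n)
    w = rng.random(n)
    flip = u + w > 1
    u[flip] = 1 - u[flip]
    w[flip] = 1 - w[flip]
    return a + u[:, None] * (b[idx] - a) + w[:, None] * (c[idx] - a)


def _crop_by_chord(
    xy: np.ndarray, rng: np.random.Generator, keep_fraction_range=(0.5, 0.85)
):
    """Halfplane mask emulating a fracture cutting through the cluster."""
    th = rng.random() * 2.0 * np.pi
    normal = np.array([np.cos(th), np.sin(th)])
    proj = xy @ normal
    q = rng.uniform(*keep_fraction_range)
    cut = np.quantile(proj, q)
    return proj <= cut, normal, cut


def generate_scene(
    preset: GroupPreset,
    rng: np.random.Generator | int,
    scene_id: int = 0,
    animal_id: int = 0,
    pface_margin_nm: float = 250.0,
    force_complete: bool = False,
) -> SynapseScene:
    """Draw one synthetic fractured synapse from a preset.

    Steps: draw the PSD area (lognormal), place Poisson IMPs uniformly
    in a shrinkage-calibrated disk, demarcate their hull, draw the scene
    density (lognormal), scatter Poisson pan-AMPAR and GluN1 gold
    uniformly inside the hull, scatter Poisson background gold on the
    surrounding P-face frame, and optionally truncate by a random chord.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # (i) target hull area
    mu_a, sg_a = _lognormal_params(preset.area_mean, preset.area_sd / preset.area_mean)
    area_um2 = float(rng.lognormal(mu_a, sg_a))
    area_nm2 = area_um2 * NM2_PER_UM2

    # (ii) IMP placement in a disk inflated by the mean shrinkage at the
    # preset's typical IMP count (the factor varies slowly with count)
    mean_imps_at_mean = preset.imp_density * preset.area_mean
    s = _cached_shrinkage(mean_imps_at_mean)
    disk_area_nm2 = area_nm2 / s
    radius = math.sqrt(disk_area_nm2 / np.pi)
    n_imp = max(3, int(rng.poisson(preset.imp_density / NM2_PER_UM2 * disk_area_nm2)))
    imp_xy = _uniform_in_disk(n_imp, radius, rng)

    # (vii) decide completeness up front so the crop applies to everything
    complete = True
    if not force_complete and rng.random() < preset.incomplete_fraction:
        complete = False
        for _ in range(20):
            keep, normal, cut = _crop_by_chord(imp_xy, rng)
            if keep.sum() >= 3:
                imp_xy = imp_xy[keep]
                break
        else:  # pragma: no cover - pathological
            complete = True

    try:
        hull = convex_hull(imp_xy)
    except DegenerateGeometryError:  # pragma: no cover - prob ~ 0
        imp_xy = _uniform_in_disk(max(4, n_imp), radius, rng)
        hull = convex_hull(imp_xy)

    # (iii) scene density, (iv) pan-AMPAR gold uniform in the hull
    if preset.mean_density > 0:
        mu_d, sg_d = _lognormal_params(preset.mean_density, preset.density_cv) if preset.density_cv > 0 else (math.log(preset.mean_density), 0.0)
        density = float(rng.lognormal(mu_d, sg_d)) if sg_d > 0 else preset.mean_density
    else:
        density = 0.0
    hull_area_um2 = hull.area_nm2 / NM2_PER_UM2
    n_ampar = rng.poisson(density * hull_area_um2)
    ampar_xy = _uniform_in_hull(int(n_ampar), hull.xy, rng)

    # (v) GluN1 co-label
    n_glun1 = rng.poisson(preset.glun1_rate)
    glun1_xy = _uniform_in_hull(int(n_glun1), hull.xy, rng)

    # (vi) background on the P-face frame around the generation disk
    half = radius + pface_margin_nm
    outer = _ShapelyPolygon(
        [(-half, -half), (half, -half), (half, half), (-half, half)]
    )
    inner = _ShapelyPolygon(
        [
            (radius + 10.0) * np.array([np.cos(t), np.sin(t)])
            for t in np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ]
    )
    pface = outer.difference(inner)
    n_bg = rng.poisson(preset.background_rate * pface.area / NM2_PER_UM2)
    bg_xy = np.zeros((0, 2))
    if n_bg > 0:
        pts = []
        while len(pts) < n_bg:
            cand = rng.uniform(-half, half, size=(4 * n_bg, 2))
            dist = np.hypot(cand[:, 0], cand[:, 1])
            ok = dist > radius + 10.0
            pts.extend(cand[ok][: n_bg - len(pts)])
        bg_xy = np.asarray(pts)

    particles: list[ParticleRecord] = []
    for x, y in ampar_xy:
        particles.append(ParticleRecord(Point(float(x), float(y)), 10, "panAMPA", "E"))
    for x, y in glun1_xy:
        particles.append(ParticleRecord(Point(float(x), float(y)), 5, "GluN1", "E"))
    for x, y in bg_xy:
        particles.append(ParticleRecord(Point(float(x), float(y)), 10, "panAMPA", "P"))

    return SynapseScene(
        scene_id=scene_id,
        imp_points=imp_xy,
        true_polygon=hull,
        particles=particles,
        complete=complete,
        pface_region=pface,
        genotype=preset.genotype,
        age_months=preset.age_months,
        compartment=preset.compartment,
        animal_id=animal_id,
        true_density=density,
        meta={"preset": preset.name, "target_area_um2": area_um2},
    )


def generate_dataset(
    preset: GroupPreset,
    n: int,
    rng_seed: int | np.random.Generator,
    n_animals: int = 3,
    force_complete: bool = False,
    pface_margin_nm: float = 250.0,
) -> list[SynapseScene]:
    """n scenes with ids 0..n-1; animals assigned round-robin (default 3,
    the number of animals measured per group in the study)."""
    if n < 1:
        raise ValueError(f"need n >= 1 scenes, got {n}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return [
        generate_scene(
            preset,
            rng,
            scene_id=i,
            animal_id=i % n_animals,
            force_complete=force_complete,
            pface_margin_nm=pface_margin_nm,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Median-count calibration
# ---------------------------------------------------------------------------

def simulate_count_median(
    preset: GroupPreset, reps: int = 20000, seed: int = 999
) -> float:
    """Median pan-AMPAR count over simulated synapses (fast path: counts
    only, no geometry — Poisson around density x area)."""
    rng = np.random.default_rng(seed)
    mu_a, sg_a = _lognormal_params(preset.area_mean, preset.area_sd / preset.area_mean)
    mu_d, sg_d = _lognormal_params(preset.mean_density, preset.density_cv)
    areas = rng.lognormal(mu_a, sg_a, size=reps)
    dens = rng.lognormal(mu_d, sg_d, size=reps)
    counts = rng.poisson(dens * areas)
    return float(np.median(counts))


def calibrate_area_to_median(
    genotype: str,
    age_months: int,
    compartment: str,
    reps: int = 20000,
    seed: int = 999,
    tol: float = 0.25,
) -> float:
    """Area mean (um^2) at which the simulated median particle count
    matches the published median for the cell.

    Bisection on the area mean with the area CV held at the published
    spine relative spread.  Used once to freeze the shipped presets for
    cells without a published PSD area.
    """
    key = (genotype, age_months, compartment)
    row = GROUP_TABLE[key]
    target = row["count_median"]
    base = make_preset(genotype, age_months, compartment)

    def median_at(area_mean: float) -> float:
        p = replace(base, area_mean=area_mean, area_sd=area_mean * AREA_CV)
        return simulate_count_median(p, reps=reps, seed=seed)

    lo, hi = 0.002, 0.5
    if not (median_at(lo) <= target <= median_at(hi)):
        raise CalibrationError(f"median target {target} out of bracket for {key}")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = median_at(mid)
        if abs(m - target) <= tol:
            return mid
        if m < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Pre-embedding profiles
# ---------------------------------------------------------------------------

#: Published plasma-membrane fraction of GluA2/3 labeling (pre-embedding,
#: 12 months): overall, spines, dendritic shafts.
PREEMBED_MEMBRANE_FRACTION: dict[str, dict[str, float]] = {
    "WT": {"total": 0.61, "spine": 0.68, "shaft": 0.57},
    "APP_PS1": {"total": 0.28, "spine": 0.38, "shaft": 0.25},
}

#: Distance band (nm) within which a particle counts as membrane-associated.
DEFAULT_EPS_MEMBRANE_NM = 25.0


@dataclass
class PreEmbedProfile:
    """One pre-embedding cell profile: a closed membrane outline and the
    silver-enhanced gold particles inside it (nm)."""

    cell_id: int
    animal_id: int
    genotype: str
    compartment: str  # "spine" or "shaft"
    membrane: np.ndarray  # (n, 2) closed polyline vertices, nm
    particles: np.ndarray  # (m, 2) nm

    @property
    def membrane_polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.membrane)


def _blob_outline(
    rng: np.random.Generator, mean_radius: float, n_vertices: int = 48
) -> np.ndarray:
    """Smooth closed outline: an ellipse-ish blob with low-order radial noise."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, mean_radius, dtype=float)
    for k in (2, 3):
        amp = rng.uniform(0.0, 0.12) * mean_radius
        ph = rng.random() * 2 * np.pi
        r += amp * np.cos(k * t + ph)
    stretch = rng.uniform(1.0, 1.4)
    return np.column_stack([r * np.cos(t) * stretch, r * np.sin(t)])


def _sample_in_region(
    region, n: int, rng: np.random.Generator, max_iter: int = 200
) -> np.ndarray:
    """Rejection-sample n uniform points inside a shapely region."""
    import shapely as _sh

    minx, miny, maxx, maxy = region.bounds
    out: list[np.ndarray] = []
    for _ in range(max_iter):
        if len(out) >= n:
            break
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(4 * n, 64), 2))
        ok = _sh.contains_xy(region, cand[:, 0], cand[:, 1])
        out.extend(cand[ok][: n - len(out)])
    if len(out) < n:  # pragma: no cover - degenerate region
        raise CalibrationError("could not sample points in region")
    return np.asarray(out)


def generate_preembed_profiles(
    p_membrane: float,
    n_particles_per_cell: int = 25,
    n_cells: int = 40,
    n_animals: int = 3,
    rng_seed: int | np.random.Generator = 0,
    genotype: str = "WT",
    compartment: str = "shaft",
    eps_mem_nm: float = DEFAULT_EPS_MEMBRANE_NM,
) -> list[PreEmbedProfile]:
    """Synthetic pre-embedding profiles with a known membrane fraction.

    Each cell is a smooth closed dendrite/spine outline; each particle
    is placed with probability ``p_membrane`` uniformly in the band
    within ``eps_mem_nm`` of the membrane (inside the profile), else
    uniformly in the interior beyond the band.
    """
    if not (0.0 <= p_membrane <= 1.0):
        raise ValueError("p_membrane must be a proportion")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    mean_radius = 250.0 if compartment == "spine" else 450.0
    profiles: list[PreEmbedProfile] = []
    cell_id = 0
    for animal in range(n_animals):
        for _ in range(n_cells):
            outline = _blob_outline(rng, mean_radius)
            poly = _ShapelyPolygon(outline)
            core = poly.buffer(-eps_mem_nm)
            band = poly.difference(core)
            n_mem = int(rng.binomial(n_particles_per_cell, p_membrane))
            n_int = n_particles_per_cell - n_mem
            pts = []
            if n_mem:
                pts.append(_sample_in_region(band, n_mem, rng))
            if n_int:
                pts.append(_sample_in_region(core, n_int, rng))
            particles = (
                np.vstack(pts) if pts else np.zeros((0, 2))
            )
            profiles.append(
                PreEmbedProfile(
                    cell_id=cell_id,
                    animal_id=animal,
                    genotype=genotype,
                    compartment=compartment,
                    membrane=outline,
                    particles=particles,
                )
            )
            cell_id += 1
    return profiles


def generate_preembed_dataset(
    genotype: str,
    n_cells_per_animal: int = 40,
    n_particles_per_cell: int = 25,
    n_animals: int = 3,
    rng_seed: int | np.random.Generator = 0,
    eps_mem_nm: float = DEFAULT_EPS_MEMBRANE_NM,
) -> list[PreEmbedProfile]:
    """Genotype preset: spine and shaft cells at the published
    compartment-specific membrane fractions, mixed so that the pooled
    fraction matches the published overall value.
    """
    if genotype not in PREEMBED_MEMBRANE_FRACTION:
        raise ConfigurationError(f"unknown genotype {genotype!r}")
    fr = PREEMBED_MEMBRANE_FRACTION[genotype]
    # choose the spine share w so that w*p_spine + (1-w)*p_shaft = p_total
    w = (fr["total"] - fr["shaft"]) / (fr["spine"] - fr["shaft"])
    n_spine = int(round(w * n_cells_per_animal))
    n_shaft = n_cells_per_animal - n_spine
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    spine = generate_preembed_profiles(
        fr["spine"], n_particles_per_cell, n_spine, n_animals, rng,
        genotype=genotype, compartment="spine", eps_mem_nm=eps_mem_nm,
    )
    shaft = generate_preembed_profiles(
        fr["shaft"], n_particles_per_cell, n_shaft, n_animals, rng,
        genotype=genotype, compartment="shaft", eps_mem_nm=eps_mem_nm,
    )
    for i, p in enumerate(spine + shaft):
        p.cell_id = i
    return spine + shaft
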