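"""Per-synapse quantification of replica immunogold labeling.

Implements the measurement rules of the freeze-fracture workflow:

* the postsynaptic specialization is demarcated as the convex hull of
  its IMP cluster;
* a gold particle is synaptic if it lies inside the demarcated outline
  or within 30 nm of its edge (inclusive), the nominal antibody reach;
* an incomplete (fracture-truncated) specialization is analyzable only
  if it retains at least 30 IMPs;
* a cluster counts as a verified glutamatergic synapse only if
  co-labeled with more than two GluN1 particles (i.e. >= 3);
* density = pan-AMPAR count / demarcated area (um^2);
* non-specific background is estimated on the P-face and reported but
  not subtracted (it is ~0.5% of the synaptic signal).

Particle-to-cluster assignment is purely geometric: gold within the
dilated outline is counted regardless of its nominal fracture face,
because face attribution is ambiguous at the demarcation edge — this is
what lets background labeling leak into the rim, as on real replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import (
    DegenerateGeometryError,
    DilationRadius,
    Polygon,
    convex_hull,
    polygon_area,
    within_dilation_mask,
)
from .synthetic import ParticleRecord, SynapseScene

DEFAULT_RIM_NM = 30.0
DEFAULT_GLUN1_MIN = 3  # "more than two" co-label particles
DEFAULT_IMP_MIN = 30  # minimum IMPs for an incomplete specialization

STUDY_TABLE_COLUMNS = [
    "scene_id",
    "genotype",
    "age_months",
    "compartment",
    "animal_id",
    "complete",
    "included",
    "exclusion_reason",
    "imp_count",
    "n_glun1",
    "n_ampar",
    "area_um2",
    "density_per_um2",
]


@dataclass
class SynapseRecord:
    """One quantified synapse (one row of the study table)."""

    scene_id: int
    polygon: Polygon | None
    area: float  # um^2
    imp_count: int
    n_ampar: int
    n_glun1: int
    density: float  # particles/um^2
    complete: bool
    included: bool
    exclusion_reason: str | None
    genotype: str
    age_months: int
    compartment: str
    animal_id: int


@dataclass(frozen=True)
class BackgroundEstimate:
    """Pooled P-face background: rate = particles / area."""

    total_particles: int
    total_area: float  # um^2
    rate: float  # particles/um^2


@dataclass(frozen=True)
class PoolCheck:
    """Kruskal-Wallis pooling check across levels of a factor."""

    factor: str
    levels: tuple
    statistic: float
    p_value: float
    decision: Literal["pool", "do-not-pool", "inconclusive"]
    note: str = ""


def demarcate(imp_points: np.ndarray | Sequence) -> Polygon:
    """Convex-hull demarcation of an IMP point set (nm coordinates)."""
    return convex_hull(np.asarray(imp_points, dtype=float))


def assign_particles(
    particles: Iterable[ParticleRecord],
    poly: Polygon,
    d: DilationRadius | float = DEFAULT_RIM_NM,
) -> tuple[int, int]:
    """Count synaptic particles per channel under the inclusive rim rule.

    Returns ``(n_ampar, n_glun1)``: particles inside the demarcated
    outline or within ``d`` nm of its edge.  Particles farther out
    contribute to neither count.
    """
    plist = list(particles)
    if not plist:
        return 0, 0
    xy = np.array([[p.position.x, p.position.y] for p in plist])
    inside = within_dilation_mask(xy, poly, d)
    n_ampar = sum(1 for p, ok in zip(plist, inside) if ok and p.channel == "panAMPA")
    n_glun1 = sum(1 for p, ok in zip(plist, inside) if ok and p.channel == "GluN1")
    return n_ampar, n_glun1


def qc_synapse(
    record: SynapseRecord,
    glun1_min: int = DEFAULT_GLUN1_MIN,
    imp_min: int = DEFAULT_IMP_MIN,
    glun1_filter: bool = True,
) -> SynapseRecord:
    """Apply the inclusion rules and set ``included`` / ``exclusion_reason``.

    included = (complete OR imp_count >= imp_min) AND n_glun1 >= glun1_min.
    With ``glun1_filter=False`` the GluN1 rule only annotates the reason
    without excluding (the alternative reading of the co-label rule).
    """
    reasons = []
    if not record.complete and record.imp_count < imp_min:
        reasons.append(f"insufficient IMPs ({record.imp_count} < {imp_min})")
    if record.n_glun1 < glun1_min:
        reasons.append(
            f"insufficient GluN1 co-labeling ({record.n_glun1} < {glun1_min})"
        )
        if not glun1_filter:
            reasons[-1] += " [annotated only]"
    excluding = [
        r
        for r in reasons
        if glun1_filter or not r.endswith("[annotated only]")
    ]
    record.included = not excluding
    record.exclusion_reason = "; ".join(reasons) if reasons else None
    return record


def synapse_density(record: SynapseRecord) -> float:
    """Particles per um^2: pan-AMPAR count over demarcated area."""
    if record.area <= 0:
        raise ValueError(f"scene {record.scene_id}: non-positive area")
    return record.n_ampar / record.area


def quantify_scene(
    scene: SynapseScene,
    rim_nm: float = DEFAULT_RIM_NM,
    glun1_min: int = DEFAULT_GLUN1_MIN,
    imp_min: int = DEFAULT_IMP_MIN,
    glun1_filter: bool = True,
) -> SynapseRecord:
    """Demarcate, assign, and QC one scene."""
    imp_xy = np.asarray(scene.imp_points, dtype=float)
    # bundles persist the demarcated hull, not the raw IMP set; the true
    # IMP count then travels as metadata
    base = dict(
        scene_id=scene.scene_id,
        imp_count=int(scene.meta.get("imp_count", imp_xy.shape[0])),
        complete=scene.complete,
        genotype=scene.genotype,
        age_months=scene.age_months,
        compartment=scene.compartment,
        animal_id=scene.animal_id,
    )
    try:
        poly = demarcate(imp_xy)
    except DegenerateGeometryError:
        return SynapseRecord(
            polygon=None,
            area=float("nan"),
            n_ampar=0,
            n_glun1=0,
            density=float("nan"),
            included=False,
            exclusion_reason="degenerate demarcation",
            **base,
        )
    n_ampar, n_glun1 = assign_particles(scene.particles, poly, rim_nm)
    area = polygon_area(poly)
    rec = SynapseRecord(
        polygon=poly,
        area=area,
        n_ampar=n_ampar,
        n_glun1=n_glun1,
        density=n_ampar / area,
        included=True,
        exclusion_reason=None,
        **base,
    )
    return qc_synapse(rec, glun1_min=glun1_min, imp_min=imp_min, glun1_filter=glun1_filter)


def build_table(
    scenes: Iterable[SynapseScene],
    rim_nm: float = DEFAULT_RIM_NM,
    glun1_min: int = DEFAULT_GLUN1_MIN,
    imp_min: int = DEFAULT_IMP_MIN,
    glun1_filter: bool = True,
) -> pd.DataFrame:
    """Quantify every scene into the study table (one row per synapse).

    Excluded synapses are retained with their exclusion reason so the
    audit trail survives into downstream summaries.
    """
    rows = []
    for scene in scenes:
        r = quantify_scene(
            scene,
            rim_nm=rim_nm,
            glun1_min=glun1_min,
            imp_min=imp_min,
            glun1_filter=glun1_filter,
        )
        rows.append(
            {
                "scene_id": r.scene_id,
                "genotype": r.genotype,
                "age_months": r.age_months,
                "compartment": r.compartment,
                "animal_id": r.animal_id,
                "complete": r.complete,
                "included": r.included,
                "exclusion_reason": r.exclusion_reason,
                "imp_count": r.imp_count,
                "n_glun1": r.n_glun1,
                "n_ampar": r.n_ampar,
                "area_um2": r.area,
                "density_per_um2": r.density,
            }
        )
    if not rows:
        import warnings

        warnings.warn("no scenes to quantify; returning empty study table")
        return pd.DataFrame(columns=STUDY_TABLE_COLUMNS)
    return pd.DataFrame(rows, columns=STUDY_TABLE_COLUMNS)


def background_density(scenes: Iterable[SynapseScene]) -> BackgroundEstimate:
    """Pooled P-face background: total particles over total P-face area.

    Reported alongside, never subtracted from, the synaptic densities.
    """
    total_particles = 0
    total_area = 0.0
    for scene in scenes:
        if scene.pface_region is None or scene.pface_region.is_empty:
            continue
        area = scene.pface_area_um2
        total_area += area
        total_particles += sum(1 for p in scene.particles if p.face == "P")
    if total_area <= 0:
        raise ValueError("no P-face area available for background estimation")
    return BackgroundEstimate(
        total_particles=total_particles,
        total_area=total_area,
        rate=total_particles / total_area,
    )


def pool_check(
    table: pd.DataFrame,
    factor: Literal["completeness", "animal"],
    alpha: float = 0.05,
) -> PoolCheck:
    """Kruskal-Wallis test of per-synapse densities across factor levels.

    'pool' when p >= alpha: no evidence the levels differ, so they may
    be analyzed together (the workflow applied to complete/incomplete
    synapses and to animals).
    """
    col = {"completeness": "complete", "animal": "animal_id"}[factor]
    df = table[table["included"]]
    groups = [
        g["density_per_um2"].to_numpy()
        for _, g in df.groupby(col)
    ]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return PoolCheck(
            factor=factor,
            levels=tuple(sorted(df[col].unique())),
            statistic=float("nan"),
            p_value=float("nan"),
            decision="inconclusive",
            note="fewer than two levels with >= 2 observations",
        )
    if np.ptp(np.concatenate(groups)) == 0:
        # identical constant data: trivially poolable
        return PoolCheck(
            factor=factor,
            levels=tuple(sorted(df[col].unique())),
            statistic=0.0,
            p_value=1.0,
            decision="pool",
            note="constant densities",
        )
    stat, p = sps.kruskal(*groups)
    return PoolCheck(
        factor=factor,
        levels=tuple(sorted(df[col].unique())),
        statistic=float(stat),
        p_value=float(p),
        decision="pool" if p >= alpha else "do-not-pool",
    )
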