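"""Pre-embedding immunogold compartment analysis.

On thin sections labeled before embedding, each silver-enhanced gold
particle inside a digitized cell profile is assigned to the plasma
membrane pool if it lies within ``eps`` nm of the membrane outline
(default 25 nm, the nominal localization accuracy of silver-enhanced
1.4-nm gold), otherwise to the intracellular pool.  Group comparisons
use two-sample t-tests on animal-level percentages with a Holm-Sidak
correction across the compartment families (total / spines / shafts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry import LinearRing, Point as _ShapelyPoint

from .stats import holm_sidak
from .synthetic import DEFAULT_EPS_MEMBRANE_NM, PreEmbedProfile

Level = Literal["cell", "animal", "group"]


@dataclass(frozen=True)
class PartitionResult:
    """Membrane vs intracellular split at one grouping level."""

    level: str
    key: tuple
    n_membrane: int
    n_intracellular: int
    p_membrane: float  # percent
    p_intracellular: float  # percent


def membrane_distances(
    points: np.ndarray, membrane: np.ndarray
) -> np.ndarray:
    """Minimum distance (nm) from each point to the closed membrane polyline."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return np.zeros(0)
    ring = LinearRing(np.asarray(membrane, dtype=float))
    return shapely.distance(shapely.points(points), ring)


def assign_compartment(
    p: Sequence[float],
    membrane: np.ndarray,
    eps: float = DEFAULT_EPS_MEMBRANE_NM,
) -> str:
    """'membrane' iff the particle is within ``eps`` nm of the outline."""
    d = membrane_distances(np.asarray([p], dtype=float), membrane)[0]
    return "membrane" if d <= eps else "intracellular"


def _profile_counts(profile: PreEmbedProfile, eps: float) -> tuple[int, int]:
    d = membrane_distances(profile.particles, profile.membrane)
    n_mem = int(np.sum(d <= eps))
    return n_mem, int(len(d) - n_mem)


def partition(
    profiles: Iterable[PreEmbedProfile],
    level: Level = "group",
    eps: float = DEFAULT_EPS_MEMBRANE_NM,
) -> list[PartitionResult]:
    """Partition particle counts at the requested grouping level.

    * ``cell``: one result per profile (pooled particle counts);
    * ``animal``: per animal, percentage = mean over that animal's cells
      (each cell weighted equally, as in the published per-animal
      summaries); counts are pooled;
    * ``group``: per genotype, pooled counts over all cells.

    Profiles with zero particles are skipped with a warning.
    """
    rows = []
    skipped = 0
    for pr in profiles:
        if len(pr.particles) == 0:
            skipped += 1
            continue
        n_mem, n_int = _profile_counts(pr, eps)
        rows.append(
            dict(
                genotype=pr.genotype,
                animal_id=pr.animal_id,
                cell_id=pr.cell_id,
                compartment=pr.compartment,
                n_mem=n_mem,
                n_int=n_int,
            )
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} profile(s) with zero particles")
    if not rows:
        raise ValueError("no usable profiles")
    df = pd.DataFrame(rows)

    def pct(nm, ni):
        tot = nm + ni
        return 100.0 * nm / tot if tot else float("nan")

    results: list[PartitionResult] = []
    if level == "cell":
        for r in df.itertuples():
            results.append(
                PartitionResult(
                    "cell",
                    (r.genotype, r.animal_id, r.cell_id),
                    r.n_mem,
                    r.n_int,
                    pct(r.n_mem, r.n_int),
                    100.0 - pct(r.n_mem, r.n_int),
                )
            )
    elif level == "animal":
        for (geno, animal), g in df.groupby(["genotype", "animal_id"]):
            cell_pcts = 100.0 * g["n_mem"] / (g["n_mem"] + g["n_int"])
            p_mem = float(cell_pcts.mean())
            results.append(
                PartitionResult(
                    "animal",
                    (geno, animal),
                    int(g["n_mem"].sum()),
                    int(g["n_int"].sum()),
                    p_mem,
                    100.0 - p_mem,
                )
            )
    elif level == "group":
        for geno, g in df.groupby("genotype"):
            nm, ni = int(g["n_mem"].sum()), int(g["n_int"].sum())
            results.append(
                PartitionResult("group", (geno,), nm, ni, pct(nm, ni), 100.0 - pct(nm, ni))
            )
    else:
        raise ValueError(f"unknown level {level!r}")
    return results


def partition_table(
    profiles: Iterable[PreEmbedProfile],
    eps: float = DEFAULT_EPS_MEMBRANE_NM,
) -> pd.DataFrame:
    """Animal-level membrane percentages per compartment family
    (total / spine / shaft), the unit of the group comparison."""
    profiles = list(profiles)
    rows = []
    for family in ("total", "spine", "shaft"):
        subset = (
            profiles
            if family == "total"
            else [p for p in profiles if p.compartment == family]
        )
        if not subset:
            continue
        for res in partition(subset, level="animal", eps=eps):
            geno, animal = res.key
            rows.append(
                dict(
                    family=family,
                    genotype=geno,
                    animal_id=animal,
                    p_membrane=res.p_membrane,
                    p_intracellular=res.p_intracellular,
                    n_membrane=res.n_membrane,
                    n_intracellular=res.n_intracellular,
                )
            )
    return pd.DataFrame(rows)


def compare_partitions(table: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-tests of animal-level membrane percentages between the
    two genotypes, one test per compartment family, Holm-Sidak-adjusted
    across the families.

    ``table`` is the output of :func:`partition_table` with both
    genotypes present.  (Membrane and intracellular percentages are
    complementary, so one test per family carries the whole family.)
    """
    genos = sorted(table["genotype"].unique())
    if len(genos) != 2:
        raise ValueError(f"need exactly 2 genotypes, got {genos}")
    rows = []
    for family, g in table.groupby("family", sort=False):
        a = g[g["genotype"] == genos[0]]["p_membrane"].to_numpy()
        b = g[g["genotype"] == genos[1]]["p_membrane"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"family {family!r}: need >= 2 animals per group")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(
            dict(
                family=family,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                diff=float(a.mean() - b.mean()),
                t=float(t),
                p_raw=float(p),
            )
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())
    out.attrs["genotypes"] = tuple(genos)
    return out
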