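"""Group summaries and inferential statistics for the study table.

The analysis mirrors the published workflow: per-group summaries
(synapse n, median/range of particle counts, mean +/- SEM and
median/range of densities), two-way ANOVA of density on genotype x
compartment within one age with Bonferroni-adjusted pairwise genotype
contrasts, Pearson correlation of particle count with synaptic area,
and advisory assumption checks (Levene, Shapiro-Wilk).  Observations
enter at the synapse level, matching the pooling of animals after the
pooling check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

DESIGN_FACTORS = ("genotype", "compartment")


@dataclass(frozen=True)
class GroupSummary:
    """Table-1-style summary of one genotype x age x compartment cell."""

    genotype: str
    age_months: int
    compartment: str
    n: int
    count_median: float
    count_min: int
    count_max: int
    density_mean: float
    density_sem: float
    density_median: float
    density_min: float
    density_max: float


@dataclass
class AnovaReport:
    """Two-way ANOVA decomposition plus Bonferroni post-hoc contrasts."""

    table: pd.DataFrame  # effects x (sum_sq, df, F, PR(>F))
    ss_type: int
    posthoc: pd.DataFrame  # pairwise genotype contrasts within compartment
    age_months: int | None = None

    @property
    def p_genotype(self) -> float:
        return float(self.table.loc["C(genotype)", "PR(>F)"])

    @property
    def p_compartment(self) -> float:
        return float(self.table.loc["C(compartment)", "PR(>F)"])

    @property
    def p_interaction(self) -> float:
        return float(self.table.loc["C(genotype):C(compartment)", "PR(>F)"])


def _included(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["included"]] if "included" in table.columns else table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summaries over included synapses, in the layout of the
    published table: synapse n, median and range of particle counts,
    mean (+/-SEM), median and range of densities.

    Empty design cells are omitted (with a warning).
    """
    df = _included(table)
    rows = []
    for (geno, age, comp), g in df.groupby(
        ["genotype", "age_months", "compartment"], sort=True
    ):
        counts = g["n_ampar"].to_numpy()
        dens = g["density_per_um2"].to_numpy()
        n = len(g)
        rows.append(
            {
                "genotype": geno,
                "age_months": age,
                "compartment": comp,
                "n": n,
                "count_median": float(np.median(counts)),
                "count_min": int(counts.min()),
                "count_max": int(counts.max()),
                "density_mean": float(dens.mean()),
                "density_sem": float(dens.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "density_median": float(np.median(dens)),
                "density_min": float(dens.min()),
                "density_max": float(dens.max()),
            }
        )
    if len(rows) < df[["genotype", "age_months", "compartment"]].drop_duplicates().shape[0]:
        import warnings

        warnings.warn("some design cells were empty and omitted")
    return pd.DataFrame(rows)


def pearson_count_area(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) of particle count vs synaptic area."""
    df = _included(table)
    if len(df) < 3:
        raise ValueError("need at least 3 synapses for a correlation")
    x = df["n_ampar"].to_numpy(dtype=float)
    y = df["area_um2"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def two_way_anova(
    table: pd.DataFrame,
    response: str = "density_per_um2",
    factors: tuple[str, str] = DESIGN_FACTORS,
    age_months: int | None = None,
) -> AnovaReport:
    """Two-way ANOVA of density on genotype x compartment within one age.

    Type II sums of squares (the published cell sizes are unequal), with
    Bonferroni-adjusted pairwise genotype contrasts within each
    compartment as the post-hoc family.
    """
    df = _included(table)
    if age_months is not None:
        df = df[df["age_months"] == age_months]
    fa, fb = factors
    cells = df.groupby([fa, fb]).size()
    la, lb = df[fa].nunique(), df[fb].nunique()
    if la < 2 or lb < 2:
        raise ValueError(f"need >= 2 levels per factor, got {la} x {lb}")
    if len(cells) < la * lb or (cells < 2).any():
        missing = [
            c for c in
            [(a, b) for a in df[fa].unique() for b in df[fb].unique()]
            if c not in cells.index or cells.get(c, 0) < 2
        ]
        raise ValueError(f"empty or singleton design cells: {missing}")
    model = smf.ols(f"{response} ~ C({fa}) * C({fb})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={f"C({fa})": "C(genotype)", f"C({fb})": "C(compartment)",
                            f"C({fa}):C({fb})": "C(genotype):C(compartment)"})

    # Bonferroni post-hoc: genotype contrast within each compartment
    rows = []
    comps = sorted(df[fb].unique())
    genos = sorted(df[fa].unique())
    k = len(comps) * (len(genos) * (len(genos) - 1) // 2)
    for comp in comps:
        sub = df[df[fb] == comp]
        for i in range(len(genos)):
            for j in range(i + 1, len(genos)):
                a = sub[sub[fa] == genos[i]][response]
                b = sub[sub[fa] == genos[j]][response]
                t, p = sps.ttest_ind(a, b, equal_var=True)
                rows.append(
                    {
                        "compartment": comp,
                        "contrast": f"{genos[i]} vs {genos[j]}",
                        "mean_diff": float(a.mean() - b.mean()),
                        "t": float(t),
                        "p_raw": float(p),
                        "p_bonferroni": float(min(1.0, p * k)),
                    }
                )
    return AnovaReport(
        table=aov, ss_type=2, posthoc=pd.DataFrame(rows), age_months=age_months
    )


@dataclass(frozen=True)
class AssumptionReport:
    levene_stat: float
    levene_p: float
    shapiro: pd.DataFrame  # per-group W and p (NaN where skipped)
    notes: tuple[str, ...] = ()


def assumption_checks(groups: dict[str, np.ndarray]) -> AssumptionReport:
    """Levene homogeneity-of-variance across groups and Shapiro-Wilk
    normality per group.  Advisory only: the ANOVA is not gated on them.

    Groups with n < 3 skip Shapiro-Wilk with a note; constant groups are
    flagged as degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    notes: list[str] = []
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    lev_stat, lev_p = sps.levene(*arrays.values())
    rows = []
    for name, arr in arrays.items():
        if len(arr) < 3:
            rows.append({"group": name, "W": np.nan, "p": np.nan})
            notes.append(f"{name}: n < 3, Shapiro-Wilk skipped")
            continue
        if np.ptp(arr) == 0:
            rows.append({"group": name, "W": np.nan, "p": np.nan})
            notes.append(f"{name}: constant sample, normality undefined")
            continue
        w, p = sps.shapiro(arr)
        rows.append({"group": name, "W": float(w), "p": float(p)})
    return AssumptionReport(
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        shapiro=pd.DataFrame(rows),
        notes=tuple(notes),
    )


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Sidak (Holm-Sidak) multiplicity adjustment.

    Sort ascending; the i-th smallest (1-based) p becomes
    1 - (1 - p)**(m - i + 1); enforce monotone nondecreasing adjusted
    values; return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D list of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def bonferroni(p_values, k: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, k * p), k defaulting to len(p)."""
    p = np.asarray(p_values, dtype=float)
    k = p.size if k is None else k
    return np.minimum(1.0, p * k)
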