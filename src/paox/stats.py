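"""Cohort statistics for the longitudinal oximetry study.

The experimental unit is the animal: the five placental sO2 measurements of
an animal on a gestational day are averaged before inference.  The primary
analysis is a two-way repeated-measures (mixed) ANOVA with cohort (NP vs
RUPP) as the between-subject factor and gestational day as the
within-subject factor, followed by per-day group contrasts with Bonferroni
adjustment.  Helpers cover the companion analyses: paired within-group
gestational-day comparisons, Welch t-tests recomputed from printed
mean ± SEM summaries, and the a priori two-sample power calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "AnovaResult",
    "average_per_animal",
    "rm_anova",
    "pairwise_bonferroni",
    "t_from_summary",
    "power_two_sample",
    "P_FLOOR",
]

#: Smallest p-value ever reported, to avoid printing exact zeros.
P_FLOOR = 1e-300


def _floor_p(p: float) -> float:
    if not np.isfinite(p):
        return 1.0  # zero-variance / degenerate designs: no evidence either way
    return float(min(1.0, max(P_FLOOR, p)))


@dataclass(frozen=True)
class EffectTest:
    df1: int
    df2: int
    F: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-ANOVA effects plus per-gestational-day group contrasts.

    ``effects`` keys: ``group``, ``gd``, ``interaction``.  ``contrasts`` has
    one row per gestational day with the NP-vs-RUPP Welch t statistic and
    raw/Bonferroni-adjusted p-values.
    """

    effects: Mapping[str, EffectTest]
    contrasts: pd.DataFrame = field(repr=False)

    def contrast_p(self, gd: int, adjusted: bool = True) -> float:
        row = self.contrasts.loc[self.contrasts["gd"] == gd]
        if row.empty:
            raise KeyError(f"no contrast for gestational day {gd}")
        return float(row["p_adj" if adjusted else "p_raw"].iloc[0])


def average_per_animal(placenta_table: pd.DataFrame, value_col: str = "so2") -> pd.DataFrame:
    """Collapse placenta-level rows to animal-level means.

    Expects tidy columns ``group, animal, gd`` plus ``value_col`` (the
    per-placenta saturation).  Returns one row per (group, animal, gd) with
    ``mean_so2`` and the contributing placenta count ``n_placentas``.
    Cells absent from the input simply yield no row — nothing is imputed;
    use :func:`missing_cells` to list them.
    """
    required = {"group", "animal", "gd", value_col}
    missing = required - set(placenta_table.columns)
    if missing:
        raise ValidationError(f"cohort table missing column(s): {sorted(missing)}")
    if placenta_table.empty:
        raise InsufficientDataError("cohort table is empty")
    out = (
        placenta_table.groupby(["group", "animal", "gd"], as_index=False)[value_col]
        .agg(mean_so2="mean", n_placentas="count")
        .sort_values(["group", "animal", "gd"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def missing_cells(animal_table: pd.DataFrame) -> pd.DataFrame:
    """(animal, gd) combinations absent from an animal-level table."""
    animals = animal_table[["group", "animal"]].drop_duplicates()
    gds = animal_table["gd"].drop_duplicates()
    full = animals.merge(gds, how="cross")
    merged = full.merge(animal_table[["animal", "gd"]].assign(_seen=True),
                        on=["animal", "gd"], how="left")
    return merged[merged["_seen"].isna()][["group", "animal", "gd"]].reset_index(drop=True)


def rm_anova(animal_table: pd.DataFrame, value_col: str = "mean_so2") -> AnovaResult:
    """Two-way repeated-measures ANOVA (group between, gestational day within).

    Runs a mixed ANOVA with the animal as subject (Type-III-style sums of
    squares as computed by pingouin; no sphericity correction by default —
    with only three within levels the correction barely moves the group
    contrasts of interest).  Per-day NP-vs-RUPP contrasts use Welch t-tests
    with Bonferroni adjustment across the gestational days.

    Degenerate tables with zero residual variance report ``p = 1`` by
    convention (no evidence against the null is extractable).
    """
    required = {"group", "animal", "gd", value_col}
    if required - set(animal_table.columns):
        raise ValidationError(f"animal table needs columns {sorted(required)}")
    counts = animal_table.groupby("group")["animal"].nunique()
    if len(counts) < 2 or (counts < 2).any():
        raise InsufficientDataError("each group needs at least two animals")

    df = animal_table.rename(columns={value_col: "_y"})[["group", "animal", "gd", "_y"]]
    n_sub = df["animal"].nunique()
    n_gd = df["gd"].nunique()
    dfs = {"group": (1, n_sub - 2),
           "gd": (n_gd - 1, (n_gd - 1) * (n_sub - 2)),
           "interaction": (n_gd - 1, (n_gd - 1) * (n_sub - 2))}
    effects: dict[str, EffectTest] = {}
    if np.isclose(df["_y"].var(ddof=0), 0.0):
        # all observations identical: F is 0/0; report p = 1 by convention
        for key, (d1, d2) in dfs.items():
            effects[key] = EffectTest(df1=d1, df2=d2, F=0.0, p=1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            aov = pg.mixed_anova(data=df, dv="_y", within="gd", subject="animal",
                                 between="group", correction=False)
        for source, key in (("group", "group"), ("gd", "gd"),
                            ("Interaction", "interaction")):
            row = aov.loc[aov["Source"] == source].iloc[0]
            effects[key] = EffectTest(
                df1=int(row["DF1"]), df2=int(row["DF2"]),
                F=float(row["F"]) if np.isfinite(row["F"]) else 0.0,
                p=_floor_p(row["p_unc"]),
            )

    groups = sorted(df["group"].unique())
    gds = sorted(df["gd"].unique())
    rows = []
    for gd in gds:
        a = df.loc[(df["gd"] == gd) & (df["group"] == groups[0]), "_y"].to_numpy()
        b = df.loc[(df["gd"] == gd) & (df["group"] == groups[1]), "_y"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = sps.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(p):  # zero variance in both samples
            t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, P_FLOOR)
        rows.append({
            "gd": gd,
            "mean_" + groups[0]: a.mean(),
            "mean_" + groups[1]: b.mean(),
            "t": float(t),
            "p_raw": _floor_p(p),
            "p_adj": _floor_p(min(1.0, p * len(gds))),
        })
    return AnovaResult(effects=effects, contrasts=pd.DataFrame(rows))


def pairwise_bonferroni(
    animal_table: pd.DataFrame, value_col: str = "mean_so2"
) -> pd.DataFrame:
    """Paired t-tests between gestational-day pairs within each group.

    Animals are matched across days; the Bonferroni multiplier is the number
    of day pairs.  Identical paired samples report p = 1; nonzero constant
    differences (zero variance) hit the documented p floor.
    """
    gds = sorted(animal_table["gd"].unique())
    if len(gds) < 2:
        raise InsufficientDataError("need at least two gestational days")
    n_pairs = len(gds) * (len(gds) - 1) // 2
    rows = []
    for group, sub in animal_table.groupby("group"):
        wide = sub.pivot(index="animal", columns="gd", values=value_col)
        for g1, g2 in combinations(gds, 2):
            pair = wide[[g1, g2]].dropna()
            if len(pair) < 2:
                raise InsufficientDataError(
                    f"fewer than 2 paired observations for {group} GD{g1}-GD{g2}"
                )
            d = pair[g1].to_numpy() - pair[g2].to_numpy()
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            elif np.isclose(d.std(ddof=1), 0.0):
                t, p = np.sign(d.mean()) * np.inf, P_FLOOR
            else:
                t, p = sps.ttest_rel(pair[g1], pair[g2])
            rows.append({
                "group": group, "gd_a": g1, "gd_b": g2, "n": len(pair),
                "t": float(t), "p_raw": _floor_p(p),
                "p_adj": _floor_p(min(1.0, p * n_pairs)),
            })
    return pd.DataFrame(rows)


def t_from_summary(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
) -> tuple[float, float, float]:
    """Welch t-test recomputed from printed mean ± SEM summaries.

    Returns ``(t, df, p)`` with ``t = (mean1 - mean2) / sqrt(sem1^2 + sem2^2)``,
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.  Welch is
    chosen because printed SEMs often differ markedly between groups.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValidationError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    v1, v2 = sem1**2, sem2**2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), _floor_p(p)


def power_two_sample(
    effect_size_d: float, n_per_group: int, alpha: float = 0.05, sides: int = 2
) -> float:
    """Power of a two-sample t-test at Cohen's d, equal group sizes.

    Exact noncentral-t computation: noncentrality ``d * sqrt(n/2)``,
    ``2n - 2`` degrees of freedom.  ``sides`` selects a one- or two-sided
    rejection region.
    """
    if effect_size_d <= 0:
        raise ValidationError("effect size must be positive")
    if n_per_group < 2:
        raise ValidationError("need n >= 2 per group")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if sides not in (1, 2):
        raise ValidationError("sides must be 1 or 2")
    df = 2 * n_per_group - 2
    ncp = effect_size_d * np.sqrt(n_per_group / 2.0)
    if sides == 1:
        crit = sps.t.isf(alpha, df)
        return float(sps.nct.sf(crit, df, ncp))
    crit = sps.t.isf(alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))
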