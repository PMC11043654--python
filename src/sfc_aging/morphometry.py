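"""Normative z-standardization of grey-matter measures and region-set statistics.

Regional measures of middle-aged and elderly subjects are expressed in young
standard-deviation units: Z = (x_OC - mu_YC) / sigma_YC, where mu_YC and
sigma_YC are the mean and (n-1) standard deviation of the region in the young
group.  Thickness and volume tables are analyzed separately and never pooled
(subcortical regions only have volumes; cortical regions have thickness).

Region-set effects (MCR vs LCR vs rest) are assessed with a one-way ANOVA
whose observation unit is the region (its mean Z across the group's
subjects), followed by pairwise contrasts on the pooled within-set variance
with Bonferroni adjustment.  A subject-level variant (unit="subject": each
subject's mean Z over the set's regions) is available behind a switch.

Spatial-similarity analyses correlate, across regions, young-group regional
SFC (step-1 strength, or the combined-map step index) with the group's
per-region mean Z, using Pearson's r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import RegionSets
from .io import RegionalTable

__all__ = [
    "NormativeStats",
    "StandardizedTable",
    "AnovaResult",
    "CorrelationResult",
    "normative_stats",
    "standardize",
    "regionset_anova",
    "sfc_gm_correlation",
]


@dataclass
class NormativeStats:
    """Per-region young-group mean and SD for one measure kind."""

    mu: pd.Series
    sd: pd.Series
    measure_kind: str
    n_young: int

    @property
    def regions(self) -> list[str]:
        return list(self.mu.index)


@dataclass
class StandardizedTable:
    """Subject x region z-scores of middle/elderly subjects against young norms."""

    z: pd.DataFrame
    groups: pd.Series
    measure_kind: str

    @property
    def regions(self) -> list[str]:
        return list(self.z.columns)

    def group_mean(self, group: str) -> pd.Series:
        """Per-region mean Z across the group's subjects."""
        sel = self.groups == group
        if not sel.any():
            raise ValueError(f"no subjects of group {group!r} in standardized table")
        return self.z.loc[sel.values].mean(axis=0)


def normative_stats(young_table: RegionalTable) -> NormativeStats:
    """Per-region sample mean and SD (denominator n-1) of the young group.

    Zero-SD regions cannot be standardized and are excluded with a warning.
    """
    if any(s.group != "young" for s in young_table.subjects):
        raise ValueError("normative stats must be computed on the young group only")
    n = len(young_table.subjects)
    if n < 2:
        raise ValueError(f"need at least 2 young subjects, got {n}")
    mu = young_table.values.mean(axis=0)
    sd = young_table.values.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        warnings.warn(f"excluding zero-variance region(s) from normative stats: {zero}", stacklevel=2)
        mu = mu.drop(zero)
        sd = sd.drop(zero)
    return NormativeStats(mu, sd, young_table.measure_kind, n)


def standardize(table: RegionalTable, norms: NormativeStats) -> StandardizedTable:
    """Z = (x_OC - mu_YC) / sigma_YC element-wise for middle/elderly subjects."""
    if table.measure_kind != norms.measure_kind:
        raise ValueError(
            f"measure kind mismatch: table {table.measure_kind!r} vs norms {norms.measure_kind!r}"
        )
    missing = [r for r in table.regions if r not in norms.mu.index]
    if missing:
        raise ValueError(f"region(s) missing from normative stats: {missing}")
    regions = [r for r in table.regions if r in norms.mu.index]
    x = table.values[regions]
    z = (x - norms.mu[regions]) / norms.sd[regions]
    groups = table.group_labels
    return StandardizedTable(z, groups, table.measure_kind)


@dataclass
class AnovaResult:
    """One-way ANOVA over region sets plus Bonferroni-adjusted pairwise contrasts."""

    F: float
    df_between: int
    df_within: int
    p: float
    set_means: dict[str, float]
    set_sizes: dict[str, int]
    posthoc: pd.DataFrame  # columns: a, b, diff, t, p_adj
    unit: str
    group: str

    def posthoc_p(self, a: str, b: str) -> float:
        for _, row in self.posthoc.iterrows():
            if {row["a"], row["b"]} == {a, b}:
                return float(row["p_adj"])
        raise KeyError(f"no post hoc contrast between {a!r} and {b!r}")


def regionset_anova(
    ztable: StandardizedTable,
    sets: RegionSets,
    group: str,
    unit: str = "region",
) -> AnovaResult:
    """One-way ANOVA of standardized GM across the MCR / LCR / rest partition.

    unit="region": each region contributes its mean Z over the group's
    subjects (the factor is the set the region belongs to).  unit="subject":
    each subject contributes its mean Z over the set's regions.  Pairwise
    contrasts use the pooled within-group mean square with Bonferroni
    adjustment over the three comparisons.
    """
    if group not in ("middle", "elderly"):
        raise ValueError(f"region-set ANOVA applies to middle or elderly, got {group!r}")
    if unit not in ("region", "subject"):
        raise ValueError(f"unknown observation unit {unit!r}")
    regions = ztable.regions
    membership = {name: [r for r in getattr(sets, attr) if r in regions]
                  for name, attr in (("MCR", "mcr"), ("LCR", "lcr"), ("rest", "rest"))}
    samples: dict[str, np.ndarray] = {}
    if unit == "region":
        gmean = ztable.group_mean(group)
        for name, regs in membership.items():
            samples[name] = gmean[regs].to_numpy()
    else:
        sel = (ztable.groups == group).values
        for name, regs in membership.items():
            samples[name] = ztable.z.loc[sel, regs].mean(axis=1).to_numpy() if regs else np.array([])
    for name, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"set {name!r} has fewer than 2 observations; no variance estimate")
    names = list(samples)
    arrays = [samples[n] for n in names]
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    N = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_within = N - k
    msw = ss_within / df_within
    rows = []
    n_comp = len(list(combinations(names, 2)))
    for a, b in combinations(names, 2):
        xa, xb = samples[a], samples[b]
        diff = xa.mean() - xb.mean()
        se = np.sqrt(msw * (1 / len(xa) + 1 / len(xb)))
        tstat = diff / se
        p_raw = 2 * stats.t.sf(abs(tstat), df_within)
        rows.append({"a": a, "b": b, "diff": diff, "t": tstat, "p_adj": min(1.0, p_raw * n_comp)})
    return AnovaResult(
        F=float(F),
        df_between=k - 1,
        df_within=df_within,
        p=float(p),
        set_means={n: float(samples[n].mean()) for n in names},
        set_sizes={n: len(samples[n]) for n in names},
        posthoc=pd.DataFrame(rows),
        unit=unit,
        group=group,
    )


@dataclass
class CorrelationResult:
    """Pearson correlation across regions between an SFC predictor and mean Z."""

    r: float
    p: float
    n: int
    predictor: str
    measure_kind: str
    group: str


def sfc_gm_correlation(
    regional_sfc: pd.Series,
    ztable: StandardizedTable,
    predictor: str,
    group: str,
) -> CorrelationResult:
    """Pearson r across regions: young regional SFC vs the group's mean Z.

    ``predictor`` names what ``regional_sfc`` holds: "step1_strength"
    (young-group regional step-1 SFC, the strength of direct connectivity) or
    "combined_step_index" (young-group mean combined-map step).  Regions are
    aligned by name, complete cases only; dropped regions are logged.
    """
    if predictor not in ("combined_step_index", "step1_strength"):
        raise ValueError(f"unknown predictor {predictor!r}")
    gmean = ztable.group_mean(group)
    shared = [r for r in regional_sfc.index if r in gmean.index]
    dropped = sorted(set(regional_sfc.index) ^ set(gmean.index))
    if dropped:
        warnings.warn(f"dropping unmatched region(s) from correlation: {dropped[:10]}", stacklevel=2)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared regions, got {len(shared)}")
    x = regional_sfc[shared].to_numpy(dtype=float)
    y = gmean[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in predictor or target")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(shared), predictor, ztable.measure_kind, group)
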