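"""Startle-induced negative geotaxis (SING) scoring and group statistics.

In the SING assay, groups of 10 flies are tapped to the bottom of a
vertical tube; 10 s later the number of flies above a 2 cm mark is
counted, the trial repeated 15 times per tube, and the per-tube average
taken as one observation.  The experimental unit is the tube average
(typically 10 tubes per sex per genotype), not the individual fly.

The decision tree for comparing an experimental genotype against its
two genetic controls:

* every group passes an Anderson-Darling normality test at alpha = 0.05
  AND the variance ratio max/min stays below Hartley's f-max critical
  value  ->  one-way ANOVA; if the omnibus is significant, pairwise
  Tukey-Kramer;
* otherwise  ->  Kruskal-Wallis; if significant, pairwise Mann-Whitney
  U at the Dunn-Sidak-adjusted level alpha' = 1 - (1 - alpha)^(1/k).

A genotype counts as affected only under the dual-control rule: the
experimental group differs from BOTH controls while the controls do not
differ from each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
#: supported Anderson-Darling significance levels (percent), per scipy
_AD_LEVELS = (15.0, 10.0, 5.0, 2.5, 1.0)


@dataclass
class SingTrialBlock:
    """Per-trial climbing counts for one tube of one genotype/sex."""

    genotype: str
    sex: str
    counts: Sequence[int]
    group_size: int = 10
    n_trials: int = 15

    def __post_init__(self) -> None:
        if len(self.counts) != self.n_trials:
            raise ValueError(
                f"{self.genotype}: got {len(self.counts)} trials, n_trials={self.n_trials}"
            )
        for c in self.counts:
            if not (0 <= c <= self.group_size):
                raise ValueError(
                    f"{self.genotype}: count {c} outside [0, {self.group_size}]"
                )


def sing_score(block: SingTrialBlock, expected_trials: int = 15) -> float:
    """Per-tube performance: arithmetic mean of the per-trial counts.

    A trial count other than ``expected_trials`` draws a warning, not an
    error (truncated sessions occur in practice).
    """
    if block.n_trials != expected_trials:
        warnings.warn(
            f"{block.genotype}: {block.n_trials} trials, expected {expected_trials}",
            stacklevel=2,
        )
    return float(np.mean(block.counts))


def anderson_darling_normal(x: Sequence[float], alpha: float = DEFAULT_ALPHA) -> bool:
    """True iff the Anderson-Darling test does NOT reject normality at alpha."""
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError(f"Anderson-Darling needs n >= 5 (got {len(x)})")
    level = alpha * 100.0
    if level not in _AD_LEVELS:
        raise ValueError(f"alpha {alpha} unsupported; choose from {[l/100 for l in _AD_LEVELS]}")
    with warnings.catch_warnings():
        # scipy >= 1.17 warns about the future removal of critical_values;
        # the tabulated critical-value route is exactly what this gate needs
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    idx = list(res.significance_level).index(level)
    return bool(res.statistic < res.critical_values[idx])


def normality_gate(
    groups: Sequence[Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> tuple[bool, list[bool]]:
    """Overall normality verdict and the per-group verdicts.

    Overall is true iff every group passes Anderson-Darling at alpha.
    """
    per_group = [anderson_darling_normal(g, alpha) for g in groups]
    return all(per_group), per_group


@lru_cache(maxsize=256)
def hartley_fmax_critical(k: int, df: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Critical value of Hartley's f-max (max/min of k sample variances).

    Computed as the (1 - alpha) quantile of max/min over k independent
    chi-square(df)/df variates, by a large fixed-seed simulation
    (deterministic).  Supported for 2 <= k <= 10 and 2 <= df <= 60,
    the range of the classical tables.
    """
    if not (2 <= k <= 10):
        raise ValueError(f"k={k} outside supported range 2..10")
    if not (2 <= df <= 60):
        raise ValueError(f"df={df} outside supported range 2..60")
    rng = np.random.default_rng(987_654_321)
    n_sim = 200_000
    v = rng.chisquare(df, size=(n_sim, k)) / df
    ratio = v.max(axis=1) / v.min(axis=1)
    return float(np.quantile(ratio, 1.0 - alpha))


def variance_gate(
    groups: Sequence[Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> tuple[bool, float]:
    """Hartley's f-max homogeneity gate; returns (verdict, fmax).

    A zero-variance group makes the ratio undefined: the gate returns
    False with a warning.  Group sizes should be equal or nearly so;
    the smallest group's df is used (conservative side of the table).
    """
    variances = [float(np.var(g, ddof=1)) for g in groups]
    if min(variances) == 0.0:
        warnings.warn("zero-variance group: f-max undefined, gate fails", stacklevel=2)
        return False, float("inf")
    fmax = max(variances) / min(variances)
    df = min(len(g) for g in groups) - 1
    k = len(groups)
    try:
        crit = hartley_fmax_critical(k, df, alpha)
    except ValueError:
        warnings.warn(
            f"Hartley critical value unavailable for k={k}, df={df}; gate fails "
            "(nonparametric branch will be used)", stacklevel=2,
        )
        return False, fmax
    return fmax <= crit, fmax


def dunn_sidak_alpha(alpha: float, k: int) -> float:
    """Sidak-adjusted per-comparison level: 1 - (1 - alpha)^(1/k)."""
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


@dataclass
class GroupComparison:
    """Outcome of the three-group decision tree."""

    branch_taken: str  # "anova_tukey" | "kw_mwu"
    omnibus_p: float
    pairwise_p: dict[str, float] = field(default_factory=dict)
    pairwise_significant: dict[str, bool] = field(default_factory=dict)
    normal: bool = True
    variance_ok: bool = True

    PAIRS = ("exp_vs_control_uas", "exp_vs_control_gal4", "control_uas_vs_control_gal4")


def decision_tree(
    experimental: Sequence[float],
    control_uas: Sequence[float],
    control_gal4: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """The full normality/variance-gated three-group comparison.

    Parametric branch: one-way ANOVA, then Tukey-Kramer pairwise (valid
    for unequal group sizes).  Nonparametric branch: Kruskal-Wallis,
    then pairwise Mann-Whitney U at the Dunn-Sidak-adjusted level.
    When the omnibus test is not significant, all pairwise comparisons
    are marked non-significant and no post hoc test is run.
    """
    groups = [np.asarray(g, dtype=float) for g in (experimental, control_uas, control_gal4)]
    normal, _per = normality_gate(groups, alpha)
    var_ok = False
    if normal:
        var_ok, _fmax = variance_gate(groups, alpha)
    comp = GroupComparison(
        branch_taken="anova_tukey" if (normal and var_ok) else "kw_mwu",
        omnibus_p=np.nan, normal=normal, variance_ok=var_ok,
    )
    pair_idx = [(0, 1), (0, 2), (1, 2)]
    if comp.branch_taken == "anova_tukey":
        comp.omnibus_p = float(stats.f_oneway(*groups).pvalue)
        if comp.omnibus_p < alpha:
            # Tukey-Kramer: studentized-range p-values, valid for unequal n
            res = stats.tukey_hsd(*groups)
            for key, (i, j) in zip(GroupComparison.PAIRS, pair_idx):
                p = float(res.pvalue[i, j])
                comp.pairwise_p[key] = p
                comp.pairwise_significant[key] = p < alpha
        else:
            for key in GroupComparison.PAIRS:
                comp.pairwise_p[key] = np.nan
                comp.pairwise_significant[key] = False
    else:
        comp.omnibus_p = float(stats.kruskal(*groups).pvalue)
        if comp.omnibus_p < alpha:
            adj = dunn_sidak_alpha(alpha, len(pair_idx))
            for key, (i, j) in zip(GroupComparison.PAIRS, pair_idx):
                p = float(stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided").pvalue)
                comp.pairwise_p[key] = p
                comp.pairwise_significant[key] = p < adj
        else:
            for key in GroupComparison.PAIRS:
                comp.pairwise_p[key] = np.nan
                comp.pairwise_significant[key] = False
    return comp


def dual_control_rule(comparison: GroupComparison) -> bool:
    """Affected iff exp differs from both controls and controls agree."""
    sig = comparison.pairwise_significant
    return (
        sig["exp_vs_control_uas"]
        and sig["exp_vs_control_gal4"]
        and not sig["control_uas_vs_control_gal4"]
    )


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read per-trial counts: genotype, sex, tube_id, trial_index, count_above_mark."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "sex", "tube_id", "trial_index", "count_above_mark"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def tube_averages(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-trial counts to per-tube SING scores."""
    out = (
        df.groupby(["genotype", "sex", "tube_id"], as_index=False)["count_above_mark"]
        .mean()
        .rename(columns={"count_above_mark": "sing_score"})
    )
    return out


def analyse_genotype(
    df: pd.DataFrame,
    experimental: str,
    control_uas: str,
    control_gal4: str,
    sex: Optional[str] = None,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Decision tree + dual-control verdict for one genotype triplet.

    With ``sex`` None the sexes are pooled; the report helper runs both
    pooled and per-sex analyses.
    """
    tubes = tube_averages(df)
    if sex is not None:
        tubes = tubes[tubes["sex"] == sex]
    def grab(genotype: str) -> np.ndarray:
        vals = tubes.loc[tubes["genotype"] == genotype, "sing_score"].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no tubes for genotype {genotype!r}" + (f" sex {sex!r}" if sex else ""))
        return vals

    comp = decision_tree(grab(experimental), grab(control_uas), grab(control_gal4), alpha)
    return {
        "experimental": experimental,
        "sex": sex or "pooled",
        "branch": comp.branch_taken,
        "omnibus_p": comp.omnibus_p,
        **{f"p_{k}": v for k, v in comp.pairwise_p.items()},
        "significant": dual_control_rule(comp),
    }
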