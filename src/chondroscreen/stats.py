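"""Plate-level QC, hit calling, dose-response summaries and hypothesis tests.

The replication unit throughout is the *well*: cells within a well are
pseudo-replicates, so every test runs on per-well aggregates.  Hit calling
codifies the screen's control-referenced logic: a compound x concentration is
a morphology hit when it differs significantly from the basal (negative)
control on both area and roundness, is *not* distinguishable from the
chondrogenic (positive) control on either, and carries a mean cell area above
the large-cell flag threshold.  The "indistinguishable from chondro" arm is
absence of evidence at alpha, not formal equivalence; an optional TOST arm is
available when an equivalence margin is justified.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphology import LARGE_CELL_AREA_UM2
from .migration import MIGRATION_COUNT_THRESHOLD

__all__ = [
    "dilution_factor",
    "coefficient_of_variation",
    "QCReport",
    "qc_gate",
    "AnovaTukeyResult",
    "anova_tukey",
    "unpaired_t",
    "tost_equivalence",
    "call_morphology_hits",
    "dose_response_summary",
    "CV_GATE_PERCENT",
    "DEFAULT_ALPHA",
]

CV_GATE_PERCENT = 20.0
DEFAULT_ALPHA = 0.05


def dilution_factor(
    predilution: float = 50.0,
    aliquot_ul: float = 10.0,
    diluent_ul: float = 190.0,
) -> float:
    """Overall dilution of a compound dosed into culture.

    The screen pre-dilutes stocks 50x in basal medium, then transfers 10 µL
    into 190 µL of culture (a further 20x), i.e. a 1000x overall dilution.
    """
    if predilution <= 0 or aliquot_ul <= 0 or diluent_ul < 0:
        raise ValueError("volumes and predilution factor must be positive")
    return predilution * (aliquot_ul + diluent_ul) / aliquot_ul


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV% = sample SD (n-1 denominator) / mean x 100."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    mean = x.mean()
    if math.isclose(mean, 0.0, abs_tol=1e-300):
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean * 100.0)


@dataclass
class QCReport:
    """Per-entry CV gate results: entry passes iff CV% < threshold (strict)."""

    cv_percent: dict[str, float]
    threshold_percent: float = CV_GATE_PERCENT
    passes: dict[str, bool] = field(init=False)
    overall_pass: bool = field(init=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cv_percent.values()):
            raise ValueError("CV values must be non-negative")
        self.passes = {k: v < self.threshold_percent for k, v in self.cv_percent.items()}
        self.overall_pass = all(self.passes.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry": list(self.cv_percent),
                "cv_percent": list(self.cv_percent.values()),
                "threshold_percent": self.threshold_percent,
                "pass": list(self.passes.values()),
            }
        )


def qc_gate(cv_percent: Mapping[str, float], threshold: float = CV_GATE_PERCENT) -> QCReport:
    """Apply the reproducibility gate (CV < threshold, strict) to a set of
    (condition, parameter) CV entries.  An empty report passes vacuously,
    with a warning."""
    if not cv_percent:
        warnings.warn("qc_gate called with no entries; passing vacuously")
    return QCReport(cv_percent=dict(cv_percent), threshold_percent=threshold)


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA omnibus result plus Tukey-HSD adjusted pairwise p-values
    (symmetric matrix with unit diagonal, indexed by group name)."""

    f_statistic: float
    p_value: float
    pairwise_p: pd.DataFrame
    group_means: dict[str, float]
    degenerate: bool = False

    def p_between(self, a: str, b: str) -> float:
        return float(self.pairwise_p.loc[a, b])


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's HSD over named groups.

    Requires >= 2 groups with >= 2 observations each.  A fully degenerate
    design (no between- and no within-group variance) is reported as F = 0
    with all pairwise p = 1 and ``degenerate=True``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("anova_tukey needs at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {n!r} has fewer than two observations")
    means = {n: float(a.mean()) for n, a in zip(names, arrays)}
    grand = np.concatenate(arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)

    k = len(names)
    unit = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    if ss_between <= 1e-300:
        # no separation between groups at all
        return AnovaTukeyResult(
            f_statistic=0.0, p_value=1.0, pairwise_p=unit, group_means=means,
            degenerate=ss_within <= 1e-300,
        )
    if ss_within <= 1e-300:
        # perfect separation: zero within-group variance
        pw = unit.copy()
        for a, b in itertools.combinations(names, 2):
            p = 1.0 if math.isclose(means[a], means[b]) else 0.0
            pw.loc[a, b] = pw.loc[b, a] = p
        return AnovaTukeyResult(
            f_statistic=float("inf"), p_value=0.0, pairwise_p=pw,
            group_means=means, degenerate=True,
        )

    f_stat, p_val = sps.f_oneway(*arrays)
    res = sps.tukey_hsd(*arrays)
    pw = pd.DataFrame(res.pvalue, index=names, columns=names)
    np.fill_diagonal(pw.values, 1.0)
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p_val), pairwise_p=pw, group_means=means
    )


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample unpaired Student's t-test (pooled variance, two-sided)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if math.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def tost_equivalence(
    a: Sequence[float], b: Sequence[float], margin: float
) -> float:
    """Two one-sided tests for equivalence of means within +/- margin.

    Returns the TOST p-value (max of the two one-sided p's); small p supports
    equivalence.  Off by default in hit calling — use only with a justified
    margin.
    """
    if margin <= 0:
        raise ValueError("equivalence margin must be positive")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least two observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    if se == 0:
        return 0.0 if abs(x.mean() - y.mean()) < margin else 1.0
    df = nx + ny - 2
    diff = x.mean() - y.mean()
    p_lower = sps.t.sf((diff + margin) / se, df)
    p_upper = sps.t.cdf((diff - margin) / se, df)
    return float(max(p_lower, p_upper))


def _condition_groups(
    summaries: pd.DataFrame, parameter: str, log_scale: bool = False
) -> dict[str, np.ndarray]:
    groups: dict[str, np.ndarray] = {}
    for cond, sub in summaries.groupby("condition", sort=False):
        vals = sub[parameter].to_numpy(dtype=float)
        if log_scale:
            if np.any(vals <= 0):
                raise ValueError(f"{parameter} must be positive for log-scale analysis")
            vals = np.log(vals)
        groups[str(cond)] = vals
    return groups


def call_morphology_hits(
    summaries: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    area_flag_um2: float = LARGE_CELL_AREA_UM2,
    migration_threshold: int = MIGRATION_COUNT_THRESHOLD,
    equivalence_margin: float | None = None,
    log_area: bool = True,
) -> pd.DataFrame:
    """Control-referenced hit calling over a plate of per-well aggregates.

    ``summaries`` needs one row per well with columns ``condition``, ``role``,
    ``compound_id``, ``concentration_nM``, ``mean_area_um2``,
    ``mean_roundness`` and (optionally) ``migration_count``.  One ANOVA +
    Tukey family per parameter spans all conditions on the plate, so the
    pairwise p-values are adjusted over every comparison drawn.  Cell areas
    are compared on the log scale by default (``log_area``): well-to-well
    variation in area is multiplicative, and pooling a single ANOVA variance
    across small basal and large chondrogenic cells is only tenable after the
    log transform.  Reported group means stay in µm².

    morphology_hit = differs from basal on area AND roundness (p < alpha)
    AND not distinguishable from chondro on either (p >= alpha; or TOST
    equivalence at ``equivalence_margin`` when given) AND mean area >
    ``area_flag_um2``.  migration_hit = mean well migration count strictly
    above ``migration_threshold``.
    """
    required = {"condition", "role", "mean_area_um2", "mean_roundness"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    n_neg = int((summaries["role"] == "negative").sum())
    n_pos = int((summaries["role"] == "positive").sum())
    if n_neg < 2 or n_pos < 2:
        raise ValueError(
            f"hit calling needs >= 2 negative and >= 2 positive control wells "
            f"(got {n_neg}, {n_pos})"
        )

    results = {}
    for param in ("mean_area_um2", "mean_roundness"):
        results[param] = anova_tukey(
            _condition_groups(summaries, param, log_scale=log_area and param == "mean_area_um2")
        )

    has_migration = "migration_count" in summaries.columns
    rows = []
    compound_rows = summaries[summaries["role"] == "compound"]
    for (comp, conc), sub in compound_rows.groupby(["compound_id", "concentration_nM"], sort=False):
        cond = str(sub["condition"].iloc[0])
        row: dict = {
            "compound_id": comp,
            "concentration_nM": float(conc),
            "n_wells": len(sub),
            "mean_area_um2": float(sub["mean_area_um2"].mean()),
            "mean_roundness": float(sub["mean_roundness"].mean()),
        }
        arms_basal, arms_chondro = [], []
        for param, short in (("mean_area_um2", "area"), ("mean_roundness", "roundness")):
            res = results[param]
            p_neg = res.p_between(cond, "negative")
            p_pos = res.p_between(cond, "positive")
            row[f"p_{short}_vs_basal"] = p_neg
            row[f"p_{short}_vs_chondro"] = p_pos
            arms_basal.append(p_neg < alpha)
            if equivalence_margin is not None:
                p_eq = tost_equivalence(
                    sub[param], summaries.loc[summaries["role"] == "positive", param],
                    margin=equivalence_margin,
                )
                row[f"p_{short}_equiv_chondro"] = p_eq
                arms_chondro.append(p_eq < alpha)
            else:
                arms_chondro.append(p_pos >= alpha)
        row["morphology_hit"] = bool(
            all(arms_basal) and all(arms_chondro) and row["mean_area_um2"] > area_flag_um2
        )
        if has_migration:
            mig = float(sub["migration_count"].mean())
            row["migration_count"] = mig
            row["migration_hit"] = bool(mig > migration_threshold)
        rows.append(row)
    return pd.DataFrame(rows)


def dose_response_summary(
    summaries: pd.DataFrame,
    concentrations_nM: Sequence[float] = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
    parameters: Sequence[str] = ("mean_area_um2", "mean_roundness"),
    alpha: float = DEFAULT_ALPHA,
    log_area: bool = True,
) -> pd.DataFrame:
    """Per-concentration dose-response table for one compound.

    For each concentration present: mean +/- SD of each parameter over its
    replicate wells, plus Tukey-adjusted comparisons against the basal and
    chondrogenic controls (one family per parameter across all concentration
    levels and both controls).  Rows are sorted by ascending concentration.
    Missing design concentrations are summarized as available, with a
    warning; with fewer than two groups of compound wells no omnibus test is
    run and p-values are NaN.
    """
    comp = summaries[summaries["role"] == "compound"]
    if comp.empty:
        raise ValueError("no compound wells in summaries")
    compounds = comp["compound_id"].unique()
    if len(compounds) != 1:
        raise ValueError(f"dose_response_summary expects one compound (got {list(compounds)})")
    present = sorted(comp["concentration_nM"].unique())
    missing = sorted(set(map(float, concentrations_nM)) - set(map(float, present)))
    if missing:
        warnings.warn(f"concentration levels missing from the plate: {missing}")

    # replicate check
    counts = comp.groupby("concentration_nM").size()
    low = counts[counts < 2]
    if not low.empty:
        warnings.warn(f"concentrations with < 2 replicate wells: {list(low.index)}")

    testable = len(present) >= 1 and all(counts[c] >= 2 for c in present)
    results = {}
    if testable:
        for param in parameters:
            groups = _condition_groups(
                summaries, param, log_scale=log_area and param == "mean_area_um2"
            )
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) >= 2:
                results[param] = anova_tukey(groups)

    rows = []
    for conc in present:
        sub = comp[comp["concentration_nM"] == conc]
        cond = str(sub["condition"].iloc[0])
        row = {"concentration_nM": float(conc), "n_wells": len(sub)}
        for param in parameters:
            short = param.replace("mean_", "").replace("_um2", "")
            row[f"{short}_mean"] = float(sub[param].mean())
            row[f"{short}_sd"] = float(sub[param].std(ddof=1)) if len(sub) > 1 else float("nan")
            res = results.get(param)
            if res is not None and cond in res.pairwise_p.index and "negative" in res.pairwise_p.index:
                row[f"p_{short}_vs_basal"] = res.p_between(cond, "negative")
                row[f"p_{short}_vs_chondro"] = (
                    res.p_between(cond, "positive") if "positive" in res.pairwise_p.index else float("nan")
                )
                row[f"sig_{short}_vs_basal"] = bool(row[f"p_{short}_vs_basal"] < alpha)
            else:
                row[f"p_{short}_vs_basal"] = float("nan")
                row[f"p_{short}_vs_chondro"] = float("nan")
                row[f"sig_{short}_vs_basal"] = False
        rows.append(row)
    return pd.DataFrame(rows).sort_values("concentration_nM", ignore_index=True)
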