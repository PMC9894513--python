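"""Cohort-level statistics of arch measurements and matching percentages.

Works on a long-format table with one value per (subject, group, timepoint,
variable, side).  The analysis mirrors the standard workflow for
longitudinal two-group orthodontic data: Shapiro-Wilk and Levene gates,
paired t for within-group T0-T1 change, unpaired t for between-group and
side-to-side comparisons, ICC(2,1) for intra-examiner reliability, and the
three report tables (bilateral widths, emi-lateral side differences,
matching percentage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

log = logging.getLogger("palatosym")

__all__ = [
    "EmptySelectionError",
    "StatResult",
    "ICCResult",
    "Summary",
    "MeanDifference",
    "summarize",
    "mean_difference",
    "paired_t",
    "unpaired_t",
    "shapiro_wilk",
    "levene",
    "icc_reliability",
    "check_printed_consistency",
    "build_report_tables",
    "ReportBundle",
    "validate_cohort",
]

COHORT_COLUMNS = ("subject_id", "group", "timepoint", "variable", "side", "value")


class EmptySelectionError(ValueError):
    """A cohort selection matched no (or too few) rows."""


@dataclass
class StatResult:
    """Outcome of a single hypothesis test."""

    test_name: str
    statistic: float
    df: float
    p_value: float
    mean_1: float | None = None
    sd_1: float | None = None
    n_1: int | None = None
    mean_2: float | None = None
    sd_2: float | None = None
    n_2: int | None = None
    mean_diff: float | None = None
    alpha: float = 0.05
    notes: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name, "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "significant": self.significant,
            "notes": list(self.notes),
        }


@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    form: str = "ICC(2,1)"
    degenerate: bool = False


@dataclass
class Summary:
    mean: float
    sd: float
    n: int


@dataclass
class MeanDifference:
    """Per-subject paired differences and their summary."""

    diffs: pd.Series
    mean: float
    sd: float
    excluded_subjects: list


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format contract: required columns, one value per cell."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    keys = ["subject_id", "timepoint", "variable", "side"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        raise ValueError(
            f"duplicate cohort cells for keys {table.loc[dup, keys].values[:5].tolist()}"
        )
    return table


def _select(table: pd.DataFrame, group: str, timepoint: str, variable: str,
            side: str) -> pd.DataFrame:
    m = (
        (table["group"] == group)
        & (table["timepoint"] == timepoint)
        & (table["variable"] == variable)
        & (table["side"] == side)
    )
    return table.loc[m]


def summarize(table: pd.DataFrame, group: str, timepoint: str, variable: str,
              side: str = "bilateral") -> Summary:
    """Sample mean / SD (n-1 denominator) / n of one cohort cell."""
    sel = _select(table, group, timepoint, variable, side)
    if len(sel) < 2:
        raise EmptySelectionError(
            f"selection ({group}, {timepoint}, {variable}, {side}) has {len(sel)} row(s); need >= 2"
        )
    v = sel["value"].to_numpy(float)
    return Summary(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=len(v))


def mean_difference(
    table: pd.DataFrame,
    group: str,
    variable: str,
    axis: str = "timepoint",
    timepoint: str | None = None,
    side: str = "bilateral",
) -> MeanDifference:
    """Per-subject paired differences: T1-T0 over timepoints or nCBS-CBS over sides.

    Subjects missing either member of the pair are excluded from the paired
    statistic and listed in ``excluded_subjects``.  On complete data the mean
    of the per-subject differences equals the difference of the cell means.
    """
    if axis == "timepoint":
        a = _select(table, group, "T1", variable, side).set_index("subject_id")["value"]
        b = _select(table, group, "T0", variable, side).set_index("subject_id")["value"]
    elif axis == "side":
        if timepoint is None:
            raise ValueError("side-axis differences need an explicit timepoint")
        a = _select(table, group, timepoint, variable, "nCBS").set_index("subject_id")["value"]
        b = _select(table, group, timepoint, variable, "CBS").set_index("subject_id")["value"]
    else:
        raise ValueError("axis must be 'timepoint' or 'side'")
    common = a.index.intersection(b.index)
    excluded = sorted(set(a.index).symmetric_difference(b.index))
    if len(common) == 0:
        raise EmptySelectionError(f"no paired subjects for ({group}, {variable}, {axis})")
    if excluded:
        log.warning("mean_difference(%s, %s, %s): excluded unpaired subjects %s",
                    group, variable, axis, excluded)
    diffs = (a.loc[common] - b.loc[common]).astype(float)
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else float("nan")
    return MeanDifference(diffs=diffs, mean=float(diffs.mean()), sd=sd,
                          excluded_subjects=excluded)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def paired_t(diffs, alpha: float = 0.05) -> StatResult:
    """Paired Student's t on per-subject differences (two-sided).

    Degenerate edges: zero-variance differences give t = 0, p = 1 when the
    mean is also zero, and an infinite-t flag (p -> 0) otherwise.
    """
    d = np.asarray(getattr(diffs, "diffs", diffs), float)
    d = d if d.ndim else d.reshape(1)
    n = len(d)
    if n < 2:
        raise EmptySelectionError("paired t needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    res = StatResult(test_name="paired_t", statistic=0.0, df=n - 1, p_value=1.0,
                     mean_1=mean, sd_1=sd, n_1=n, mean_diff=mean, alpha=alpha)
    if sd == 0.0:
        if mean == 0.0:
            res.notes.append("zero variance, zero mean: t defined as 0, p = 1")
        else:
            res.statistic = float(np.inf) if mean > 0 else float(-np.inf)
            res.p_value = 0.0
            res.notes.append("degenerate: zero variance with nonzero mean diff")
        return res
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    res.statistic = float(t)
    res.p_value = float(p)
    return res


def levene(sample_1, sample_2, alpha: float = 0.05) -> StatResult:
    """Levene's test for equality of variances (center = mean, classic form)."""
    x = np.asarray(sample_1, float)
    y = np.asarray(sample_2, float)
    res = StatResult(test_name="levene", statistic=float("nan"), df=float("nan"),
                     p_value=float("nan"), n_1=len(x), n_2=len(y), alpha=alpha)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        res.notes.append("not computable: both samples constant")
        res.p_value = 1.0
        return res
    w, p = stats.levene(x, y, center="mean")
    res.statistic, res.p_value = float(w), float(p)
    res.df = float(len(x) + len(y) - 2)
    return res


def unpaired_t(sample_1, sample_2, alpha: float = 0.05,
               levene_gate: bool = True) -> StatResult:
    """Unpaired Student's t (pooled variance), two-sided.

    When the Levene gate rejects equality of variances at ``alpha``, the
    Welch correction is applied instead — logged in ``notes``, never silent.
    """
    x = np.asarray(sample_1, float)
    y = np.asarray(sample_2, float)
    if len(x) < 2 or len(y) < 2:
        raise EmptySelectionError("unpaired t needs n >= 2 per sample")
    res = StatResult(
        test_name="unpaired_t", statistic=0.0, df=len(x) + len(y) - 2, p_value=1.0,
        mean_1=float(x.mean()), sd_1=float(x.std(ddof=1)), n_1=len(x),
        mean_2=float(y.mean()), sd_2=float(y.std(ddof=1)), n_2=len(y),
        mean_diff=float(x.mean() - y.mean()), alpha=alpha,
    )
    if res.sd_1 == 0.0 and res.sd_2 == 0.0:
        if res.mean_diff == 0.0:
            res.notes.append("zero variance, equal means: t defined as 0, p = 1")
        else:
            res.statistic = float(np.inf) if res.mean_diff > 0 else float(-np.inf)
            res.p_value = 0.0
            res.notes.append("degenerate: zero variance with unequal means")
        return res
    equal_var = True
    if levene_gate:
        lev = levene(x, y, alpha=alpha)
        if np.isfinite(lev.p_value) and lev.p_value < alpha:
            equal_var = False
            res.notes.append(
                f"Levene rejected equal variances (p={lev.p_value:.4g}); Welch correction applied"
            )
            log.info("unpaired_t: %s", res.notes[-1])
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    res.statistic, res.p_value = float(t), float(p)
    if not equal_var:  # Welch-Satterthwaite df
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        res.df = float((vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)))
    return res


def shapiro_wilk(sample, alpha: float = 0.05) -> StatResult:
    """Shapiro-Wilk normality test; gates the parametric workflow."""
    x = np.asarray(sample, float)
    res = StatResult(test_name="shapiro_wilk", statistic=float("nan"), df=float(len(x)),
                     p_value=float("nan"), n_1=len(x), alpha=alpha)
    if len(x) < 3:
        raise EmptySelectionError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        res.notes.append("not computable: constant sample")
        return res
    w, p = stats.shapiro(x)
    res.statistic, res.p_value = float(w), float(p)
    return res


def icc_reliability(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Intra-class correlation ICC(2,1): two-way random effects, absolute
    agreement, single measures — the standard reliability index for repeated
    digital-model measurements.

    ``ratings`` is (n_subjects, k_raters_or_sessions).  CI is the standard
    F-based interval.  A matrix with no between-subject variance is flagged
    degenerate.
    """
    m = np.asarray(ratings, float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects, >=2 raters/sessions)")
    if m.shape[0] < 5:
        raise ValueError("need at least 5 subjects for a meaningful ICC")
    if np.ptp(m) == 0:
        return ICCResult(value=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), degenerate=True)
    n, k = m.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": m.ravel(),
    })
    icc = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                             ratings="score")
    typed = icc.set_index("Type")
    # absolute-agreement single-measures row; label differs across versions
    label = "ICC(A,1)" if "ICC(A,1)" in typed.index else "ICC2"
    row = typed.loc[label]
    ci_col = "CI95%" if "CI95%" in typed.columns else "CI95"
    ci_low, ci_high = (float(c) for c in row[ci_col])
    return ICCResult(value=float(row["ICC"]), ci_low=ci_low, ci_high=ci_high)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def check_printed_consistency(summary: dict, diffs: dict,
                              tol: float = 0.005) -> list[dict]:
    """Flag difference cells inconsistent with their own summary means.

    For each reported difference (T1-T0 change or nCBS-CBS side gap),
    recompute it from the corresponding summary means and flag the cell when
    the two disagree beyond printing precision (``tol`` = half a unit in the
    last printed digit).  Side gaps are compared in magnitude, since reported
    gaps are positive magnitudes per side.  Returns one record per flagged
    cell; nothing fails.
    """
    flags = []
    for key, (stated, _sd) in diffs.items():
        group, variable, which = key
        spec = summary.get((group, variable))
        if spec is None:
            continue
        if which == "T1-T0":
            if isinstance(spec["T0"], dict):
                continue
            computed = spec["T1"][0] - spec["T0"][0]
        else:  # side gap at a timepoint
            cell = spec[which]
            computed = cell["nCBS"][0] - cell["CBS"][0]
        # reported columns print magnitudes; compare magnitude to magnitude
        delta = abs(abs(computed) - abs(stated))
        if delta > tol + 1e-12:
            flags.append({
                "group": group, "variable": variable, "cell": which,
                "stated": stated, "computed_from_means": round(computed, 10),
            })
            log.warning("printed summary inconsistency: %s %s %s stated %.4g vs %.4g",
                        group, variable, which, stated, computed)
    return flags


@dataclass
class ReportBundle:
    """The three cohort report tables plus the analysis log."""

    bilateral: pd.DataFrame      # ICW/IMW by group x timepoint, T1-T0, between-group test
    emilateral: pd.DataFrame     # eICW/eIMW CBS vs nCBS with the three test families
    matching: pd.DataFrame       # matching % with T1-T0 and between-group test
    log: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        import json
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.bilateral.to_csv(out / "table2.csv", index=False)
        self.emilateral.to_csv(out / "table3.csv", index=False)
        self.matching.to_csv(out / "table4.csv", index=False)
        (out / "analysis_log.json").write_text(json.dumps(self.log, indent=2, default=str))


def _values(table, group, timepoint, variable, side):
    sel = _select(table, group, timepoint, variable, side)
    if sel.empty:
        raise EmptySelectionError(f"empty cohort group selection ({group}, {timepoint}, "
                                  f"{variable}, {side})")
    return sel["value"].to_numpy(float)


def build_report_tables(table: pd.DataFrame, alpha: float = 0.05,
                        printed_reference: tuple[dict, dict] | None = None) -> ReportBundle:
    """Assemble the three cohort report tables.

    * bilateral: per group, ICW/IMW means at T0/T1, per-subject T1-T0 change
      with its paired t, and the unpaired between-group test on the change.
    * emilateral: per group/timepoint, CBS and nCBS means, the per-subject
      side gap with side-to-side (unpaired), inter-timing (paired on gaps)
      and between-group (unpaired on gaps) tests.
    * matching: matching % at T0/T1 per group with paired T1-T0 and the
      between-group test on the change.

    Normality (Shapiro-Wilk) and variance (Levene) gate outcomes are logged
    in the bundle; with ``printed_reference`` = (summary, diffs) the bundle
    also carries consistency flags for reported differences that disagree
    with their own means.
    """
    validate_cohort(table)
    gates: dict = {}
    analysis_log: dict = {"alpha": alpha, "gates": gates}

    variables = set(zip(table["group"], table["variable"]))
    for group in ("TG", "CG"):
        if not (table["group"] == group).any():
            raise EmptySelectionError(f"cohort has no rows for group {group!r}")

    def gate(name, values):
        try:
            sw = shapiro_wilk(values, alpha=alpha)
            gates[name] = {"shapiro_p": sw.p_value, "normal": not sw.significant
                           if np.isfinite(sw.p_value) else None}
        except EmptySelectionError:
            gates[name] = {"shapiro_p": None, "normal": None}

    bilateral_rows = []
    for variable in ("ICW", "IMW"):
        if not any(v == variable for _, v in variables):
            continue
        changes = {}
        for group in ("TG", "CG"):
            s0 = summarize(table, group, "T0", variable)
            s1 = summarize(table, group, "T1", variable)
            gate(f"{group}/{variable}/T0", _values(table, group, "T0", variable, "bilateral"))
            md = mean_difference(table, group, variable, axis="timepoint")
            pt = paired_t(md, alpha=alpha)
            changes[group] = md
            bilateral_rows.append({
                "group": group, "variable": variable,
                "mean_T0": s0.mean, "sd_T0": s0.sd,
                "mean_T1": s1.mean, "sd_T1": s1.sd, "n": s0.n,
                "mean_T1_T0": md.mean, "sd_T1_T0": md.sd,
                "p_inter_timing": pt.p_value,
            })
        ut = unpaired_t(changes["TG"].diffs, changes["CG"].diffs, alpha=alpha)
        for row in bilateral_rows[-2:]:
            row["p_inter_group"] = ut.p_value

    emi_rows = []
    for variable in ("eICW", "eIMW"):
        if not any(v == variable for _, v in variables):
            continue
        for group in ("TG", "CG"):
            gap_by_tp = {}
            for tp in ("T0", "T1"):
                s_cbs = summarize(table, group, tp, variable, side="CBS")
                s_ncbs = summarize(table, group, tp, variable, side="nCBS")
                md = mean_difference(table, group, variable, axis="side", timepoint=tp)
                gap_by_tp[tp] = md
                side_t = unpaired_t(
                    _values(table, group, tp, variable, "nCBS"),
                    _values(table, group, tp, variable, "CBS"),
                    alpha=alpha,
                )
                emi_rows.append({
                    "group": group, "variable": variable, "timepoint": tp,
                    "mean_CBS": s_cbs.mean, "sd_CBS": s_cbs.sd,
                    "mean_nCBS": s_ncbs.mean, "sd_nCBS": s_ncbs.sd, "n": s_cbs.n,
                    "mean_side_gap": md.mean, "sd_side_gap": md.sd,
                    "p_side_to_side": side_t.p_value,
                })
            inter_timing = paired_t(gap_by_tp["T1"].diffs - gap_by_tp["T0"].diffs,
                                    alpha=alpha)
            for row in emi_rows[-2:]:
                row["p_inter_timing_gap"] = inter_timing.p_value
        tg_gap_change = (mean_difference(table, "TG", variable, axis="side", timepoint="T1").diffs
                         - mean_difference(table, "TG", variable, axis="side", timepoint="T0").diffs)
        cg_gap_change = (mean_difference(table, "CG", variable, axis="side", timepoint="T1").diffs
                         - mean_difference(table, "CG", variable, axis="side", timepoint="T0").diffs)
        ug = unpaired_t(tg_gap_change, cg_gap_change, alpha=alpha)
        for row in emi_rows[-4:]:
            row["p_inter_group_gap"] = ug.p_value

    match_rows = []
    if any(v == "matching_pct" for _, v in variables):
        changes = {}
        for group in ("TG", "CG"):
            s0 = summarize(table, group, "T0", "matching_pct")
            s1 = summarize(table, group, "T1", "matching_pct")
            md = mean_difference(table, group, "matching_pct", axis="timepoint")
            pt = paired_t(md, alpha=alpha)
            changes[group] = md
            match_rows.append({
                "group": group,
                "mean_T0": s0.mean, "sd_T0": s0.sd,
                "mean_T1": s1.mean, "sd_T1": s1.sd, "n": s0.n,
                "mean_T1_T0": md.mean, "sd_T1_T0": md.sd,
                "p_inter_timing": pt.p_value,
            })
        ut = unpaired_t(changes["TG"].diffs, changes["CG"].diffs, alpha=alpha)
        for row in match_rows:
            row["p_inter_group"] = ut.p_value

    if printed_reference is not None:
        analysis_log["printed_inconsistencies"] = check_printed_consistency(
            printed_reference[0], printed_reference[1]
        )

    return ReportBundle(
        bilateral=pd.DataFrame(bilateral_rows),
        emilateral=pd.DataFrame(emi_rows),
        matching=pd.DataFrame(match_rows),
        log=analysis_log,
    )
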