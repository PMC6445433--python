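"""Eye selection, quality gating and the case-control statistical battery.

The analysis compares a pooled cognitively impaired arm (amnestic MCI plus
early AD) against 1:1 matched cognitively normal controls:

* per-participant eye selection (right eye unless it fails the device quality
  gates or shows pathology, then the left; otherwise excluded),
* normality-gated two-sample tests (Shapiro–Wilk at α = 0.05 per group →
  Student's t for parametric, Mann–Whitney U for nonparametric data),
* Hedges' g standardized mean differences with the small-sample correction
  J = 1 − 3/(4N − 9),
* normality-gated Pearson/Spearman correlations of each vascular metric with
  the MoCA cognitive score over the entire cohort,
* two-way single-measure intraclass correlations, absolute-agreement ICC(A,1)
  and consistency ICC(C,1), for inter-grader reliability,
* assembly of the demographic, vascular-metric and correlation summary tables.

No multiple-testing correction is applied; α = 0.05 throughout.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_roi import ParticipantRecord
from .vessel_metrics import MIN_SQ, MIN_SSI

logger = logging.getLogger(__name__)

ALPHA_NORMALITY = 0.05

#: Table-2-style vascular metric rows: (column, label)
TABLE2_VARIABLES = [
    ("scp_vd", "Parafoveal SCP VD (%)"),
    ("scp_vld", "Parafoveal SCP VLD (%)"),
    ("scp_afi", "Parafoveal SCP AFI"),
    ("rpc_vd_global", "Peripapillary RPC VD global (%)"),
    ("rpc_vd_superior", "Peripapillary RPC VD superior (%)"),
    ("rpc_vd_capillary", "Peripapillary RPC capillary VD (%)"),
    ("rpc_vld", "Peripapillary RPC VLD (%)"),
    ("svc_vd", "Peripapillary SVC VD (%)"),
    ("svc_vld", "Peripapillary SVC VLD (%)"),
]

#: the seven vascular parameters correlated with MoCA (Table-3-style)
TABLE3_VARIABLES = [
    ("scp_vd", "Parafoveal SCP VD"),
    ("scp_vld", "Parafoveal SCP VLD"),
    ("scp_afi", "Parafoveal SCP AFI"),
    ("rpc_vd_global", "Peripapillary RPC VD"),
    ("rpc_vld", "Peripapillary RPC VLD"),
    ("svc_vd", "Peripapillary SVC VD"),
    ("svc_vld", "Peripapillary SVC VLD"),
]

TABLE_S1_VARIABLES = [
    ("wr_vd", "Parafoveal whole-retina VD (%)"),
    ("dcp_vd", "Parafoveal DCP VD (%)"),
    ("faz_area_mm2", "FAZ area (mm^2)"),
    ("rnfl_um", "RNFL thickness (um)"),
]

TABLE1_VARIABLES = [
    ("age", "Age (years)"),
    ("education_years", "Education (years)"),
    ("iop_mmhg", "IOP (mmHg)"),
    ("interval_years", "Cognitive-imaging interval (years)"),
    ("moca", "MoCA (total = 30)"),
    ("cdr", "CDR"),
    ("craft_imm", "Craft Story Immediate (total = 25)"),
    ("craft_del", "Craft Story Delayed (total = 25)"),
    ("ravlt_del", "RAVLT Delayed (total = 15)"),
]


@dataclass
class GroupComparisonResult:
    variable: str
    n_impaired: int
    n_control: int
    mean_impaired: float
    sd_impaired: float
    min_impaired: float
    max_impaired: float
    mean_control: float
    sd_control: float
    min_control: float
    max_control: float
    test_used: str  # {student_t, mann_whitney}
    p_value: float
    hedges_g: float
    cohen_d: float
    shapiro_p_impaired: float = np.nan
    shapiro_p_control: float = np.nan


@dataclass
class CorrelationResult:
    x: str
    y: str
    method: str  # {pearson, spearman}
    r: float
    p: float
    n: int


@dataclass
class ICCResult:
    mode: str  # {absolute_agreement, consistency}
    value: float
    n_subjects: int
    k_raters: int


# ---------------------------------------------------------------------------
# Eye selection
# ---------------------------------------------------------------------------


def _eye_passes(rec: ParticipantRecord, min_sq: int, min_ssi: dict) -> bool:
    if rec.pathology:
        return False
    checks = [
        (rec.sq_macula, min_sq),
        (rec.sq_disc, min_sq),
        (rec.ssi_macula, min_ssi["macula"]),
        (rec.ssi_disc, min_ssi["disc"]),
    ]
    return all(not np.isnan(v) and v >= gate for v, gate in checks)


def select_eye(
    records: Sequence[ParticipantRecord],
    min_sq: int = MIN_SQ,
    min_ssi: dict | None = None,
) -> ParticipantRecord | None:
    """Pick one eye per participant: OD if it passes the quality gates and is
    free of pathology, else OS if OS passes, else None (participant excluded,
    logged)."""
    if min_ssi is None:
        min_ssi = dict(MIN_SSI)
    if not 1 <= len(records) <= 2:
        raise ValueError("select_eye expects 1-2 eye rows for one participant")
    ids = {r.id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records belong to different participants: {ids}")
    by_eye = {r.eye: r for r in records}
    for eye in ("OD", "OS"):
        rec = by_eye.get(eye)
        if rec is not None and _eye_passes(rec, min_sq, min_ssi):
            return rec
    logger.info("participant %s excluded: no eye passes the quality gates", records[0].id)
    return None


def select_cohort(
    records: Iterable[ParticipantRecord],
    min_sq: int = MIN_SQ,
    min_ssi: dict | None = None,
) -> list[ParticipantRecord]:
    """Apply :func:`select_eye` across a per-eye cohort table."""
    by_id: dict[str, list[ParticipantRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.id, []).append(rec)
    out = []
    for pid in by_id:
        chosen = select_eye(by_id[pid], min_sq=min_sq, min_ssi=min_ssi)
        if chosen is not None:
            out.append(chosen)
    return out


# ---------------------------------------------------------------------------
# Two-sample comparison
# ---------------------------------------------------------------------------


def hedges_g(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """(Hedges' g, Cohen's d) for *b minus a*, pooled SD, J = 1 − 3/(4N − 9)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return float("nan"), float("nan")
    d = (b.mean() - a.mean()) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return j * d, d


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value: exact for combined n <= 25 without
    ties, otherwise the tie-corrected normal approximation with continuity
    correction."""
    combined = np.concatenate([a, b])
    exact = len(combined) <= 25 and len(np.unique(combined)) == len(combined)
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_groups(
    values_impaired: Sequence[float],
    values_control: Sequence[float],
    force_test: str | None = None,
    variable: str = "",
    alpha_normality: float = ALPHA_NORMALITY,
) -> GroupComparisonResult:
    """Normality-gated two-sample comparison of impaired vs control values.

    Missing values are dropped per group.  Unless ``force_test`` is given
    (``"student_t"`` or ``"mann_whitney"``), Student's t is used when both
    groups pass Shapiro–Wilk at ``alpha_normality``, Mann–Whitney U otherwise.
    Hedges' g is signed as control minus impaired (positive g = controls
    higher).
    """
    a = np.asarray(values_impaired, float)
    b = np.asarray(values_control, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 non-missing values per group")

    sw_a = sw_b = np.nan
    if force_test is None:
        degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
        if degenerate:
            test = "mann_whitney"  # Shapiro undefined on constant data
        else:
            sw_a = stats.shapiro(a).pvalue
            sw_b = stats.shapiro(b).pvalue
            test = (
                "student_t"
                if (sw_a > alpha_normality and sw_b > alpha_normality)
                else "mann_whitney"
            )
    elif force_test in ("student_t", "mann_whitney"):
        test = force_test
    else:
        raise ValueError("force_test must be 'student_t' or 'mann_whitney'")

    if test == "student_t":
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    else:
        p = _mann_whitney(a, b)
    g, d = hedges_g(a, b)
    if math.isnan(g):
        logger.warning("compare_groups(%s): zero pooled variance, g undefined", variable)
    return GroupComparisonResult(
        variable=variable,
        n_impaired=len(a),
        n_control=len(b),
        mean_impaired=float(a.mean()),
        sd_impaired=float(a.std(ddof=1)),
        min_impaired=float(a.min()),
        max_impaired=float(a.max()),
        mean_control=float(b.mean()),
        sd_control=float(b.std(ddof=1)),
        min_control=float(b.min()),
        max_control=float(b.max()),
        test_used=test,
        p_value=p,
        hedges_g=float(g),
        cohen_d=float(d),
        shapiro_p_impaired=float(sw_a),
        shapiro_p_control=float(sw_b),
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n, no ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, perm)[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    force_method: str | None = None,
    x_name: str = "x",
    y_name: str = "y",
    alpha_normality: float = ALPHA_NORMALITY,
    exact_max_n: int = 8,
) -> CorrelationResult:
    """Normality-gated correlation between two paired variables.

    Pearson when both variables pass Shapiro–Wilk at ``alpha_normality``,
    Spearman otherwise (or as forced).  Spearman p-values are exact
    (permutation enumeration) for ``n <= exact_max_n`` without ties, else the
    scipy asymptotic approximation.
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant vector: correlation undefined")

    if force_method is None:
        ok = (
            stats.shapiro(xv).pvalue > alpha_normality
            and stats.shapiro(yv).pvalue > alpha_normality
        )
        method = "pearson" if ok else "spearman"
    elif force_method in ("pearson", "spearman"):
        method = force_method
    else:
        raise ValueError("force_method must be 'pearson' or 'spearman'")

    if method == "pearson":
        res = stats.pearsonr(xv, yv)
        r, p = float(res.statistic), float(res.pvalue)
    else:
        r = float(stats.spearmanr(xv, yv).statistic)
        no_ties = len(np.unique(xv)) == n and len(np.unique(yv)) == n
        if n <= exact_max_n and no_ties:
            p = float(_spearman_exact_p(xv, yv))
        else:
            p = float(stats.spearmanr(xv, yv).pvalue)
    return CorrelationResult(x=x_name, y=y_name, method=method, r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


def icc(ratings: np.ndarray, mode: str) -> ICCResult:
    """Two-way single-measure intraclass correlation from a complete
    subjects × raters layout.

    ``mode="absolute_agreement"`` gives ICC(A,1), which penalizes systematic
    rater offsets; ``mode="consistency"`` gives ICC(C,1), which does not
    (McGraw & Wong two-way mean-squares definitions).
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters array")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells not allowed in the two-way ICC layout")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if mode == "consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
    elif mode == "absolute_agreement":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    else:
        raise ValueError("mode must be 'absolute_agreement' or 'consistency'")
    return ICCResult(mode=mode, value=float(value), n_subjects=n, k_raters=k)


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------


def _comparison_row(result: GroupComparisonResult, label: str) -> dict:
    return {
        "variable": label,
        "n_impaired": result.n_impaired,
        "n_control": result.n_control,
        "impaired_mean": result.mean_impaired,
        "impaired_sd": result.sd_impaired,
        "impaired_range": f"{result.min_impaired:g}-{result.max_impaired:g}",
        "control_mean": result.mean_control,
        "control_sd": result.sd_control,
        "control_range": f"{result.min_control:g}-{result.max_control:g}",
        "test": result.test_used,
        "p_value": result.p_value,
        "hedges_g": result.hedges_g,
    }


def _missing_row(label: str) -> dict:
    return {
        "variable": label,
        "n_impaired": 0,
        "n_control": 0,
        "impaired_mean": np.nan,
        "impaired_sd": np.nan,
        "impaired_range": "",
        "control_mean": np.nan,
        "control_sd": np.nan,
        "control_range": "",
        "test": "",
        "p_value": np.nan,
        "hedges_g": np.nan,
    }


def _metric_values(records: Sequence[ParticipantRecord], column: str) -> np.ndarray:
    return np.array([rec.metrics.get(column, np.nan) for rec in records], float)


def reproduce_tables(
    cohort: Sequence[ParticipantRecord],
    force_test: str | None = None,
    force_corr: str | None = None,
) -> dict:
    """Assemble the full statistical output from analysis-ready records.

    ``cohort`` holds one selected eye per participant.  Returns a dict with
    four DataFrames — ``table1`` (demographics/cognition), ``table2``
    (vascular metrics), ``table3`` (MoCA correlations over the entire
    cohort), ``tableS1`` (supplementary metrics) — and a ``diagnostics``
    record of the per-variable normality p-values and tests chosen.
    """
    impaired = [r for r in cohort if r.impaired]
    control = [r for r in cohort if not r.impaired]
    if len(impaired) < 2 or len(control) < 2:
        raise ValueError("need at least 2 participants per group")
    diagnostics: dict[str, dict] = {}

    def compare(values_i, values_c, column, label, rows):
        vi = np.asarray(values_i, float)
        vc = np.asarray(values_c, float)
        if np.isnan(vi).all() or np.isnan(vc).all() or (
            len(vi[~np.isnan(vi)]) < 2 or len(vc[~np.isnan(vc)]) < 2
        ):
            rows.append(_missing_row(label))
            return
        res = compare_groups(vi, vc, force_test=force_test, variable=column)
        diagnostics[column] = {
            "shapiro_p_impaired": res.shapiro_p_impaired,
            "shapiro_p_control": res.shapiro_p_control,
            "test": res.test_used,
            "cohen_d": res.cohen_d,
        }
        rows.append(_comparison_row(res, label))

    t1_rows: list[dict] = []
    for column, label in TABLE1_VARIABLES:
        compare(
            [getattr(r, column) for r in impaired],
            [getattr(r, column) for r in control],
            column,
            label,
            t1_rows,
        )
    t2_rows: list[dict] = []
    for column, label in TABLE2_VARIABLES:
        compare(
            _metric_values(impaired, column),
            _metric_values(control, column),
            column,
            label,
            t2_rows,
        )
    ts1_rows: list[dict] = []
    for column, label in TABLE_S1_VARIABLES:
        compare(
            _metric_values(impaired, column),
            _metric_values(control, column),
            column,
            label,
            ts1_rows,
        )

    t3_rows: list[dict] = []
    moca = np.array([r.moca for r in cohort], float)
    for column, label in TABLE3_VARIABLES:
        vals = _metric_values(cohort, column)
        keep = ~(np.isnan(vals) | np.isnan(moca))
        if keep.sum() < 3 or np.ptp(vals[keep]) == 0:
            t3_rows.append(
                {"variable": label, "method": "", "r": np.nan, "p_value": np.nan, "n": 0}
            )
            continue
        res = correlate(
            moca, vals, force_method=force_corr, x_name="moca", y_name=column
        )
        diagnostics.setdefault("correlations", {})[column] = {"method": res.method}
        t3_rows.append(
            {
                "variable": label,
                "method": res.method,
                "r": res.r,
                "p_value": res.p,
                "n": res.n,
            }
        )

    return {
        "table1": pd.DataFrame(t1_rows),
        "table2": pd.DataFrame(t2_rows),
        "table3": pd.DataFrame(t3_rows),
        "tableS1": pd.DataFrame(ts1_rows),
        "diagnostics": diagnostics,
    }
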