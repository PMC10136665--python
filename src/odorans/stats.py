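"""Paired cohort statistics: T0-vs-T1 and within-session phase comparisons.

The cohort feature table is long-form: one row per (subject, session,
phase, feature, value). Comparisons follow small-cohort nonparametric
practice: Shapiro-Wilk normality is recorded but the paired Wilcoxon
signed-rank test is used throughout (exact null for n <= 25, zero
differences dropped), Kendall's tau-b for correlations, significance
markers * p < 0.05 and ** p < 0.01, no multiple-testing correction by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    InsufficientDataError,
    NoInformationError,
)

log = logging.getLogger(__name__)

ECG_FEATURES = ("HR", "RMSSD", "NN50", "CSI", "CVI", "LF", "HF", "LF/HF")
GSR_FEATURES = ("Global", "Tonic", "Phasic")
FEATURE_ORDER = ECG_FEATURES + GSR_FEATURES
PHASE_ORDER = ("Baseline", "Task", "Recovery")

TABLE_COLUMNS = [
    "feature", "phase", "n_pairs",
    "mean_t0", "sd_t0", "mean_t1", "sd_t1",
    "test", "p_value", "marker",
]


def significance_marker(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def normality_check(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk statistic, p-value, and the normality decision at alpha."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or len(v) > 5000:
        raise InsufficientDataError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise DegenerateSampleError("all values identical")
    res = sst.shapiro(v)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue >= alpha)


def paired_wilcoxon(t0_values, t1_values) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's original policy); the exact
    null distribution is used for n <= 25 (falling back to the
    tie-corrected normal approximation when ties prevent it). Returns
    (statistic, p, n_used).
    """
    a = np.asarray(t0_values, dtype=float)
    b = np.asarray(t1_values, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    d = b - a
    nz = d[d != 0]
    if len(nz) == 0:
        raise NoInformationError("all paired differences are zero")
    if len(nz) < 5:
        raise InsufficientDataError(
            f"only {len(nz)} nonzero differences; need >= 5"
        )
    log.debug("wilcoxon: dropped %d zero differences", len(d) - len(nz))
    method = "exact" if len(nz) <= 25 else "approx"
    try:
        res = sst.wilcoxon(nz, zero_method="wilcox", method=method)
    except ValueError:
        res = sst.wilcoxon(nz, zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue), int(len(nz))


def kendall_correlation(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie handling and its two-sided p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ConfigurationError("Kendall correlation needs paired n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateSampleError("constant vector: tau undefined")
    res = sst.kendalltau(xv, yv)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort feature table
# ---------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "session", "phase", "feature", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"feature table lacks columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject", "session", "phase", "feature"])
    if dup.any():
        raise ConfigurationError(
            f"{int(dup.sum())} duplicate (subject, session, phase, feature) rows"
        )
    return table


def _ordered(values, order) -> list:
    known = [v for v in order if v in values]
    extra = [v for v in values if v not in order]
    return known + sorted(extra)


def compare_sessions(
    table: pd.DataFrame,
    min_pairs: int = 5,
    features: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One comparison row per feature x phase: T0 vs T1 paired Wilcoxon.

    Means and sample (N-1) SDs are computed over the paired subjects. Cells
    with fewer than ``min_pairs`` complete pairs, or with no informative
    differences, get a missing p-value and a logged warning.
    """
    validate_feature_table(table)
    rows = []
    phases = _ordered(table["phase"].unique(), PHASE_ORDER)
    feats = list(features) if features else _ordered(
        table["feature"].unique(), FEATURE_ORDER
    )
    wide = table.pivot_table(
        index=["subject", "phase", "feature"], columns="session", values="value",
        aggfunc="first",
    )
    for phase in phases:
        for feature in feats:
            try:
                cell = wide.xs((phase, feature), level=("phase", "feature"))
            except KeyError:
                continue
            cell = cell.dropna(subset=["T0", "T1"]) if {
                "T0", "T1"
            } <= set(cell.columns) else cell.iloc[0:0]
            n = len(cell)
            row = {
                "feature": feature, "phase": phase, "n_pairs": n,
                "mean_t0": np.nan, "sd_t0": np.nan,
                "mean_t1": np.nan, "sd_t1": np.nan,
                "test": "wilcoxon", "p_value": np.nan, "marker": "",
            }
            if n:
                row["mean_t0"] = float(cell["T0"].mean())
                row["sd_t0"] = float(cell["T0"].std(ddof=1)) if n > 1 else np.nan
                row["mean_t1"] = float(cell["T1"].mean())
                row["sd_t1"] = float(cell["T1"].std(ddof=1)) if n > 1 else np.nan
            if n < min_pairs:
                log.warning(
                    "%s/%s: only %d complete pairs; p-value omitted",
                    phase, feature, n,
                )
            else:
                try:
                    _, p, _ = paired_wilcoxon(cell["T0"], cell["T1"])
                    row["p_value"] = p
                    row["marker"] = significance_marker(p)
                except (NoInformationError, InsufficientDataError) as exc:
                    log.warning("%s/%s: %s", phase, feature, exc)
            rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def compare_phases(
    table: pd.DataFrame,
    session: str,
    pairs: tuple[tuple[str, str], ...] = (("Baseline", "Task"), ("Task", "Recovery")),
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Within-session phase contrasts (e.g. Baseline vs Task) per feature."""
    validate_feature_table(table)
    sub = table[table["session"] == session]
    rows = []
    feats = _ordered(sub["feature"].unique(), FEATURE_ORDER)
    wide = sub.pivot_table(
        index=["subject", "feature"], columns="phase", values="value",
        aggfunc="first",
    )
    for pa, pb in pairs:
        for feature in feats:
            try:
                cell = wide.xs(feature, level="feature")
            except KeyError:
                continue
            if pa not in cell.columns or pb not in cell.columns:
                continue
            cell = cell.dropna(subset=[pa, pb])
            n = len(cell)
            row = {
                "feature": feature, "phase": f"{pa} vs {pb}", "n_pairs": n,
                "mean_t0": float(cell[pa].mean()) if n else np.nan,
                "sd_t0": float(cell[pa].std(ddof=1)) if n > 1 else np.nan,
                "mean_t1": float(cell[pb].mean()) if n else np.nan,
                "sd_t1": float(cell[pb].std(ddof=1)) if n > 1 else np.nan,
                "test": "wilcoxon", "p_value": np.nan, "marker": "",
            }
            if n >= min_pairs:
                try:
                    _, p, _ = paired_wilcoxon(cell[pa], cell[pb])
                    row["p_value"] = p
                    row["marker"] = significance_marker(p)
                except (NoInformationError, InsufficientDataError) as exc:
                    log.warning("%s %s/%s: %s", session, row["phase"], feature, exc)
            else:
                log.warning(
                    "%s %s/%s: only %d complete pairs; p-value omitted",
                    session, row["phase"], feature, n,
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Odor identification scoring
# ---------------------------------------------------------------------------

@dataclass
class IdentificationScore:
    """Per-subject correct-identification counts and the cohort summary."""

    counts: pd.DataFrame          # columns subject, session, correct
    summary: pd.DataFrame         # columns session, mean, sd, n
    p_value: float                # paired Wilcoxon T0 vs T1 (NaN if unavailable)


def score_identification(
    responses: dict[str, dict[str, list[str]]],
    answer_key: tuple[str, ...],
    synonyms: dict[str, str] | None = None,
) -> IdentificationScore:
    """Count exact (case-insensitive) descriptor matches against the key.

    ``responses[subject][session]`` is the ordered list of reported
    descriptors; an optional synonym map normalises spelling variants.
    Descriptors not in the key are flagged and counted incorrect.
    """
    syn = {k.strip().lower(): v.strip().lower() for k, v in (synonyms or {}).items()}
    key = [k.strip().lower() for k in answer_key]
    known = set(key)
    rows = []
    for subject, sessions in responses.items():
        for session, answers in sessions.items():
            correct = 0
            for i, given in enumerate(answers[: len(key)]):
                g = str(given).strip().lower()
                g = syn.get(g, g)
                if g not in known:
                    log.warning(
                        "%s/%s: unknown descriptor %r counted incorrect",
                        subject, session, given,
                    )
                if g == key[i]:
                    correct += 1
            rows.append({"subject": subject, "session": session, "correct": correct})
    counts = pd.DataFrame(rows)
    summary = (
        counts.groupby("session")["correct"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    p = np.nan
    wide = counts.pivot_table(index="subject", columns="session", values="correct")
    if {"T0", "T1"} <= set(wide.columns):
        paired = wide.dropna(subset=["T0", "T1"])
        if len(paired) >= 5:
            try:
                _, p, _ = paired_wilcoxon(paired["T0"], paired["T1"])
            except (NoInformationError, InsufficientDataError):
                pass
    return IdentificationScore(counts=counts, summary=summary, p_value=float(p))
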