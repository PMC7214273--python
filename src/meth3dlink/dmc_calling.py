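"""Differential CpG methylation calling over the transdifferentiation course.

A CpG is called differentially methylated when its between-endpoint test is
significant (p < 0.05 by default, unadjusted) AND the endpoint beta change is
large (|delta beta| >= 0.66 by default, inclusive). Both inequalities matter:
strict ``<`` on p, inclusive ``>=`` on the magnitude. The significance test
defaults to a Welch t between the 0 h and 168 h replicate groups, matching the
endpoint semantics of the delta-beta filter; a one-way F across all seven
timepoints is available for probes whose trajectory is not endpoint-dominated.

Statistics are computed on beta values directly. An M-value transform
(log2(b/(1-b))) is available for the test stage only — the delta-beta filter
is always on the beta scale, where the 0.66 threshold is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .io_formats import BetaMatrix

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_DELTA_THRESHOLD = 0.66


@dataclass(frozen=True)
class DMCRecord:
    """Per-probe differential methylation call."""

    probe_id: str
    beta_t0: float
    beta_t168: float
    delta_beta: float  # beta_t168 - beta_t0, in [-1, 1]
    p_value: float
    q_value: float
    direction: str  # 'hypo' if delta_beta < 0 else 'hyper'
    passes: bool


@dataclass(frozen=True)
class ConcordanceRecord:
    """How close a DMC's endpoint methylation sits to each control profile."""

    probe_id: str
    dist_to_positive: float
    dist_to_negative: float
    macrophage_like: bool


@dataclass(frozen=True)
class DMCSummary:
    n_probes: int
    n_pass: int
    n_hypo: int
    n_hyper: int


def _group(beta: BetaMatrix, timepoint_h: int) -> np.ndarray:
    cols = beta.columns_for("transdiff", timepoint_h)
    if not cols:
        raise InputError(f"no transdiff samples at {timepoint_h} h")
    return beta.values[cols].to_numpy(dtype=float)


def delta_beta(beta: BetaMatrix, probe_id: str, t_from: int, t_to: int) -> float:
    """Signed mean beta change: mean(beta at t_to) - mean(beta at t_from)."""
    cols_from = beta.columns_for("transdiff", t_from)
    cols_to = beta.columns_for("transdiff", t_to)
    if not cols_from or not cols_to:
        raise InputError(f"missing timepoint among ({t_from} h, {t_to} h)")
    row = beta.values.loc[probe_id]
    return float(row[cols_to].mean() - row[cols_from].mean())


def _m_transform(arr: np.ndarray) -> np.ndarray:
    eps = 1e-6  # guard against beta of exactly 0 or 1
    b = np.clip(arr, eps, 1 - eps)
    return np.log2(b / (1 - b))


def _welch_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t over rows; degenerate rows handled by
    convention: zero variance in both groups gives p = 1 for equal means and
    the smallest positive float for unequal means (so p stays in (0, 1])."""
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a[degenerate].mean(axis=1), b[degenerate].mean(axis=1))
        fill = np.where(equal, 1.0, np.finfo(float).tiny)
        p[degenerate] = fill
    return np.clip(p, np.finfo(float).tiny, 1.0)


def test_probe(
    beta: BetaMatrix,
    probe_id: str,
    method: Literal["welch_t", "anova_f"] = "welch_t",
    use_m_values: bool = False,
) -> float:
    """Two-sided p-value for differential methylation of one probe.

    ``welch_t`` compares the 0 h and 168 h replicate groups (>=2 replicates in
    each); ``anova_f`` is a one-way F across all timepoints with >=2
    replicates at >=2 timepoints.
    """
    idx = beta.values.index.get_loc(probe_id)
    if method == "welch_t":
        a = _group(beta, 0)[idx : idx + 1]
        b = _group(beta, 168)[idx : idx + 1]
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise InputError("welch_t needs >=2 replicates at both 0 h and 168 h")
        if use_m_values:
            a, b = _m_transform(a), _m_transform(b)
        return float(_welch_t_pvalues(a, b)[0])
    if method == "anova_f":
        groups = []
        for t in beta.timepoints():
            g = _group(beta, t)[idx]
            if len(g) >= 2:
                groups.append(_m_transform(g) if use_m_values else g)
        if len(groups) < 2:
            raise InputError("anova_f needs >=2 replicates at >=2 timepoints")
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(
            [g[0] for g in groups]
        ) == 0:
            return 1.0
        f, p = stats.f_oneway(*groups)
        if np.isnan(p):
            means = [float(np.mean(g)) for g in groups]
            return 1.0 if np.ptp(means) == 0 else float(np.finfo(float).tiny)
        return float(np.clip(p, np.finfo(float).tiny, 1.0))
    raise InputError(f"unknown test method {method!r}")


def call_dmcs(
    beta: BetaMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    adjust: Literal["none", "bh"] = "none",
    method: Literal["welch_t", "anova_f"] = "welch_t",
    use_m_values: bool = False,
) -> list[DMCRecord]:
    """Call differentially methylated CpGs between 0 h and 168 h.

    Returns one record per probe in input row order. ``passes`` is the
    conjunction of the significance filter (strict ``<`` on p, or on the BH
    q-value when ``adjust='bh'``) and the magnitude filter (inclusive ``>=``
    on |delta beta|).
    """
    if beta.values.empty:
        raise InputError("empty beta matrix")
    a = _group(beta, 0)
    b = _group(beta, 168)

    mean0 = a.mean(axis=1)
    mean168 = b.mean(axis=1)
    delta = mean168 - mean0

    if method == "welch_t":
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise InputError("welch_t needs >=2 replicates at both 0 h and 168 h")
        ta, tb = (
            (_m_transform(a), _m_transform(b)) if use_m_values else (a, b)
        )
        p = _welch_t_pvalues(ta, tb)
    else:
        p = np.array(
            [
                test_probe(beta, pid, method=method, use_m_values=use_m_values)
                for pid in beta.feature_ids
            ]
        )

    q = multipletests(p, method="fdr_bh")[1]
    sig = (q if adjust == "bh" else p) < p_threshold
    # inclusive magnitude filter; epsilon so a delta of exactly the threshold
    # passes despite binary rounding of values like 0.66
    passes = sig & (np.abs(delta) >= delta_threshold - 1e-12)

    return [
        DMCRecord(
            probe_id=pid,
            beta_t0=float(mean0[i]),
            beta_t168=float(mean168[i]),
            delta_beta=float(delta[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            direction="hypo" if delta[i] < 0 else "hyper",
            passes=bool(passes[i]),
        )
        for i, pid in enumerate(beta.feature_ids)
    ]


def passing(dmcs: Sequence[DMCRecord]) -> list[DMCRecord]:
    return [d for d in dmcs if d.passes]


def summarize(dmcs: Sequence[DMCRecord]) -> DMCSummary:
    ps = passing(dmcs)
    return DMCSummary(
        n_probes=len(dmcs),
        n_pass=len(ps),
        n_hypo=sum(d.direction == "hypo" for d in ps),
        n_hyper=sum(d.direction == "hyper" for d in ps),
    )


def control_concordance(
    beta: BetaMatrix, dmcs: Sequence[DMCRecord], tol: float = 0.2
) -> list[ConcordanceRecord]:
    """Score whether each passing DMC's 168 h methylation mimics the positive
    (macrophage-like) control rather than the negative (untransdifferentiated)
    control: macrophage_like requires dist_to_positive < tol and
    dist_to_positive < dist_to_negative."""
    pos_cols = beta.columns_for("positive_control")
    neg_cols = beta.columns_for("negative_control")
    if not pos_cols or not neg_cols:
        raise InputError("both control conditions are required")
    out = []
    for d in dmcs:
        if not d.passes:
            continue
        row = beta.values.loc[d.probe_id]
        dp = abs(d.beta_t168 - float(row[pos_cols].mean()))
        dn = abs(d.beta_t168 - float(row[neg_cols].mean()))
        out.append(
            ConcordanceRecord(
                probe_id=d.probe_id,
                dist_to_positive=dp,
                dist_to_negative=dn,
                macrophage_like=(dp < tol and dp < dn),
            )
        )
    return out


def macrophage_like_fraction(records: Sequence[ConcordanceRecord]) -> float:
    if not records:
        return 0.0
    return sum(r.macrophage_like for r in records) / len(records)


def dmc_table(dmcs: Sequence[DMCRecord]):
    """Flat DataFrame view of DMC records (one row per probe)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "probe_id": [d.probe_id for d in dmcs],
            "beta_t0": [d.beta_t0 for d in dmcs],
            "beta_t168": [d.beta_t168 for d in dmcs],
            "delta_beta": [d.delta_beta for d in dmcs],
            "p_value": [d.p_value for d in dmcs],
            "q_value": [d.q_value for d in dmcs],
            "direction": [d.direction for d in dmcs],
            "passes": [d.passes for d in dmcs],
        }
    )
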