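"""Edgewise group statistics and cohort-balance tests.

All edgewise operations act on the 190 unique off-diagonal edges of the
20x20 connectivity matrices.  Multiple testing is controlled with
Benjamini-Hochberg FDR over that family (duplicated symmetric entries
would distort the correction, so the flattened 400-entry view is never
used here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import ConnectivityMatrix, edge_names


@dataclass
class EdgewiseStats:
    """Per-edge statistic with raw p, BH-adjusted q and significance mask."""

    table: pd.DataFrame  # edge_i, edge_j, statistic, p, q, significant
    kind: str
    statistic_name: str
    q_threshold: float
    notes: str = ""

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.table[self.table.significant]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone enforced).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    valid = np.isfinite(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def _edge_stack(matrices: list[ConnectivityMatrix], kind: str | None = None) -> np.ndarray:
    if not matrices:
        raise ValueError("empty matrix list")
    kinds = {m.kind for m in matrices}
    if len(kinds) > 1:
        raise ValueError(f"mixed matrix kinds {sorted(kinds)}")
    if kind is not None and matrices[0].kind != kind:
        raise ValueError(f"expected kind {kind!r}, got {matrices[0].kind!r}")
    return np.stack([m.edge_vector() for m in matrices])


def _finish(
    statistic: np.ndarray,
    p: np.ndarray,
    labels,
    kind: str,
    statistic_name: str,
    q_threshold: float,
    notes: str = "",
    extra_cols: dict | None = None,
) -> EdgewiseStats:
    q = bh_fdr(p)
    names = edge_names(labels)
    table = pd.DataFrame(
        {
            "edge_i": [a for a, _ in names],
            "edge_j": [b for _, b in names],
            "statistic": statistic,
            "p": p,
            "q": q,
            "significant": np.where(np.isfinite(q), q < q_threshold, False),
        }
    )
    if extra_cols:
        for k, v in extra_cols.items():
            table[k] = v
    return EdgewiseStats(table, kind, statistic_name, q_threshold, notes)


def edgewise_ttest(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    q_threshold: float = 0.05,
    welch: bool = False,
) -> EdgewiseStats:
    """Two-sample t-test (pooled variance by default) per unique edge.

    Edges with zero variance in both groups get NaN p and are excluded
    from the FDR family.
    """
    a = _edge_stack(group_a)
    b = _edge_stack(group_b, kind=group_a[0].kind)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if welch:
        res = sps.ttest_ind(a, b, axis=0, equal_var=False)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    else:
        m1, m2 = a.mean(0), b.mean(0)
        v1, v2 = a.var(0, ddof=1), b.var(0, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(np.abs(t), df)
        # zero pooled variance: t undefined, drop the edge from the family
        degenerate = sp2 == 0
        t = np.where(degenerate, np.where(m1 == m2, 0.0, np.nan), t)
        p = np.where(degenerate, np.nan, p)
    return _finish(
        t, p, group_a[0].labels, group_a[0].kind, "t", q_threshold,
        notes=f"two-sample t ({'Welch' if welch else 'pooled'}), A minus B",
    )


def edgewise_duration_correlation(
    matrices: list[ConnectivityMatrix],
    durations,
    q_threshold: float = 0.05,
) -> EdgewiseStats:
    """Pearson correlation of every edge with disease duration."""
    x = _edge_stack(matrices)
    d = np.asarray(durations, dtype=float)
    if len(d) != x.shape[0]:
        raise ValueError("durations length must match subject count")
    if not np.isfinite(d).all():
        raise ValueError("durations must be finite")
    n = len(d)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(d) == 0:
        raise ValueError("durations are constant; correlation undefined")
    dz = d - d.mean()
    xz = x - x.mean(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xz.T @ dz) / (np.linalg.norm(xz, axis=0) * np.linalg.norm(dz))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.isfinite(r), np.where(np.abs(r) == 1.0, 0.0, p), np.nan)
    r = np.where(np.isfinite(r), r, np.nan)
    return _finish(
        r, p, matrices[0].labels, matrices[0].kind, "r", q_threshold,
        notes="Pearson r of edge z-value against epilepsy duration (years)",
    )


def interaction_model(
    matrices: list[ConnectivityMatrix],
    group_labels,
    durations,
    q_threshold: float = 0.05,
) -> EdgewiseStats:
    """Per-edge OLS ``z = b0 + b1 g + b2 d + b3 (g x d)`` with a t-test
    on the interaction coefficient b3.

    Group coding: GE = 0, FE = 1 (otherwise the first label encountered
    codes 0); the coding is recorded in ``notes``.
    """
    y = _edge_stack(matrices)
    g_raw = np.asarray(group_labels)
    d = np.asarray(durations, dtype=float)
    n = y.shape[0]
    if len(g_raw) != n or len(d) != n:
        raise ValueError("labels/durations length must match subject count")
    uniq = list(dict.fromkeys(g_raw.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    if "GE" in uniq and "FE" in uniq:
        uniq = ["GE", "FE"]
    g = (g_raw == uniq[1]).astype(float)
    for lab, cnt in zip(uniq, [int((g == 0).sum()), int((g == 1).sum())]):
        if cnt < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 subjects")
    x = np.column_stack([np.ones(n), g, d, g * d])
    if np.linalg.matrix_rank(x) < 4:
        raise ValueError("interaction design is rank-deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (4, n_edges)
    resid = y - x @ beta
    dof = n - 4
    sigma2 = (resid**2).sum(0) / dof
    se_b3 = np.sqrt(sigma2 * xtx_inv[3, 3])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[3] / se_b3
    p = np.where(se_b3 == 0, np.where(beta[3] == 0, np.nan, 0.0), 2 * sps.t.sf(np.abs(t), dof))
    t = np.where((se_b3 == 0) & (beta[3] == 0), 0.0, t)
    return _finish(
        beta[3], p, matrices[0].labels, matrices[0].kind, "b3", q_threshold,
        notes=f"interaction slope difference ({uniq[1]} minus {uniq[0]}); coding {uniq[0]}=0, {uniq[1]}=1",
        extra_cols={"t": t},
    )


@dataclass
class CohortBalance:
    age_f: float
    age_p: float
    sex_chi2: float
    sex_p: float
    duration_t: float
    duration_p: float
    frequency_t: float
    frequency_p: float


def cohort_balance(phenotypes: pd.DataFrame) -> CohortBalance:
    """Demographic balance: one-way ANOVA on age across the three
    groups, Pearson chi-square (no continuity correction) on sex, and
    pooled two-sample t on duration and seizure frequency between the
    patient groups."""
    groups = [g for g, sub in phenotypes.groupby("group", sort=False)]
    if any(len(phenotypes[phenotypes.group == g]) == 0 for g in groups):
        raise ValueError("empty group")
    ages = [phenotypes.loc[phenotypes.group == g, "age"].to_numpy() for g in groups]
    age_f, age_p = sps.f_oneway(*ages)
    contingency = pd.crosstab(phenotypes["group"], phenotypes["sex"]).to_numpy()
    if (contingency.sum(axis=0) == 0).any() or contingency.shape[1] < 2:
        sex_chi2, sex_p = 0.0, 1.0
    else:
        sex_chi2, sex_p, *_ = sps.chi2_contingency(contingency, correction=False)
    patients = phenotypes[phenotypes.group.isin(["GE", "FE"])]
    pg = [patients.loc[patients.group == g] for g in ["GE", "FE"] if (patients.group == g).any()]
    if len(pg) == 2:
        dur_t, dur_p = sps.ttest_ind(
            pg[0]["duration_years"], pg[1]["duration_years"], equal_var=True
        )
        frq_t, frq_p = sps.ttest_ind(
            pg[0]["seizure_freq_per_month"], pg[1]["seizure_freq_per_month"], equal_var=True
        )
    else:
        dur_t = dur_p = frq_t = frq_p = np.nan
    return CohortBalance(
        float(age_f), float(age_p), float(sex_chi2), float(sex_p),
        float(dur_t), float(dur_p), float(frq_t), float(frq_p),
    )
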