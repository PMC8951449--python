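"""Split-half consistency and sliding-window sensitivity analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import ConnectivityMatrix, dfc_variability, dynamic_network


@dataclass
class SplitReport:
    """Half memberships plus demographic balance of the split."""

    assignments: pd.DataFrame  # id, group, half (A/B)
    balance: pd.DataFrame  # group, age_p, sex_p

    def half_ids(self, half: str) -> list[str]:
        return self.assignments.loc[self.assignments.half == half, "id"].tolist()


def split_half(cohort: pd.DataFrame, seed: int = 0) -> SplitReport:
    """Split every group into two matched halves.

    Within each group, subjects are stratified by sex and sorted by age
    (ties shuffled reproducibly from ``seed``), then dealt alternately
    into the two halves; each stratum starts with whichever half is
    currently smaller so the final sizes differ by at most one.
    """
    rng = np.random.default_rng(seed)
    rows = []
    balance_rows = []
    for group, sub in cohort.groupby("group", sort=False):
        if len(sub) < 4:
            raise ValueError(f"group {group!r} too small to split")
        counts = {"A": 0, "B": 0}
        assign: dict[str, str] = {}
        for sex in sorted(sub["sex"].unique()):
            stratum = sub[sub.sex == sex].copy()
            stratum["_jitter"] = rng.random(len(stratum))
            stratum = stratum.sort_values(["age", "_jitter"], kind="stable")
            first = "A" if counts["A"] <= counts["B"] else "B"
            order = [first, "B" if first == "A" else "A"]
            for k, sid in enumerate(stratum["id"]):
                half = order[k % 2]
                assign[sid] = half
                counts[half] += 1
        for sid in sub["id"]:
            rows.append({"id": sid, "group": group, "half": assign[sid]})
        a = sub[sub.id.map(assign) == "A"]
        b = sub[sub.id.map(assign) == "B"]
        age_p = float(sps.ttest_ind(a["age"], b["age"], equal_var=True).pvalue)
        tab = pd.crosstab(sub.id.map(assign), sub["sex"]).to_numpy()
        if tab.shape == (2, 2):
            sex_p = float(sps.chi2_contingency(tab, correction=False)[1])
        else:
            sex_p = 1.0
        balance_rows.append({"group": group, "age_p": age_p, "sex_p": sex_p})
    return SplitReport(pd.DataFrame(rows), pd.DataFrame(balance_rows))


def pattern_correlation(
    mean_a: ConnectivityMatrix, mean_b: ConnectivityMatrix
) -> tuple[float, float]:
    """Pearson r (and p) between the 190 unique edges of two group-mean
    matrices -- the topological-consistency statistic."""
    if mean_a.kind != mean_b.kind:
        raise ValueError(f"kind mismatch: {mean_a.kind} vs {mean_b.kind}")
    if mean_a.labels != mean_b.labels:
        raise ValueError("ROI labels differ")
    r, p = sps.pearsonr(mean_a.edge_vector(), mean_b.edge_vector())
    return float(r), float(p)


def mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    kinds = {m.kind for m in matrices}
    if len(kinds) != 1:
        raise ValueError("mixed matrix kinds")
    return ConnectivityMatrix(
        np.mean([m.values for m in matrices], axis=0),
        kind=matrices[0].kind,
        labels=matrices[0].labels,
    )


def window_sweep(
    roi_signals: list[np.ndarray],
    window_sizes=(30, 60, 100),
    step_tr: int = 5,
    reference_window: int = 50,
) -> pd.DataFrame:
    """Recompute the group-mean dFC variability matrix for each window
    size and correlate its edge pattern with the reference-window one.

    Returns a table with one row per window size (reference included)
    giving the window count and the pattern correlation against the
    reference."""
    def group_sd(window: int) -> tuple[ConnectivityMatrix, int]:
        mats = []
        n_windows = None
        for sig in roi_signals:
            dyn = dynamic_network(sig, window_tr=window, step_tr=step_tr)
            n_windows = dyn.n_windows
            mats.append(dfc_variability(dyn))
        return mean_matrix(mats), n_windows

    ref, ref_windows = group_sd(reference_window)
    rows = [
        {
            "window_tr": reference_window,
            "n_windows": ref_windows,
            "pattern_r": 1.0,
            "pattern_p": 0.0,
            "reference": True,
        }
    ]
    for w in window_sizes:
        mat, n_win = group_sd(w)
        r, p = pattern_correlation(mat, ref)
        rows.append(
            {
                "window_tr": w,
                "n_windows": n_win,
                "pattern_r": r,
                "pattern_p": p,
                "reference": False,
            }
        )
    return pd.DataFrame(rows)
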