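"""Downstream quantification arithmetic for the wet-lab assays.

Covers the comparative-Ct (2^-ddCt) method for qPCR with a stable reference
miRNA (miR-103 by default), western-blot densitometry normalized to the
beta-actin loading control and expressed relative to the baseline group,
WST-1 viability from corrected absorbance (A450 - A690) relative to control,
dual-luciferase reporter ratios (firefly normalized by Renilla, percent of
control), and the two-tailed two-sample t-test used for all pairwise
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ddct_ratio",
    "normalize_densitometry",
    "wst1_viability",
    "reporter_ratio",
    "two_tailed_t",
    "DEFAULT_REFERENCE_MIRNA",
]

DEFAULT_REFERENCE_MIRNA = "miR-103"


def _group_mean_ct(ct: pd.DataFrame, mirna: str, group: str) -> float:
    sub = ct[(ct["mirna"] == mirna) & (ct["group"] == group)]
    if sub.empty:
        raise ValueError(f"no Ct values for {mirna!r} in group {group!r}")
    vals = sub["ct"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite Ct for {mirna!r} in group {group!r}")
    return float(vals.mean())


def ddct_ratio(
    ct: pd.DataFrame,
    target: str,
    test_group: str,
    baseline_group: str,
    reference: str = DEFAULT_REFERENCE_MIRNA,
) -> dict:
    """Relative expression of ``target`` by the comparative-Ct method.

    dCt(g) = mean Ct(target, g) - mean Ct(reference, g);
    ddCt = dCt(test) - dCt(baseline); ratio = 2^-ddCt.

    ``ct`` is a long table with columns (mirna, sample_id, group, ct).
    Per-sample ratios (each sample's 2^-(dCt - dCt_baseline)) are also
    returned for dispersion estimates.
    """
    dct_test = _group_mean_ct(ct, target, test_group) - _group_mean_ct(
        ct, reference, test_group
    )
    dct_base = _group_mean_ct(ct, target, baseline_group) - _group_mean_ct(
        ct, reference, baseline_group
    )
    ddct = dct_test - dct_base

    # per-sample dCt in the test group relative to the baseline mean dCt
    per_sample = []
    ref_mean = {
        g: _group_mean_ct(ct, reference, g) for g in (test_group, baseline_group)
    }
    sub = ct[(ct["mirna"] == target) & (ct["group"] == test_group)]
    for _, row in sub.iterrows():
        per_sample.append(
            2.0 ** -((row["ct"] - ref_mean[test_group]) - dct_base)
        )
    return {
        "ratio": float(2.0 ** -ddct),
        "ddct": float(ddct),
        "dct_test": float(dct_test),
        "dct_baseline": float(dct_base),
        "per_sample_ratios": per_sample,
    }


def normalize_densitometry(
    table: pd.DataFrame, baseline_group: str = "ACR"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band densities normalized by beta-actin, relative to the baseline group.

    Each lane's ratio is (target_band/actin_band) divided by the mean
    target/actin of the baseline-group lanes, so the baseline group has mean
    ratio 1 by construction. Returns (per-lane table with ``ratio``,
    per-group mean/sd table).
    """
    required = {"lane_id", "group", "target_band", "actin_band"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"densitometry table missing column(s) {sorted(missing)}")
    zero = table[table["actin_band"] <= 0]
    if len(zero):
        raise ValueError(
            f"non-positive actin density in lane(s) {zero['lane_id'].tolist()}"
        )
    if (table["target_band"] < 0).any():
        raise ValueError("negative target band density")
    if not (table["group"] == baseline_group).any():
        raise ValueError(f"baseline group {baseline_group!r} absent from table")
    out = table.copy()
    out["target_over_actin"] = out["target_band"] / out["actin_band"]
    base_mean = out.loc[out["group"] == baseline_group, "target_over_actin"].mean()
    out["ratio"] = out["target_over_actin"] / base_mean
    per_group = (
        out.groupby("group")["ratio"].agg(["mean", "std"]).reset_index()
    )
    return out, per_group


def wst1_viability(a450, a690, control_corrected: float):
    """Percent viability: 100 * (A450 - A690) / control corrected absorbance."""
    if control_corrected <= 0:
        raise ValueError("control corrected absorbance must be positive")
    a450 = np.asarray(a450, dtype=float)
    a690 = np.asarray(a690, dtype=float)
    out = 100.0 * (a450 - a690) / control_corrected
    return float(out) if out.ndim == 0 else out


def reporter_ratio(firefly, renilla, control_ratio: float):
    """Firefly normalized by Renilla, as percent of the control ratio."""
    if control_ratio <= 0:
        raise ValueError("control firefly/Renilla ratio must be positive")
    renilla = np.asarray(renilla, dtype=float)
    if (renilla <= 0).any():
        raise ValueError("Renilla luminescence must be positive")
    firefly = np.asarray(firefly, dtype=float)
    out = 100.0 * (firefly / renilla) / control_ratio
    return float(out) if out.ndim == 0 else out


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def two_tailed_t(
    group_a, group_b, equal_var: bool = True
) -> TTestResult:
    """Two-sample two-tailed t-test (equal-variance by default; Welch with
    ``equal_var=False``).

    Two identical zero-variance groups are a degenerate comparison: by
    convention t = 0, p = 1, flagged ``degenerate=True``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(t=0.0, p=1.0, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p))
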