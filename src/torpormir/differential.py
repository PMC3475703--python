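"""Non-informative filtering, noise flooring and signed fold-difference
selection.

Probes without a single expression value above the system-noise floor carry
no usable signal and are excluded. Remaining values below the floor are
raised to it before group means are compared, so that fold differences are
never inflated by background-level denominators. The fold is a signed ratio:
+LH/ACR when LH >= ACR, -ACR/LH otherwise (negative = lower in the torpor
group), so its magnitude is always >= 1 and +1 denotes exact equality.
Selection keeps probes with |fold| >= threshold (1.25 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "filter_noninformative",
    "floor_to_noise",
    "fold_difference",
    "select_differential",
    "differential_table",
    "DifferentialResult",
]

DEFAULT_FOLD_THRESHOLD = 1.25


def filter_noninformative(
    matrix: ExpressionMatrix, nu: float
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop probes with no value strictly above the noise floor ``nu``.

    Returns ``(kept_matrix, excluded_probe_ids)``; the kept and excluded sets
    partition the input and probe ordering is preserved.
    """
    if nu <= 0:
        raise ValueError("noise floor must be positive")
    keep = (matrix.values > nu).any(axis=1)
    excluded = list(matrix.probe_ids[~keep])
    kept = matrix.copy_with(matrix.values.loc[keep])
    return kept, excluded


def floor_to_noise(matrix: ExpressionMatrix, nu: float) -> ExpressionMatrix:
    """Raise every value below ``nu`` to ``nu`` (idempotent)."""
    if nu <= 0:
        raise ValueError("noise floor must be positive")
    return matrix.copy_with(matrix.values.clip(lower=nu))


def fold_difference(mean_lh, mean_acr):
    """Signed fold between group means (vectorized).

    ``+mean_lh/mean_acr`` when LH >= ACR, else ``-mean_acr/mean_lh``;
    +1.0 at exact equality. Magnitude is always >= 1.
    """
    lh = np.asarray(mean_lh, dtype=float)
    acr = np.asarray(mean_acr, dtype=float)
    if (lh <= 0).any() or (acr <= 0).any():
        raise ValueError("group means must be positive (floor first)")
    with np.errstate(divide="ignore"):
        fold = np.where(lh >= acr, lh / acr, -acr / lh)
    if fold.ndim == 0:
        return float(fold)
    return fold


@dataclass
class DifferentialResult:
    """Per-probe fold table plus the accounting block."""

    records: pd.DataFrame  # index probe_id: mean_ACR, mean_LH, fold, selected
    accounting: dict  # {total, excluded, kept, selected}


def select_differential(
    records: pd.DataFrame, threshold: float = DEFAULT_FOLD_THRESHOLD
) -> tuple[pd.DataFrame, dict]:
    """Mark records with |fold| >= threshold (inclusive) as selected.

    Returns the records with a ``selected`` column plus tallies
    ``{selected, up, down}``.
    """
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    fold = records["fold"].to_numpy(dtype=float)
    if (np.abs(fold) < 1).any():
        raise ValueError("fold magnitudes < 1 found; records must come from "
                         "fold_difference")
    out = records.copy()
    out["selected"] = np.abs(fold) >= threshold
    sel = out.loc[out["selected"], "fold"]
    tallies = {
        "selected": int(out["selected"].sum()),
        "up": int((sel > 0).sum()),
        "down": int((sel < 0).sum()),
    }
    return out, tallies


def differential_table(
    matrix: ExpressionMatrix,
    nu: float,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    baseline_group: str = "ACR",
    test_group: str = "LH",
) -> DifferentialResult:
    """Full filter -> floor -> fold -> select pass over a matrix.

    The accounting block always satisfies ``total = kept + excluded``.
    """
    kept, excluded = filter_noninformative(matrix, nu)
    floored = floor_to_noise(kept, nu)
    mean_acr = floored.group_means(baseline_group)
    mean_lh = floored.group_means(test_group)
    fold = fold_difference(mean_lh.to_numpy(), mean_acr.to_numpy())
    records = pd.DataFrame(
        {
            "mean_ACR": mean_acr,
            "mean_LH": mean_lh,
            "fold": fold,
        },
        index=floored.probe_ids,
    )
    records, tallies = select_differential(records, threshold)
    accounting = {
        "total": matrix.n_probes,
        "excluded": len(excluded),
        "kept": kept.n_probes,
        **tallies,
    }
    assert accounting["total"] == accounting["kept"] + accounting["excluded"]
    return DifferentialResult(records=records, accounting=accounting)
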