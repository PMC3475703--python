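"""Parent miRNA family grouping and per-family summaries.

Probes on a multi-species chip carry miRBase-style names such as
``hsa-miR-200b-3p`` or ``mmu-let-7f-2``. The parent family is obtained by
stripping, case-insensitively: the species prefix, the ``-3p``/``-5p`` arm
suffix or a trailing ``*``, a duplicate-locus numeric suffix, and the
trailing lettered variant — so both examples above group under ``miR-200``
and ``let-7`` regardless of species. Selected probes are then summarized per
family: members, up/down counts, sign concordance, and the extreme
(largest-magnitude) signed fold.

Name-based grouping keeps e.g. miR-141 and miR-429 as their own families;
the broader seed-based family (miR-200a/b/c with miR-141/miR-429) can be
imposed with an explicit ``family_map`` override, never inferred.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "parse_parent_family",
    "summarize_families",
    "plot_family_bars",
    "UNKNOWN_FAMILY",
]

UNKNOWN_FAMILY = "UNKNOWN"

_NAME_RE = re.compile(
    r"""^
    (?:[a-z]{3,4}-)?          # optional species prefix, e.g. hsa- / mml-
    (?P<stem>mir|let)-(?P<num>\d+)
    (?P<letters>[a-z]*)       # lettered variant(s): a, b, ...
    (?:-\d+)?                 # duplicate-locus suffix: -1, -2
    (?:-[35]p)?               # arm
    \*?                       # legacy star strand
    $""",
    re.IGNORECASE | re.VERBOSE,
)


def parse_parent_family(probe_id: str) -> str:
    """Parent family of a miRBase-style identifier.

    >>> parse_parent_family("hsa-miR-200b-3p")
    'miR-200'
    >>> parse_parent_family("mmu-let-7f-2")
    'let-7'

    Unparseable identifiers map to ``"UNKNOWN"``.
    """
    if not isinstance(probe_id, str) or not probe_id.strip():
        raise ValueError("probe id must be a non-empty string")
    m = _NAME_RE.match(probe_id.strip())
    if not m:
        return UNKNOWN_FAMILY
    stem = "let" if m.group("stem").lower() == "let" else "miR"
    return f"{stem}-{m.group('num')}"


def _apply_family_map(
    probe_id: str, parsed: str, family_map: dict[str, str] | None
) -> str:
    if not family_map:
        return parsed
    if probe_id in family_map:
        return family_map[probe_id]
    if parsed in family_map:
        return family_map[parsed]
    return parsed


def summarize_families(
    records: pd.DataFrame,
    family_map: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-family summary of selected differential records.

    Parameters
    ----------
    records
        DataFrame with a probe-id index (or ``probe_id`` column) and a
        ``fold`` column of signed folds with magnitude >= 1.
    family_map
        Optional override mapping (probe id or parsed family name ->
        family), e.g. to impose seed-based families.

    Returns a DataFrame with one row per family — columns ``family``,
    ``members`` (probe-id list), ``n_members``, ``n_up``, ``n_down``,
    ``concordant``, ``extreme_fold`` and ``mean_fold`` — ordered by member
    count descending, ties broken lexicographically by family name.

    Member counts are per probe (per-species entries), which is how one
    family can have dozens of members on a cross-species chip. On a
    magnitude tie the extreme fold is reported with positive sign.
    """
    df = records.copy()
    if "probe_id" not in df.columns:
        df = df.reset_index().rename(columns={df.index.name or "index": "probe_id"})
    folds = df["fold"].to_numpy(dtype=float)
    if (np.abs(folds) < 1).any():
        bad = df.loc[np.abs(folds) < 1, "probe_id"].tolist()
        raise ValueError(
            f"fold magnitude < 1 for {bad[:5]}; records must come from the "
            "differential stage"
        )
    if isinstance(family_map, pd.Series):
        family_map = family_map.to_dict()

    df["family"] = [
        _apply_family_map(pid, parse_parent_family(pid), family_map)
        for pid in df["probe_id"]
    ]

    rows = []
    for family, grp in df.groupby("family"):
        f = grp["fold"].to_numpy(dtype=float)
        n_up = int((f > 0).sum())
        n_down = int((f < 0).sum())
        # extreme fold: maximal |fold|; a magnitude tie resolves to positive
        mx = np.abs(f).max()
        tied = f[np.abs(f) == mx]
        extreme = float(tied.max())
        rows.append(
            {
                "family": family,
                "members": list(grp["probe_id"]),
                "n_members": len(grp),
                "n_up": n_up,
                "n_down": n_down,
                "concordant": n_up == 0 or n_down == 0,
                "extreme_fold": extreme,
                "mean_fold": float(f.mean()),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["n_members", "family"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def plot_family_bars(summaries: pd.DataFrame, path: str | Path) -> Path:
    """Stacked bar chart of per-family up/down member counts.

    Down-regulated members are drawn in red below up-regulated members in
    green (the conventional coloring for this summary); each bar is
    annotated with the family's extreme fold. An empty summary produces a
    placeholder figure rather than an error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    if summaries is None or len(summaries) == 0:
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.text(0.5, 0.5, "no families selected", ha="center", va="center")
        ax.set_axis_off()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path

    x = np.arange(len(summaries))
    down = summaries["n_down"].to_numpy()
    up = summaries["n_up"].to_numpy()
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(summaries)), 5))
    ax.bar(x, down, color="firebrick", label="down-regulated")
    ax.bar(x, up, bottom=down, color="forestgreen", label="up-regulated")
    for xi, (d, u, ef) in enumerate(zip(down, up, summaries["extreme_fold"])):
        ax.text(xi, d + u + 0.3, f"{ef:+.2f}", rotation=90,
                ha="center", va="bottom", fontsize=7)
    ax.set_xticks(x)
    ax.set_xticklabels(summaries["family"], rotation=90, fontsize=7)
    ax.set_ylabel("differentially regulated members")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
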