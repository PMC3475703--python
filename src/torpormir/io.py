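"""Table readers/writers shared by the CLI and pipeline.

Canonical on-disk dialect is TSV with a header row (UTF-8); comma-separated
files are accepted on read via delimiter sniffing. An expression matrix is a
TSV whose first column is ``probe_id`` followed by one column per sample,
with a companion sample sheet (``sample_id``, ``group``). Write-then-read
round-trips preserve values to full precision and row ordering.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "read_table",
    "write_table",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_family_map",
    "write_json",
    "read_json",
    "file_sha256",
]


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Delimited table with header; tab or comma, sniffed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed table {path}: {err}") from err


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_expression_tsv(
    matrix_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Expression matrix + sample sheet, with validation.

    Errors name the offending probe or sample: duplicated probe rows,
    samples missing from either file, missing group labels.
    """
    m = read_table(matrix_path)
    first = m.columns[0]
    dupes = m[first][m[first].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicated probe row(s) in {matrix_path}: {dupes[:5]}")
    values = m.set_index(first)
    values.index.name = "probe_id"
    values = values.astype(float)

    s = read_table(samples_path)
    needed = {"sample_id", "group"}
    missing_cols = needed - set(s.columns)
    if missing_cols:
        raise ValueError(
            f"sample sheet {samples_path} missing column(s) {sorted(missing_cols)}"
        )
    if s["group"].isna().any():
        bad = s.loc[s["group"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing group label for sample(s) {bad}")
    groups = pd.Series(s["group"].to_numpy(), index=s["sample_id"], name="group")
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_tsv(
    matrix: ExpressionMatrix, matrix_path: str | Path, samples_path: str | Path
) -> None:
    write_table(matrix.values.reset_index(), matrix_path)
    sheet = matrix.groups.rename_axis("sample_id").reset_index()
    write_table(sheet, samples_path)


def read_family_map(path: str | Path) -> dict[str, str]:
    """Two-column (probe-or-name -> family) override table."""
    df = read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"family map {path} needs two columns (name, family)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=str))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
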