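"""Canonical miRNA seed-match target-site scanner.

Finds candidate target sites by strict Watson-Crick complementarity to the
miRNA seed (positions 2-7 of the mature sequence) and classifies each site
into the canonical classes:

========  =======================================================
6mer      target matches the reverse complement of positions 2-7
7mer-m8   6mer plus a match to position 8 (5' of the core on the target)
7mer-A1   6mer plus an adenosine opposite position 1 (3' of the core)
8mer      both extensions
========  =======================================================

Coordinates are 0-based half-open on the provided target strand; DNA and RNA
are accepted interchangeably (T is read as U); every occurrence is reported,
including overlaps, each at its maximal class. G:U wobble pairs are not
counted as matches by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureMirna",
    "SeedMatch",
    "find_seed_matches",
    "scan_reporter_inserts",
    "read_fasta",
    "reporter_inserts_path",
    "MATCH_TYPES",
]

MATCH_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_STRINGENCY = {t: i for i, t in enumerate(MATCH_TYPES)}

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_WOBBLE_PARTNERS = {"G": {"C", "U"}, "U": {"A", "G"}, "A": {"U"}, "C": {"G"}}


def _normalize_rna(seq: str, what: str) -> str:
    out = seq.strip().upper().replace("T", "U")
    for ch in out:
        if ch not in "ACGU":
            raise ValueError(f"invalid character {ch!r} in {what} sequence")
    return out


@dataclass(frozen=True)
class MatureMirna:
    """Mature miRNA sequence, RNA alphabet, 5'->3'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence, self.id))
        if len(self.sequence) < 15:
            raise ValueError(
                f"mature miRNA {self.id!r} shorter than 15 nt "
                f"({len(self.sequence)})"
            )


@dataclass(frozen=True)
class SeedMatch:
    """One candidate site: 0-based half-open interval on the target strand."""

    mirna_id: str
    target_id: str
    start: int
    end: int
    match_type: str
    matched_subsequence: str


def _pairs(mir_base: str, target_base: str, wobble: bool) -> bool:
    """True when the target base can pair the miRNA base (antiparallel)."""
    if target_base == _COMPLEMENT[mir_base]:
        return True
    return wobble and target_base in _WOBBLE_PARTNERS.get(mir_base, ())


def find_seed_matches(
    mirna: MatureMirna,
    target_seq: str,
    target_id: str = "target",
    wobble: bool = False,
) -> list[SeedMatch]:
    """All canonical seed sites of ``mirna`` in ``target_seq``.

    The target is scanned 5'->3' for stretches pairing miRNA positions 2-7;
    because the duplex is antiparallel, position 8 pairs the base immediately
    5' of the core on the target and position 1 sits immediately 3' of it.
    Each occurrence is classified by its maximal type.
    """
    t = _normalize_rna(target_seq, target_id)
    if len(t) < 6:
        raise ValueError("target must be at least 6 nt")
    m = mirna.sequence
    seed = m[1:7]  # positions 2-7, 5'->3'
    matches: list[SeedMatch] = []
    for i in range(len(t) - 5):
        window = t[i:i + 6]
        # window 5'->3' pairs seed 3'->5': window[k] vs seed[5-k]
        if not all(_pairs(seed[5 - k], window[k], wobble) for k in range(6)):
            continue
        has_m8 = i >= 1 and _pairs(m[7], t[i - 1], wobble)
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            mtype, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            mtype, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            mtype, start, end = "7mer-A1", i, i + 7
        else:
            mtype, start, end = "6mer", i, i + 6
        matches.append(
            SeedMatch(
                mirna_id=mirna.id,
                target_id=target_id,
                start=start,
                end=end,
                match_type=mtype,
                matched_subsequence=t[start:end],
            )
        )
    return matches


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file; duplicate ids are rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sequence id(s) in {path}: {sorted(dupes)}")
    return [(r.id, str(r.seq)) for r in records]


def reporter_inserts_path() -> Path:
    """Bundled FASTA of the ULM reporter-construct insert sequences."""
    return Path(__file__).parent / "data" / "reporter_inserts.fasta"


def scan_reporter_inserts(
    mirnas: str | Path | list[tuple[str, str]],
    inserts: str | Path | list[tuple[str, str]] | None = None,
    min_class: str = "6mer",
    wobble: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every (miRNA, insert) pair for seed sites.

    ``mirnas``/``inserts`` are FASTA paths or (id, sequence) lists; when
    ``inserts`` is omitted the bundled reporter-insert fixture is used.
    ``min_class`` drops sites below the given stringency (6mer < 7mer-A1 <
    7mer-m8 < 8mer ordering on specificity).

    Returns (site table, per-pair summary with ``n_sites`` and ``any_site``).
    """
    if min_class not in _STRINGENCY:
        raise ValueError(f"unknown match class {min_class!r}; use one of {MATCH_TYPES}")
    if not isinstance(mirnas, list):
        mirnas = read_fasta(mirnas)
    if inserts is None:
        inserts = reporter_inserts_path()
    if not isinstance(inserts, list):
        inserts = read_fasta(inserts)
    if not mirnas or not inserts:
        raise ValueError("both miRNA and insert sets must be non-empty")

    threshold = _STRINGENCY[min_class]
    site_rows, summary_rows = [], []
    for mid, mseq in mirnas:
        mir = MatureMirna(id=mid, sequence=mseq)
        for tid, tseq in inserts:
            sites = [
                s
                for s in find_seed_matches(mir, tseq, target_id=tid, wobble=wobble)
                if _STRINGENCY[s.match_type] >= threshold
            ]
            for s in sites:
                site_rows.append(
                    {
                        "mirna_id": s.mirna_id,
                        "target_id": s.target_id,
                        "start": s.start,
                        "end": s.end,
                        "match_type": s.match_type,
                        "matched_subsequence": s.matched_subsequence,
                    }
                )
            summary_rows.append(
                {
                    "mirna_id": mid,
                    "target_id": tid,
                    "n_sites": len(sites),
                    "any_site": bool(sites),
                }
            )
    cols = ["mirna_id", "target_id", "start", "end", "match_type",
            "matched_subsequence"]
    sites_df = pd.DataFrame(site_rows, columns=cols)
    return sites_df, pd.DataFrame(summary_rows)
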