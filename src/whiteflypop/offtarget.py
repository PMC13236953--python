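"""Off-target screening of dsRNA candidates by exact 21-mer matching.

Plant-expressed dsRNAs are diced into ~21-nt siRNAs, so an exact 21-nt
identity between a dsRNA and a non-target transcript or genome is the
canonical red flag for unintended silencing.  The screen decomposes each
candidate dsRNA into all overlapping 21-mers (1-nt sliding window) and
searches every reference sequence on both strands for exact occurrences
(zero mismatches).  Mismatch-tolerant search is intentionally out of
scope; the ``max_mismatches`` flag exists only to make the contract
explicit.

Coordinates are 0-based half-open internally and 1-based inclusive in
reports; a reverse-strand hit is reported at the forward-strand coordinate
of the matched reference window.  Windows containing ``N`` never match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .exceptions import AlphabetError, DomainError

__all__ = [
    "DsRNARecord",
    "Kmer",
    "MatchReport",
    "kmerize",
    "reverse_complement",
    "screen",
    "read_fasta",
    "write_fasta",
]

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
HIT_COLUMNS = ("dsrna_id", "ref_id", "kmer", "position", "strand")


@dataclass(frozen=True)
class DsRNARecord:
    """A candidate dsRNA sequence; uppercased and alphabet-checked on ingest."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise AlphabetError(f"{self.id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Kmer:
    """One window of a dsRNA: offset (0-based), sequence, and matchability.

    Windows containing ``N`` are emitted but flagged non-matchable.
    """

    offset: int
    sequence: str
    matchable: bool


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def kmerize(sequence: str, k: int = 21, step: int = 1) -> list[Kmer]:
    """All ``k``-mers of a sequence at the given step (1-nt sliding window).

    A sequence shorter than ``k`` yields an empty list with a warning.
    """
    if k < 1 or step < 1:
        raise DomainError("k and step must be positive")
    seq = sequence.upper()
    if len(seq) < k:
        warnings.warn(
            f"sequence of length {len(seq)} shorter than k={k}; no k-mers emitted",
            stacklevel=2,
        )
        return []
    return [
        Kmer(offset=i, sequence=seq[i : i + k], matchable="N" not in seq[i : i + k])
        for i in range(0, len(seq) - k + 1, step)
    ]


@dataclass(frozen=True)
class MatchReport:
    """Exact-match hits plus per-(dsRNA, reference) totals.

    ``hits`` has one row per (dsRNA, reference, k-mer, position, strand)
    with 1-based positions; ``totals`` lists every (dsRNA, reference) pair
    in the screen, including zero-match pairs.
    """

    hits: pd.DataFrame
    totals: pd.DataFrame

    @property
    def n_matches(self) -> int:
        return len(self.hits)

    def total(self, dsrna_id: str, ref_id: str) -> int:
        sel = self.totals[
            (self.totals["dsrna_id"] == dsrna_id) & (self.totals["ref_id"] == ref_id)
        ]
        if sel.empty:
            raise KeyError(f"({dsrna_id}, {ref_id}) not in this screen")
        return int(sel["n_matches"].iloc[0])

    def write(self, outdir: str | Path) -> None:
        """Write ``hits.tsv`` and ``summary.tsv`` under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
        self.totals.to_csv(outdir / "summary.tsv", sep="\t", index=False)


def _as_records(
    sequences: Mapping[str, str] | Iterable[DsRNARecord] | Iterable[tuple[str, str]],
) -> list[DsRNARecord]:
    if isinstance(sequences, Mapping):
        return [DsRNARecord(sid, seq) for sid, seq in sequences.items()]
    out = []
    for item in sequences:
        if isinstance(item, DsRNARecord):
            out.append(item)
        else:
            sid, seq = item
            out.append(DsRNARecord(sid, seq))
    return out


def screen(
    dsrnas: Mapping[str, str] | Iterable[DsRNARecord],
    references: Mapping[str, str] | Iterable[tuple[str, str]],
    k: int = 21,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> MatchReport:
    """Exact k-mer screen of dsRNA candidates against reference panels.

    Every matchable k-mer of every dsRNA is looked up in each reference on
    the forward strand and (when ``both_strands``) the reverse strand, by
    sliding a window over the reference and testing membership in a hash
    of the dsRNA k-mers.  A k-mer occurring at several offsets of the same
    dsRNA is counted once per reference occurrence; overlapping reference
    occurrences are each counted.
    """
    if max_mismatches != 0:
        raise NotImplementedError("only exact matching (0 mismatches) is supported")
    ds_records = _as_records(dsrnas)
    ref_records = _as_records(references)
    if not ref_records:
        warnings.warn("empty reference panel; report is empty", stacklevel=2)

    # hash of dsRNA k-mers; for the reverse strand we store the reverse
    # complement so reference windows can be tested directly
    forward: dict[str, set[str]] = {}
    backward: dict[str, set[str]] = {}
    for rec in ds_records:
        for km in kmerize(rec.sequence, k=k):
            if not km.matchable:
                continue
            forward.setdefault(km.sequence, set()).add(rec.id)
            if both_strands:
                backward.setdefault(reverse_complement(km.sequence), set()).add(rec.id)

    rows: list[tuple[str, str, str, int, str]] = []
    for ref in ref_records:
        seq = ref.sequence
        for pos in range(len(seq) - k + 1):
            window = seq[pos : pos + k]
            ids = forward.get(window)
            if ids:
                rows.extend((d, ref.id, window, pos + 1, "+") for d in ids)
            ids = backward.get(window)
            if ids:
                rows.extend(
                    (d, ref.id, reverse_complement(window), pos + 1, "-") for d in ids
                )
    hits = pd.DataFrame(rows, columns=list(HIT_COLUMNS)).sort_values(
        ["dsrna_id", "ref_id", "position", "strand"], ignore_index=True
    )
    counts = hits.groupby(["dsrna_id", "ref_id"]).size() if rows else {}
    totals = pd.DataFrame(
        [
            {
                "dsrna_id": d.id,
                "ref_id": r.id,
                "n_matches": int(counts.get((d.id, r.id), 0)) if rows else 0,
            }
            for d in ds_records
            for r in ref_records
        ],
        columns=["dsrna_id", "ref_id", "n_matches"],
    )
    return MatchReport(hits=hits, totals=totals)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    """Write an id -> sequence mapping as plain FASTA."""
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
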