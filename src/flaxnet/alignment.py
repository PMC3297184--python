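"""Aligned-sequence input/output, sample grouping, and region annotation.

Conventions shared by every downstream module:

* Alignment coordinates are **1-based, inclusive**, on the alignment
  columns (so a reported site position can be compared directly with a
  published alignment position).
* Nucleotides are case-insensitive.  ``-`` is an alignment gap.  Any
  other symbol outside ``{A, C, G, T, -}`` is normalised to ``N`` and
  treated as missing data; how missing columns enter each statistic is
  decided per statistic (see :mod:`flaxnet.popgen`).
* The alignment length ``L`` is always taken from the input alignment,
  never hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_SYMBOLS = frozenset("ACGT-")
MISSING = "N"
UNASSIGNED = "unassigned"


class AlignmentError(ValueError):
    """Raised when sequences do not form a rectangular alignment."""


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


def _normalise(seq: str) -> str:
    up = seq.upper()
    return "".join(c if c in VALID_SYMBOLS else MISSING for c in up)


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment with sample grouping.

    Attributes
    ----------
    sample_ids:
        Unique, non-empty identifiers, one per row.
    seqs:
        ``(n, L)`` array of single-character nucleotide/gap symbols.
    groups:
        Mapping ``sample_id -> group label``.  Samples absent from the
        mapping are assigned the group ``"unassigned"``.
    """

    sample_ids: list[str]
    seqs: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise InputError("alignment has no sequences")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise InputError(f"duplicate sample ids: {dupes}")
        if any(not s for s in self.sample_ids):
            raise InputError("empty sample id")
        self.seqs = np.asarray(self.seqs, dtype="<U1")
        if self.seqs.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-dimensional")
        if self.seqs.shape[0] != len(self.sample_ids):
            raise AlignmentError("row count does not match sample id count")
        if self.L < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid in self.sample_ids:
            if sid not in self.groups:
                logger.warning("sample %s has no group entry; using %r", sid, UNASSIGNED)
                self.groups[sid] = UNASSIGNED

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-occurrence order."""
        seen: list[str] = []
        for sid in self.sample_ids:
            g = self.groups[sid]
            if g not in seen:
                seen.append(g)
        return seen

    def row(self, sample_id: str) -> np.ndarray:
        return self.seqs[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: list[str]) -> "Alignment":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return Alignment(
            sample_ids=list(sample_ids),
            seqs=self.seqs[idx].copy(),
            groups={s: self.groups[s] for s in sample_ids},
        )

    def by_group(self, group: str) -> "Alignment":
        members = [s for s in self.sample_ids if self.groups[s] == group]
        if not members:
            raise InputError(f"unknown or empty group: {group!r}")
        return self.subset(members)

    def columns(self, start: int, end: int) -> np.ndarray:
        """Columns ``start..end`` (1-based inclusive) as an ``(n, w)`` slice."""
        if not (1 <= start <= end <= self.L):
            raise InputError(
                f"region {start}..{end} outside alignment of length {self.L}"
            )
        return self.seqs[:, start - 1 : end]

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=sid, description="")
            for sid, row in zip(self.sample_ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_groups_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids,
             "group": [self.groups[s] for s in self.sample_ids]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_strings(
        cls,
        sample_ids: list[str],
        sequences: list[str],
        groups: dict[str, str] | None = None,
    ) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        mat = np.array([list(_normalise(s)) for s in sequences], dtype="<U1")
        return cls(sample_ids=list(sample_ids), seqs=mat, groups=dict(groups or {}))


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (``sample_id``, ``group``) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise InputError(f"groups table lacks column(s): {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise InputError("duplicate sample_id in groups table")
    return dict(zip(df["sample_id"], df["group"]))


def read_alignment(fasta_path: str | Path, groups_path: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA plus an optional sample-to-group TSV.

    All sequences must have identical length.  Samples missing from the
    group table are assigned to ``"unassigned"`` with a logged warning.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"no such file: {fasta_path}")
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise InputError(f"empty FASTA: {fasta_path}")
    groups = read_groups(groups_path) if groups_path is not None else {}
    return Alignment.from_strings(ids, seqs, groups)


@dataclass
class RegionAnnotation:
    """Ordered, non-overlapping named intervals over alignment columns.

    Intervals are 1-based inclusive.  Columns not covered by any named
    interval fall into an implicit ``other`` region.
    """

    regions: list[tuple[str, int, int]]
    L: int

    def __post_init__(self) -> None:
        for name, start, end in self.regions:
            if not (1 <= start <= end <= self.L):
                raise InputError(
                    f"region {name!r} {start}..{end} outside 1..{self.L}"
                )
        ordered = sorted(self.regions, key=lambda r: r[1])
        for (n1, _, e1), (n2, s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise InputError(f"regions {n1!r} and {n2!r} overlap")
        self.regions = ordered

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.regions]

    def interval(self, name: str) -> tuple[int, int]:
        for rname, start, end in self.regions:
            if rname == name:
                return start, end
        raise InputError(f"unknown region: {name!r}")

    def with_other(self) -> list[tuple[str, int, int]]:
        """Named regions plus implicit ``other`` intervals for uncovered columns."""
        out: list[tuple[str, int, int]] = []
        cursor = 1
        for name, start, end in self.regions:
            if start > cursor:
                out.append(("other", cursor, start - 1))
            out.append((name, start, end))
            cursor = end + 1
        if cursor <= self.L:
            out.append(("other", cursor, self.L))
        return out

    @classmethod
    def whole(cls, L: int) -> "RegionAnnotation":
        return cls(regions=[("all", 1, L)], L=L)


def read_regions(path: str | Path, L: int) -> RegionAnnotation:
    """Read a BED-like region TSV (columns ``name``, ``start``, ``end``).

    Coordinates are interpreted in the package-wide 1-based inclusive
    dialect.  An empty table yields a single region ``all`` spanning the
    whole alignment.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "start", "end"} - set(df.columns)
    if missing:
        raise InputError(f"region table lacks column(s): {sorted(missing)}")
    if df.empty:
        return RegionAnnotation.whole(L)
    regions = [
        (str(r["name"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()
    ]
    return RegionAnnotation(regions=regions, L=L)
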