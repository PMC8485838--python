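"""Reading, concatenating and column-filtering aligned cpDNA matrices.

The downstream statistics (haplotype collapsing, diversity, AMOVA,
neutrality tests) all assume a *complete* matrix: every retained column
carries an unambiguous base in every sequence.  This module enforces that
policy ("complete deletion"): any column containing a gap, ``N``, ``?`` or
an IUPAC ambiguity code in any sequence is removed before analysis, which
makes haplotype identity and site counts well defined.

Column coordinates in all reports are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Bases accepted in input alignments. ``U`` is mapped to ``T`` on read.
UNAMBIGUOUS = frozenset("ACGT")
AMBIGUITY = frozenset("RYSWKMBDHVN")
GAPLIKE = frozenset("-?")
LEGAL = UNAMBIGUOUS | AMBIGUITY | GAPLIKE


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments or metadata."""


@dataclass
class Alignment:
    """An equal-length, sample-labelled nucleotide matrix.

    Parameters
    ----------
    sample_ids:
        Unique sample identifiers, preserved verbatim from the input.
    sequences:
        Upper-case strings over ``{A,C,G,T,-,N,?}`` plus IUPAC ambiguity
        codes, all of identical length.
    partitions:
        Optional ``(region name, (start, end))`` spans, 1-based inclusive,
        recording the original cpDNA regions of a concatenated matrix.
    """

    sample_ids: list[str]
    sequences: list[str]
    partitions: list[tuple[str, tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentError("zero-length alignment")
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in number")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        bad = set("".join(self.sequences)) - LEGAL
        if bad:
            raise AlignmentError(f"illegal characters in sequences: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as an ``(n_samples, length)`` character array."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    @classmethod
    def from_matrix(
        cls,
        sample_ids: Sequence[str],
        matrix: np.ndarray,
        partitions: list[tuple[str, tuple[int, int]]] | None = None,
    ) -> "Alignment":
        seqs = ["".join(row) for row in matrix]
        return cls(list(sample_ids), seqs, partitions)

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        """Row subset preserving the order given in *sample_ids*."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        ids = list(sample_ids)
        return Alignment(ids, [self.sequences[index[s]] for s in ids], self.partitions)


@dataclass
class SiteClasses:
    """Classification of complete columns, 1-based, in original coordinates.

    ``parsimony_informative`` ⊆ ``polymorphic`` ⊆ ``complete_columns``;
    ``singleton`` is the polymorphic sites that are not informative.
    """

    complete_columns: list[int]
    polymorphic: list[int]
    parsimony_informative: list[int]
    singleton: list[int] = field(init=False)
    #: original 1-based column -> 1-based column in the filtered matrix
    column_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        informative = set(self.parsimony_informative)
        self.singleton = [c for c in self.polymorphic if c not in informative]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        poly, info = set(self.polymorphic), set(self.parsimony_informative)
        for col in self.complete_columns:
            if col in info:
                klass = "parsimony_informative"
            elif col in poly:
                klass = "singleton"
            else:
                klass = "monomorphic"
            rows.append((col, self.column_map.get(col), klass))
        return pd.DataFrame(rows, columns=["column", "filtered_column", "class"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SampleMetadata:
    sample_id: str
    population: str
    lineage: str
    latitude: float | None = None
    longitude: float | None = None


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path) -> Alignment:
    """Read a multi-record aligned FASTA file.

    Sequences are upper-cased and ``U`` is mapped to ``T``.  Raises
    :class:`AlignmentError` on empty files, duplicate ids, ragged lengths
    or characters outside the nucleotide/ambiguity/gap alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [_normalise(str(r.seq)) for r in records]
    aln = Alignment(ids, seqs)
    logger.info("read %d sequences of %d bp from %s", aln.n_samples, aln.length, path)
    return aln


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(alignments: Sequence[Alignment], names: Sequence[str] | None = None) -> Alignment:
    """Concatenate per-region alignments sharing one sample-id set.

    The output records each region as a partition with its 1-based
    inclusive column span; regions are pasted in the order given, with the
    per-sample order of regions identical for every sample.
    """
    if not alignments:
        raise AlignmentError("empty input list")
    if names is None:
        names = [f"region{i + 1}" for i in range(len(alignments))]
    ref = set(alignments[0].sample_ids)
    for a in alignments[1:]:
        if set(a.sample_ids) != ref:
            raise AlignmentError("alignments do not share an identical sample-id set")
    order = alignments[0].sample_ids
    pieces = [a.subset(order).sequences for a in alignments]
    seqs = ["".join(parts) for parts in zip(*pieces)]
    partitions = []
    start = 1
    for name, a in zip(names, alignments):
        partitions.append((name, (start, start + a.length - 1)))
        start += a.length
    return Alignment(list(order), seqs, partitions)


def filter_complete_columns(aln: Alignment) -> tuple[Alignment, SiteClasses]:
    """Apply complete deletion and classify the retained columns.

    A column is kept only when every sequence carries an unambiguous base
    (``A/C/G/T``) at it.  Site classes are computed on the retained
    columns: *polymorphic* columns show >= 2 bases, *parsimony informative*
    columns show >= 2 bases each carried by >= 2 sequences.
    """
    mat = aln.to_matrix()
    ok = np.isin(mat, list(UNAMBIGUOUS)).all(axis=0)
    if not ok.any():
        raise AlignmentError("no complete columns remain after filtering")
    kept = np.flatnonzero(ok)
    n_removed = aln.length - kept.size
    if n_removed:
        logger.info("complete-deletion removed %d of %d columns", n_removed, aln.length)
    complete = (kept + 1).tolist()
    column_map = {int(orig + 1): j + 1 for j, orig in enumerate(kept)}

    polymorphic: list[int] = []
    informative: list[int] = []
    sub = mat[:, kept]
    for j, orig in enumerate(kept):
        _, counts = np.unique(sub[:, j], return_counts=True)
        if counts.size >= 2:
            polymorphic.append(int(orig + 1))
            if (counts >= 2).sum() >= 2:
                informative.append(int(orig + 1))
    classes = SiteClasses(complete, polymorphic, informative, column_map=column_map)
    filtered = Alignment.from_matrix(aln.sample_ids, sub, aln.partitions)
    return filtered, classes


REQUIRED_COLUMNS = ("sample_id", "population", "lineage")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample-metadata TSV.

    Required columns: ``sample_id``, ``population``, ``lineage``; optional
    ``lat`` and ``lon`` in decimal degrees.  Every population code must map
    to exactly one lineage and coordinates must lie in valid ranges.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"metadata is missing required columns: {missing}")
    multi = df.groupby("population")["lineage"].nunique()
    bad = multi[multi > 1].index.tolist()
    if bad:
        raise AlignmentError(f"populations mapped to more than one lineage: {bad}")
    if df["sample_id"].duplicated().any():
        raise AlignmentError("duplicate sample ids in metadata")
    out = []
    for _, row in df.iterrows():
        lat = float(row["lat"]) if "lat" in df.columns and pd.notna(row.get("lat")) else None
        lon = float(row["lon"]) if "lon" in df.columns and pd.notna(row.get("lon")) else None
        if lat is not None and not -90.0 <= lat <= 90.0:
            raise AlignmentError(f"latitude out of range for {row['sample_id']}: {lat}")
        if lon is not None and not -180.0 <= lon <= 180.0:
            raise AlignmentError(f"longitude out of range for {row['sample_id']}: {lon}")
        out.append(
            SampleMetadata(row["sample_id"], row["population"], row["lineage"], lat, lon)
        )
    return out


def metadata_index(meta: Sequence[SampleMetadata]) -> dict[str, SampleMetadata]:
    return {m.sample_id: m for m in meta}


def check_metadata_coverage(aln: Alignment, meta: Sequence[SampleMetadata]) -> list[str]:
    """Return metadata rows whose sample ids are absent from the alignment."""
    known = set(aln.sample_ids)
    index = metadata_index(meta)
    unresolved = [s for s in aln.sample_ids if s not in index]
    if unresolved:
        raise AlignmentError(f"alignment samples without metadata: {unresolved}")
    return [m.sample_id for m in meta if m.sample_id not in known]
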