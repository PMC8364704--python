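"""Sequence, label, property-scale and dataset-manifest I/O.

MoRF annotations travel with the sequence in a lowercase-FASTA dialect:
lowercase residues are MoRF residues, uppercase residues are non-MoRF,
and a record whose header carries a ``nolabel`` tag (and whose body is
all uppercase) has no label track at all.  A sidecar TSV
(``id<TAB>binary-string``) is accepted as an alternative label source.

Amino-acid property scales are read from AAindex1 flat files (H/D/I
records, two rows of ten values, ``//`` terminators).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "AnnotatedSequence",
    "PropertyScale",
    "DatasetManifest",
    "FormatError",
    "read_annotated_fasta",
    "write_annotated_fasta",
    "read_label_tsv",
    "apply_label_tsv",
    "parse_aaindex",
    "write_aaindex",
    "aggregate_manifests",
    "manifest_from_sequences",
    "manifest_to_json",
    "manifest_from_json",
]

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the two value rows in an AAindex1 ``I`` block.
AAINDEX_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Ambiguity / non-standard codes collapsed to 'X'; property lookup for
# 'X' falls back to the mean of the 20 scale values.
_NONSTANDARD = set("BZUOJX*")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein sequence with an optional per-residue binary MoRF track.

    ``residues`` is uppercase over the 20 standard letters plus ``X``;
    ``labels`` (when present) has one 0/1 entry per residue, 1 marking a
    MoRF residue.  Residue positions are 1-based throughout the package.
    """

    id: str
    residues: str
    labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        canonical = _canonicalize(self.residues)
        if canonical != self.residues:
            object.__setattr__(self, "residues", canonical)
        if self.labels is not None:
            labels = tuple(int(v) for v in self.labels)
            if len(labels) != len(self.residues):
                raise ValueError(
                    f"{self.id}: {len(labels)} labels for "
                    f"{len(self.residues)} residues"
                )
            if any(v not in (0, 1) for v in labels):
                raise ValueError(f"{self.id}: labels must be 0/1")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_morf(self) -> int:
        if self.labels is None:
            raise ValueError(f"{self.id}: no labels present")
        return sum(self.labels)


def _canonicalize(residues: str) -> str:
    out = []
    for ch in residues.upper():
        if ch in _NONSTANDARD:
            out.append("X")
        elif ch in STANDARD_AMINO_ACIDS:
            out.append(ch)
        else:
            raise FormatError(f"invalid residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class PropertyScale:
    """One amino-acid property scale: a real value per standard residue."""

    accession: str
    description: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(STANDARD_AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"{self.accession}: scale must cover exactly the 20 standard "
                f"amino acids (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / 20.0

    def value(self, residue: str) -> float:
        """Scale value for a residue; 'X' gets the scale mean."""
        if residue == "X":
            return self.mean
        return self.values[residue]


@dataclass(frozen=True)
class DatasetManifest:
    """Residue-level bookkeeping for one labeled sequence set."""

    name: str
    n_sequences: int
    n_morf_residues: int
    n_nonmorf_residues: int

    def __post_init__(self) -> None:
        for fname in ("n_sequences", "n_morf_residues", "n_nonmorf_residues"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{self.name}: {fname} must be >= 0")

    @property
    def n_total_residues(self) -> int:
        return self.n_morf_residues + self.n_nonmorf_residues


# ---------------------------------------------------------------------------
# annotated FASTA


def read_annotated_fasta(source: str | Path | IO[str]) -> list[AnnotatedSequence]:
    """Read the lowercase-MoRF FASTA dialect.

    Lowercase letters become label 1, uppercase label 0.  A record with no
    lowercase letters and a ``nolabel`` token in its header description has
    ``labels=None``; an all-uppercase record *without* the tag is read as
    all-non-MoRF.
    """
    handle, close = _as_text_handle(source, "r")
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    out: list[AnnotatedSequence] = []
    for rec in records:
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"record {rec.id!r}: empty sequence body")
        if not all(ch.isalpha() or ch == "*" for ch in raw):
            bad = next(ch for ch in raw if not (ch.isalpha() or ch == "*"))
            raise FormatError(
                f"record {rec.id!r}: non-letter character {bad!r} in sequence"
            )
        tags = rec.description.split()[1:]
        nolabel = "nolabel" in tags
        has_lower = any(ch.islower() for ch in raw)
        if nolabel and has_lower:
            raise FormatError(
                f"record {rec.id!r}: 'nolabel' header but lowercase residues"
            )
        labels = None if nolabel else tuple(1 if ch.islower() else 0 for ch in raw)
        out.append(AnnotatedSequence(rec.id, raw, labels))
    return out


def write_annotated_fasta(
    sequences: Iterable[AnnotatedSequence],
    dest: str | Path | IO[str],
    width: int = 60,
) -> None:
    """Write sequences in the lowercase-MoRF dialect (inverse of read)."""
    handle, close = _as_text_handle(dest, "w")
    try:
        for seq in sequences:
            if seq.labels is None:
                handle.write(f">{seq.id} nolabel\n")
                body = seq.residues
            else:
                handle.write(f">{seq.id}\n")
                body = "".join(
                    ch.lower() if lab else ch
                    for ch, lab in zip(seq.residues, seq.labels)
                )
            for i in range(0, len(body), width):
                handle.write(body[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def _as_text_handle(source, mode):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# sidecar labels


def read_label_tsv(source: str | Path | IO[str]) -> dict[str, tuple[int, ...]]:
    """Read ``id<TAB>binary-string`` sidecar labels."""
    handle, close = _as_text_handle(source, "r")
    try:
        out: dict[str, tuple[int, ...]] = {}
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"label TSV line {lineno}: expected 2 columns")
            sid, bits = parts
            if not set(bits) <= {"0", "1"}:
                raise FormatError(
                    f"label TSV line {lineno}: label string must be binary"
                )
            out[sid] = tuple(int(b) for b in bits)
        return out
    finally:
        if close:
            handle.close()


def apply_label_tsv(
    sequences: Sequence[AnnotatedSequence],
    labels: dict[str, tuple[int, ...]],
) -> list[AnnotatedSequence]:
    """Attach sidecar labels to sequences by id (lengths must match)."""
    out = []
    for seq in sequences:
        if seq.id in labels:
            out.append(AnnotatedSequence(seq.id, seq.residues, labels[seq.id]))
        else:
            out.append(seq)
    return out


# ---------------------------------------------------------------------------
# AAindex1


def parse_aaindex(source: str | Path | IO[str]) -> list[PropertyScale]:
    """Parse an AAindex1 flat file into property scales.

    Values in the ``I`` block are assigned in the canonical column order
    A R N D C Q E G H I / L K M F P S T W Y V.  An ``NA`` cell is an
    error naming the accession (scales with missing values are rejected,
    not imputed).
    """
    handle, close = _as_text_handle(source, "r")
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    scales: list[PropertyScale] = []
    for chunk in text.split("//"):
        if not chunk.strip():
            continue
        accession = ""
        description = ""
        numbers: list[float] = []
        in_values = False
        lines = chunk.splitlines()
        for line in lines:
            if line.startswith("H "):
                accession = line[2:].strip()
                in_values = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_values = False
            elif line.startswith("I "):
                in_values = True
            elif in_values and line.startswith(" "):
                for cell in line.split():
                    if cell.upper() == "NA":
                        raise FormatError(
                            f"scale {accession or '<unknown>'}: NA value cell"
                        )
                    try:
                        numbers.append(float(cell))
                    except ValueError as exc:
                        raise FormatError(
                            f"scale {accession or '<unknown>'}: "
                            f"bad value cell {cell!r}"
                        ) from exc
            elif in_values:
                in_values = False
        if not accession:
            raise FormatError("record without H (accession) line")
        if len(numbers) != 20:
            raise FormatError(
                f"scale {accession}: expected 20 values, got {len(numbers)} "
                "(truncated record?)"
            )
        values = dict(zip(AAINDEX_COLUMN_ORDER, numbers))
        scales.append(PropertyScale(accession, description, values))
    return scales


def write_aaindex(scales: Iterable[PropertyScale], dest: str | Path | IO[str]) -> None:
    """Write scales as a minimal AAindex1 flat file (inverse of parse)."""
    handle, close = _as_text_handle(dest, "w")
    try:
        for scale in scales:
            handle.write(f"H {scale.accession}\n")
            handle.write(f"D {scale.description}\n")
            handle.write(f"I    A/L     R/K     N/M     D/F     C/P     "
                         f"Q/S     E/T     G/W     H/Y     I/V\n")
            vals = [scale.values[aa] for aa in AAINDEX_COLUMN_ORDER]
            for row in (vals[:10], vals[10:]):
                handle.write(" " + " ".join(f"{v: .6f}" for v in row) + "\n")
            handle.write("//\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# manifests


def aggregate_manifests(
    parts: Sequence[DatasetManifest], name: str
) -> DatasetManifest:
    """Component-wise sum of manifests, e.g. pooling test sets into one."""
    if not parts:
        raise ValueError("aggregate_manifests: empty parts")
    return DatasetManifest(
        name=name,
        n_sequences=sum(p.n_sequences for p in parts),
        n_morf_residues=sum(p.n_morf_residues for p in parts),
        n_nonmorf_residues=sum(p.n_nonmorf_residues for p in parts),
    )


def manifest_from_sequences(
    sequences: Sequence[AnnotatedSequence], name: str
) -> DatasetManifest:
    """Tally a labeled sequence set into a manifest."""
    for seq in sequences:
        if seq.labels is None:
            raise ValueError(f"manifest_from_sequences: {seq.id} lacks labels")
    n_morf = sum(seq.n_morf for seq in sequences)
    n_total = sum(len(seq) for seq in sequences)
    return DatasetManifest(
        name=name,
        n_sequences=len(sequences),
        n_morf_residues=n_morf,
        n_nonmorf_residues=n_total - n_morf,
    )


def manifest_to_json(manifest: DatasetManifest) -> str:
    return json.dumps(
        {
            "name": manifest.name,
            "n_sequences": manifest.n_sequences,
            "n_morf_residues": manifest.n_morf_residues,
            "n_nonmorf_residues": manifest.n_nonmorf_residues,
            "n_total_residues": manifest.n_total_residues,
        },
        indent=2,
    )


def manifest_from_json(text: str) -> DatasetManifest:
    data = json.loads(text)
    m = DatasetManifest(
        name=data["name"],
        n_sequences=data["n_sequences"],
        n_morf_residues=data["n_morf_residues"],
        n_nonmorf_residues=data["n_nonmorf_residues"],
    )
    if "n_total_residues" in data and data["n_total_residues"] != m.n_total_residues:
        raise FormatError(
            f"{m.name}: stated total {data['n_total_residues']} != "
            f"{m.n_total_residues}"
        )
    return m
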