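"""Peptide-level sequence features of degrons.

A degron here is a short peptide (7-58 residues in the screens this package
models) appended to the C-terminus of a reporter protein, sufficient to target
the fusion for ubiquitin-proteasome degradation.  This module computes the
properties used to characterise such peptides — grand average of hydropathy
(GRAVY, Kyte-Doolittle by default) and the longest contiguous hydrophobic
stretch — and handles translation of random genomic inserts in the fusion
reading frame, terminated by the vector's three-frame stop cassette.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParamData import kd as _KD_VALUES

__all__ = [
    "STANDARD_AA",
    "DEFAULT_HYDROPHOBIC",
    "DEFAULT_VECTOR_TAIL",
    "AlphabetError",
    "ValidationError",
    "HydropathyScale",
    "KYTE_DOOLITTLE",
    "FragmentSource",
    "DegronRecord",
    "gravy",
    "max_hydrophobic_run",
    "translate_fusion",
    "read_library",
    "write_library",
    "load_tester_set",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues counted as hydrophobic when scanning for contiguous stretches:
#: positive Kyte-Doolittle hydropathy, minus glycine.  Configurable because
#: no single definition is canonical.
DEFAULT_HYDROPHOBIC = frozenset("ACFILMVW")

#: Vector sequence downstream of the insertion site.  Contains a stop codon in
#: each of the three frames (TAA at offsets 0, 1 and 2 relative to any insert
#: length), so translation of any insert is guaranteed to terminate.
DEFAULT_VECTOR_TAIL = "TAAATAAATAA"

_DNA_ALPHABET = frozenset("ACGT")


class AlphabetError(ValueError):
    """A sequence contains a character outside the permitted alphabet."""

    def __init__(self, char: str, position: int, kind: str = "residue"):
        self.char = char
        self.position = position
        super().__init__(
            f"unknown {kind} {char!r} at position {position} (0-based)"
        )


class ValidationError(ValueError):
    """Input records violate a structural contract (e.g. duplicate ids)."""


@dataclass(frozen=True)
class HydropathyScale:
    """Residue -> hydropathy map over the 20 standard amino acids."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        keys = frozenset(self.values)
        if keys != STANDARD_AA:
            missing = sorted(STANDARD_AA - keys)
            extra = sorted(keys - STANDARD_AA)
            raise ValidationError(
                f"hydropathy scale must cover exactly the 20 standard residues; "
                f"missing={missing} extra={extra}"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


#: Kyte & Doolittle hydropathy values (dimensionless, range [-4.5, 4.5]),
#: taken from Biopython.
KYTE_DOOLITTLE = HydropathyScale("kyte-doolittle", dict(_KD_VALUES))


def _check_peptide(peptide: str, allowed: frozenset = STANDARD_AA) -> None:
    for i, ch in enumerate(peptide):
        if ch not in allowed:
            raise AlphabetError(ch, i)


def gravy(peptide: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean scale value over all residues.

    Raises ``ValueError`` on an empty peptide and :class:`AlphabetError` on a
    residue absent from the scale.
    """
    if not peptide:
        raise ValueError("gravy is undefined for an empty peptide")
    total = 0.0
    for i, ch in enumerate(peptide):
        try:
            total += scale[ch]
        except KeyError:
            raise AlphabetError(ch, i) from None
    return total / len(peptide)


def max_hydrophobic_run(
    peptide: str, hydrophobic: frozenset = DEFAULT_HYDROPHOBIC
) -> int:
    """Length of the longest contiguous run of hydrophobic residues (0 if none)."""
    if not hydrophobic <= STANDARD_AA:
        raise ValidationError("hydrophobic set must be a subset of the standard alphabet")
    _check_peptide(peptide)
    best = 0
    for is_h, group in itertools.groupby(peptide, key=lambda ch: ch in hydrophobic):
        if is_h:
            best = max(best, sum(1 for _ in group))
    return best


def _has_three_frame_stops(tail: str) -> bool:
    stops = {"TAA", "TAG", "TGA"}
    for shift in range(3):
        codons = [tail[i : i + 3] for i in range(shift, len(tail) - 2, 3)]
        if not any(c in stops for c in codons):
            return False
    return True


def translate_fusion(
    insert_dna: str, vector_tail_dna: str = DEFAULT_VECTOR_TAIL
) -> str:
    """Translate an insert in the fusion reading frame (frame 0 of the insert).

    Translation starts at position 0 of ``insert_dna``, continues into
    ``vector_tail_dna`` and stops at (excluding) the first stop codon.  The
    vector tail must contain a stop codon in all three frames downstream of
    the insertion point, which guarantees termination for any insert length.
    """
    for name, seq in (("insert", insert_dna), ("vector tail", vector_tail_dna)):
        for i, ch in enumerate(seq):
            if ch not in _DNA_ALPHABET:
                raise AlphabetError(ch, i, kind=f"{name} nucleotide")
    if not _has_three_frame_stops(vector_tail_dna):
        raise ValidationError(
            "vector tail must contain a stop codon in all three frames"
        )
    fused = insert_dna + vector_tail_dna
    fused = fused[: len(fused) - len(fused) % 3]
    return str(Seq(fused).translate(to_stop=True))


@dataclass(frozen=True)
class FragmentSource:
    """Provenance of a simulated library insert on its source genome.

    Coordinates are 0-based half-open on the forward strand; ``reverse`` marks
    inserts cloned in reverse-complement orientation (blunt cloning is
    orientation-blind).  The fusion frame is always frame 0 of the insert.
    """

    start: int
    end: int
    reverse: bool
    frame: int = 0


@dataclass(frozen=True)
class DegronRecord:
    """One degron library member with its computed sequence features."""

    id: str
    peptide: str
    length: int
    gravy: float
    max_hydrophobic_run: int
    source: FragmentSource | None = field(default=None, compare=True)

    def __post_init__(self):
        _check_peptide(self.peptide)
        if self.length != len(self.peptide):
            raise ValidationError(
                f"{self.id}: length {self.length} != len(peptide) {len(self.peptide)}"
            )
        if self.max_hydrophobic_run > self.length:
            raise ValidationError(f"{self.id}: hydrophobic run exceeds length")

    @classmethod
    def from_peptide(
        cls,
        id: str,
        peptide: str,
        scale: HydropathyScale = KYTE_DOOLITTLE,
        hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
        source: FragmentSource | None = None,
    ) -> "DegronRecord":
        """Build a record computing all features from the peptide."""
        return cls(
            id=id,
            peptide=peptide,
            length=len(peptide),
            gravy=gravy(peptide, scale),
            max_hydrophobic_run=max_hydrophobic_run(peptide, hydrophobic),
            source=source,
        )


_TSV_COLUMNS = ["id", "peptide", "length", "gravy", "max_hydrophobic_run"]
_SOURCE_COLUMNS = ["fragment_start", "fragment_end", "reverse"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".faa"}:
        return "fasta"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise ValidationError(f"cannot infer library format from {path.name!r}")


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValidationError(f"duplicate degron ids: {dups}")


def read_library(
    path: str | Path,
    fmt: str | None = None,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
) -> list[DegronRecord]:
    """Read a degron library from FASTA (id + peptide) or TSV.

    Features are recomputed on read unless present as TSV columns.  Duplicate
    ids raise :class:`ValidationError`; malformed records raise a parse error
    naming the offending line.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records: list[DegronRecord] = []
    if fmt == "fasta":
        seqs = list(SeqIO.parse(str(path), "fasta"))
        _check_unique_ids([s.id for s in seqs])
        for s in seqs:
            records.append(
                DegronRecord.from_peptide(s.id, str(s.seq), scale, hydrophobic)
            )
    elif fmt == "tsv":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                dtype={"id": str, "peptide": str},
                float_precision="round_trip",
            )
        except pd.errors.ParserError as exc:
            raise ValidationError(f"malformed TSV {path.name}: {exc}") from exc
        for col in ("id", "peptide"):
            if col not in df.columns:
                raise ValidationError(f"{path.name}: missing required column {col!r}")
        _check_unique_ids(df["id"].tolist())
        has_features = all(c in df.columns for c in _TSV_COLUMNS)
        has_source = all(c in df.columns for c in _SOURCE_COLUMNS)
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            source = None
            if has_source and pd.notna(getattr(row, "fragment_start")):
                source = FragmentSource(
                    start=int(getattr(row, "fragment_start")),
                    end=int(getattr(row, "fragment_end")),
                    reverse=bool(getattr(row, "reverse")),
                )
            try:
                if has_features:
                    records.append(
                        DegronRecord(
                            id=row.id,
                            peptide=row.peptide,
                            length=int(row.length),
                            gravy=float(row.gravy),
                            max_hydrophobic_run=int(row.max_hydrophobic_run),
                            source=source,
                        )
                    )
                else:
                    records.append(
                        DegronRecord.from_peptide(
                            row.id, row.peptide, scale, hydrophobic, source=source
                        )
                    )
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path.name} line {lineno}: {exc}") from exc
    else:
        raise ValidationError(f"unsupported library format {fmt!r}")
    return records


def write_library(
    records: Iterable[DegronRecord], path: str | Path, fmt: str | None = None
) -> Path:
    """Write a degron library as FASTA or TSV (features and provenance kept in TSV)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = list(records)
    _check_unique_ids([r.id for r in records])
    if fmt == "fasta":
        SeqIO.write(
            (SeqRecord(Seq(r.peptide), id=r.id, description="") for r in records),
            str(path),
            "fasta",
        )
    elif fmt == "tsv":
        rows = []
        for r in records:
            row = {
                "id": r.id,
                "peptide": r.peptide,
                "length": r.length,
                # shortest round-trip float representation, so read(write(x)) == x
                "gravy": repr(float(r.gravy)),
                "max_hydrophobic_run": r.max_hydrophobic_run,
                "fragment_start": r.source.start if r.source else None,
                "fragment_end": r.source.end if r.source else None,
                "reverse": r.source.reverse if r.source else None,
            }
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unsupported library format {fmt!r}")
    return path


def features_table(records: Iterable[DegronRecord]) -> pd.DataFrame:
    """Tidy per-degron feature table (one row per library member)."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "peptide": r.peptide,
                "length": r.length,
                "gravy": r.gravy,
                "max_hydrophobic_run": r.max_hydrophobic_run,
            }
            for r in records
        ]
    )


def load_tester_set() -> list[DegronRecord]:
    """The bundled 14-member degron tester set (CL1 plus 13 screen isolates)."""
    from importlib.resources import files

    path = files("degronscreen").joinpath("data/tester_set.tsv")
    with path.open("rb") as fh:  # type: ignore[attr-defined]
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return [DegronRecord.from_peptide(row.id, row.peptide) for row in df.itertuples()]
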