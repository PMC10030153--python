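"""Protein database and per-protein annotation input.

Sequences arrive as FASTA; topology regions (from transmembrane/signal-peptide
predictors) and surface-prediction consensus (SPC) scores arrive as
tab-delimited tables keyed by accession.  All protein coordinates are 1-based
inclusive, following the UniProt convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical amino-acid alphabet, plus X for an unknown residue
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: region labels a topology predictor may emit
REGION_LABELS = frozenset(
    {"extracellular", "transmembrane", "cytoplasmic", "signal_peptide"}
)


class ProteomeError(ValueError):
    """Raised for malformed sequence databases or annotation tables."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: the coordinate frame for every downstream annotation."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteomeError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ProteomeError(
                f"{self.accession}: disallowed residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered, non-overlapping regions from one predictor for one protein."""

    accession: str
    predictor: str
    regions: tuple[tuple[int, int, str], ...]

    def regions_with_label(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.regions if lab == label]


@dataclass(frozen=True)
class SurfacePredictionAnnotation:
    """SPC consensus score (0-4) and up to three signal-peptide predictor calls."""

    accession: str
    spc_score: int
    signal_peptide_calls: tuple[bool | None, bool | None, bool | None] = (
        None,
        None,
        None,
    )

    def __post_init__(self) -> None:
        if self.spc_score not in (0, 1, 2, 3, 4):
            raise ProteomeError(
                f"{self.accession}: SPC score {self.spc_score} outside 0..4"
            )

    def has_signal_peptide(self, rule: str = "any") -> bool:
        """Collapse the per-predictor calls to one boolean.

        ``any``: at least one positive call.  ``majority``: more than half of
        the non-missing calls positive.
        """
        calls = [c for c in self.signal_peptide_calls if c is not None]
        if not calls:
            return False
        if rule == "any":
            return any(calls)
        if rule == "majority":
            return sum(calls) * 2 > len(calls)
        raise ValueError(f"unknown signal-peptide rule {rule!r}")


def parse_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA database into :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved.  Duplicate accessions
    and empty sequences are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ProteomeError(f"{path}: not FASTA ({exc})") from exc
    if not parsed:
        raise ProteomeError(f"{path}: no FASTA records found")
    for rec in parsed:
        accession = rec.id
        if accession in seen:
            raise ProteomeError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                description=rec.description[len(rec.id) :].strip(),
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Inverse of :func:`parse_fasta`; the roundtrip is the identity."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _index(proteins: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {p.accession: p for p in proteins}


def load_topology(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> dict[str, list[TopologyAnnotation]]:
    """Load predictor topology regions, validated against protein lengths.

    The table needs columns ``accession``, ``predictor``, ``start``, ``end``,
    ``label``.  Regions from one predictor must be non-overlapping; several
    predictors per protein are allowed and kept separate.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"accession", "predictor", "start", "end", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ProteomeError(f"{path}: missing columns {sorted(missing)}")
    index = _index(proteins)

    out: dict[str, list[TopologyAnnotation]] = {}
    for (accession, predictor), group in table.groupby(
        ["accession", "predictor"], sort=False
    ):
        if accession not in index:
            raise ProteomeError(f"{path}: unknown accession {accession!r}")
        length = len(index[accession])
        regions: list[tuple[int, int, str]] = []
        for row in group.itertuples():
            start, end, label = int(row.start), int(row.end), str(row.label)
            if label not in REGION_LABELS:
                raise ProteomeError(f"{accession}: unknown region label {label!r}")
            if not 1 <= start <= end <= length:
                raise ProteomeError(
                    f"{accession}/{predictor}: region {start}-{end} outside 1..{length}"
                )
            regions.append((start, end, label))
        regions.sort()
        for (s1, e1, _), (s2, _e2, _) in zip(regions, regions[1:]):
            if s2 <= e1:
                raise ProteomeError(
                    f"{accession}/{predictor}: overlapping regions at {s1}-{e1} and {s2}-"
                )
        out.setdefault(accession, []).append(
            TopologyAnnotation(accession, predictor, tuple(regions))
        )
    return out


_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_bool(value: object, context: str) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "none"):
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ProteomeError(f"{context}: unparseable boolean {value!r}")


def load_surface_predictions(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> dict[str, SurfacePredictionAnnotation]:
    """Load SPC scores and signal-peptide calls; absent proteins default to
    the worst case (SPC 0, no signal peptide), which is logged."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "accession" not in table.columns or "spc_score" not in table.columns:
        raise ProteomeError(f"{path}: need columns accession, spc_score")
    sp_cols = [c for c in table.columns if c.startswith("signal_peptide")][:3]
    index = _index(proteins)

    out: dict[str, SurfacePredictionAnnotation] = {}
    for row in table.itertuples():
        accession = str(row.accession)
        if accession not in index:
            raise ProteomeError(f"{path}: unknown accession {accession!r}")
        calls = [
            _parse_bool(getattr(row, col), f"{accession}.{col}") for col in sp_cols
        ]
        calls += [None] * (3 - len(calls))
        out[accession] = SurfacePredictionAnnotation(
            accession=accession,
            spc_score=int(str(getattr(row, "spc_score"))),
            signal_peptide_calls=tuple(calls[:3]),
        )
    defaulted = [p.accession for p in proteins if p.accession not in out]
    for accession in defaulted:
        out[accession] = SurfacePredictionAnnotation(accession, 0)
    if defaulted:
        logger.info(
            "%d proteins absent from %s; defaulted to SPC 0, no signal peptide",
            len(defaulted),
            path,
        )
    return out
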