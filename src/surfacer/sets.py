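"""Presence/absence accounting across cell types, regions, and catalogs.

Exclusive-intersection semantics match UpSet plots: every accession belongs
to exactly one combination cell (the full set of datasets containing it), so
cell counts partition the accession universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def normalize_accession(accession: str, strip_isoform: bool = True) -> str:
    """Strip UniProt isoform suffixes (``P12345-2`` → ``P12345``) by default."""
    return _ISOFORM_SUFFIX.sub("", accession) if strip_isoform else accession


@dataclass(frozen=True)
class IntersectionReport:
    cells: tuple[tuple[tuple[str, ...], int, tuple[str, ...]], ...]

    @property
    def total(self) -> int:
        return sum(count for _combo, count, _acc in self.cells)


def build_presence(
    result_sets: Mapping[str, Sequence[tuple[str, Iterable[str]]]],
    min_experiments: int = 1,
    strip_isoform: bool = True,
) -> pd.DataFrame:
    """Boolean presence matrix (accession x dataset).

    ``result_sets`` maps dataset label → list of (experiment id, accessions).
    A protein is present in a dataset when identified in at least
    ``min_experiments`` of its experiments.
    """
    counts: dict[str, dict[str, int]] = {}
    for dataset, experiments in result_sets.items():
        seen_experiments: set[str] = set()
        for experiment_id, accessions in experiments:
            if experiment_id in seen_experiments:
                raise ValueError(
                    f"duplicate experiment {experiment_id!r} in dataset {dataset!r}"
                )
            seen_experiments.add(experiment_id)
            for accession in set(
                normalize_accession(a, strip_isoform) for a in accessions
            ):
                counts.setdefault(accession, {}).setdefault(dataset, 0)
                counts[accession][dataset] += 1
    datasets = list(result_sets)
    rows = {
        accession: {
            d: counts[accession].get(d, 0) >= min_experiments for d in datasets
        }
        for accession in sorted(counts)
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=datasets)
    if matrix.empty:
        matrix = pd.DataFrame(columns=datasets, dtype=bool)
    # proteins failing the threshold in every dataset drop out of the universe
    return matrix.loc[matrix.any(axis=1)] if len(matrix) else matrix


def exclusive_intersections(matrix: pd.DataFrame) -> IntersectionReport:
    """Assign each accession to exactly its combination of datasets.

    The resulting counts sum to the number of distinct accessions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 datasets")
    cells: dict[tuple[str, ...], list[str]] = {}
    datasets = list(matrix.columns)
    for accession, row in matrix.iterrows():
        combo = tuple(d for d in datasets if bool(row[d]))
        if not combo:
            continue
        cells.setdefault(combo, []).append(str(accession))
    ordered = sorted(cells.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return IntersectionReport(
        cells=tuple(
            (combo, len(accessions), tuple(sorted(accessions)))
            for combo, accessions in ordered
        )
    )


def compare_catalog(
    set_a: Iterable[str],
    set_b: Iterable[str],
    strip_isoform: bool = True,
) -> dict[str, list[str]]:
    """Two-way catalog comparison: A-only, shared, B-only (sorted lists)."""
    a = {normalize_accession(x, strip_isoform) for x in set_a}
    b = {normalize_accession(x, strip_isoform) for x in set_b}
    return {
        "a_only": sorted(a - b),
        "shared": sorted(a & b),
        "b_only": sorted(b - a),
    }
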