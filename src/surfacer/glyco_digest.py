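"""In-silico tryptic digestion, sequon enumeration, and detectability scoring.

The detectability score (per-protein count of predicted extracellular sequon
peptides that a typical LC-MS/MS run could observe) follows the CIRFESS
constraints: peptides longer than five residues with a 2+ or 3+ charge-state
m/z below 2,000.

Digestion models a Trypsin/Lys-C mixture: cleavage after every K (Lys-C does
not respect the proline rule) and after R unless the next residue is proline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .proteome_io import (
    ProteinRecord,
    SurfacePredictionAnnotation,
    TopologyAnnotation,
)

# Monoisotopic residue masses (Da), standard atomic masses; peptide mass adds
# one water.  Carried locally because no peptide-mass library ships with the
# runtime environment; cross-checked against Biopython in the test suite.
MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294986,
}

WATER = 18.010564683699997
PROTON = 1.007276
CARBAMIDOMETHYL = 57.02146
DEAMIDATION = 0.98402

#: fixed modifications applied by default (cysteine alkylation)
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": CARBAMIDOMETHYL}


class MassError(ValueError):
    """Raised when a peptide mass cannot be computed (e.g. unknown residue)."""


@dataclass(frozen=True)
class TrypticPeptide:
    accession: str
    start: int  # 1-based inclusive protein coordinates
    end: int
    sequence: str
    missed_cleavages: int

    def __len__(self) -> int:
        return len(self.sequence)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ScmSite:
    """An N-glycosylation sequon N-X-S/T (X != P); the N carries the glycan."""

    accession: str
    position: int  # protein coordinate of the asparagine
    motif: str  # the 3-residue window
    motif_class: str  # NxS | NxT | NxC


@dataclass(frozen=True)
class DetectabilityVerdict:
    peptide: TrypticPeptide
    monoisotopic_mass: float
    mz2: float
    mz3: float
    detectable: bool
    failure_reason: str | None = None


@dataclass(frozen=True)
class CirfessResult:
    """Per-protein detectability score with the contributing peptides."""

    accession: str
    score: int
    contributing: tuple[tuple[TrypticPeptide, ScmSite], ...]
    topology_source: str


def _cleavage_points(sequence: str) -> list[int]:
    """0-based indices after which the protease mixture cuts."""
    points = []
    n = len(sequence)
    for i, residue in enumerate(sequence[:-1]):
        if residue == "K":
            points.append(i)
        elif residue == "R" and sequence[i + 1] != "P":
            points.append(i)
    return points


def digest(
    sequence: str, missed_cleavages: int = 0, accession: str = ""
) -> list[TrypticPeptide]:
    """Tryptic/Lys-C digestion.

    At 0 missed cleavages the peptides tile the sequence; each product with k
    missed cleavages is the concatenation of k+1 adjacent fully cleaved
    peptides.  Peptides are returned in order of (start, end).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    # boundaries as 0-based start indices of fully cleaved peptides
    cuts = [p + 1 for p in _cleavage_points(sequence)]
    starts = [0] + cuts
    ends = cuts + [len(sequence)]
    peptides: list[TrypticPeptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for k in range(missed_cleavages + 1):
            j = i + k
            if j >= n_frag:
                break
            s, e = starts[i], ends[j]
            peptides.append(
                TrypticPeptide(
                    accession=accession,
                    start=s + 1,
                    end=e,
                    sequence=sequence[s:e],
                    missed_cleavages=k,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def find_scm_sites(
    sequence: str, include_nxc: bool = False, accession: str = ""
) -> list[ScmSite]:
    """All sequon positions N-[not P]-[S/T] (optionally N-X-C) in a sequence.

    A window containing the unknown residue X never matches (conservative
    motif calling).  Positions within two residues of the C-terminus cannot
    host a complete window.
    """
    third = {"S", "T"} | ({"C"} if include_nxc else set())
    sites: list[ScmSite] = []
    for i in range(len(sequence) - 2):
        window = sequence[i : i + 3]
        if window[0] != "N" or window[1] == "P" or window[2] not in third:
            continue
        if "X" in window:
            continue
        sites.append(
            ScmSite(
                accession=accession,
                position=i + 1,
                motif=window,
                motif_class=f"Nx{window[2]}",
            )
        )
    return sites


def peptide_mass(
    sequence: str,
    fixed_mods: Mapping[str, float] | None = DEFAULT_FIXED_MODS,
    variable_mods: Sequence[float] = (),
) -> float:
    """Monoisotopic peptide mass in Da.

    ``fixed_mods`` maps residue letters to mass deltas applied at every
    occurrence (default: carbamidomethyl cysteine).  ``variable_mods`` is a
    flat list of additional deltas (e.g. one deamidation = +0.98402).
    """
    if not sequence:
        raise MassError("empty sequence")
    fixed = fixed_mods or {}
    mass = WATER
    for residue in sequence:
        try:
            mass += MONOISOTOPIC[residue]
        except KeyError:
            raise MassError(f"no monoisotopic mass for residue {residue!r}") from None
        mass += fixed.get(residue, 0.0)
    return mass + sum(variable_mods)


def mz(mass: float, z: int) -> float:
    """m/z of a peptide of the given neutral mass at charge z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON) / z


def assess_detectability(
    peptide: TrypticPeptide | str,
    fixed_mods: Mapping[str, float] | None = DEFAULT_FIXED_MODS,
    max_mz: float = 2000.0,
    min_length: int = 6,
) -> DetectabilityVerdict:
    """MS-detectability filter: length >= 6 and 2+ or 3+ m/z below 2,000."""
    if isinstance(peptide, str):
        peptide = TrypticPeptide("", 1, len(peptide), peptide, 0)
    mass = peptide_mass(peptide.sequence, fixed_mods)
    mz2, mz3 = mz(mass, 2), mz(mass, 3)
    if len(peptide) < min_length:
        return DetectabilityVerdict(peptide, mass, mz2, mz3, False, "length")
    if min(mz2, mz3) >= max_mz:
        return DetectabilityVerdict(peptide, mass, mz2, mz3, False, "mz")
    return DetectabilityVerdict(peptide, mass, mz2, mz3, True)


def extracellular_positions(
    protein: ProteinRecord,
    annotations: Sequence[TopologyAnnotation],
    has_signal_peptide: bool = False,
) -> tuple[set[int], str]:
    """Union of positions any predictor calls extracellular.

    A protein with a signal peptide but no transmembrane segment under any
    predictor is treated as a released/anchored ectodomain: the whole mature
    chain (after the signal peptide, if annotated) counts as extracellular.
    Returns the position set and a label describing its provenance.
    """
    positions: set[int] = set()
    for annotation in annotations:
        for start, end in annotation.regions_with_label("extracellular"):
            positions.update(range(start, end + 1))
    if positions:
        sources = sorted({a.predictor for a in annotations})
        return positions, "union(" + ",".join(sources) + ")"
    any_tm = any(
        a.regions_with_label("transmembrane") for a in annotations
    )
    if has_signal_peptide and not any_tm:
        sp_end = 0
        for annotation in annotations:
            for start, end in annotation.regions_with_label("signal_peptide"):
                sp_end = max(sp_end, end)
        return set(range(sp_end + 1, len(protein) + 1)), "mature_chain"
    return set(), "none"


def cirfess_score(
    protein: ProteinRecord,
    annotations: Sequence[TopologyAnnotation] = (),
    has_signal_peptide: bool = False,
    missed_cleavages: int = 0,
    include_nxc: bool = False,
) -> CirfessResult:
    """Count distinct detectable tryptic peptides carrying an extracellular sequon.

    A peptide contributes when at least one of its sequon asparagines lies in
    a region labeled extracellular by at least one predictor and the peptide
    passes :func:`assess_detectability`.  A score of 0 means no predicted
    extracellular sequon peptide is suitable for MS analysis.
    """
    extracellular, source = extracellular_positions(
        protein, annotations, has_signal_peptide
    )
    contributing: list[tuple[TrypticPeptide, ScmSite]] = []
    if extracellular:
        sites = [
            s
            for s in find_scm_sites(
                protein.sequence, include_nxc, protein.accession
            )
            if s.position in extracellular
        ]
        if sites:
            seen: set[tuple[int, int]] = set()
            for peptide in digest(
                protein.sequence, missed_cleavages, protein.accession
            ):
                span = (peptide.start, peptide.end)
                if span in seen:
                    continue
                site = next(
                    (s for s in sites if peptide.contains(s.position)), None
                )
                if site is None:
                    continue
                if assess_detectability(peptide).detectable:
                    seen.add(span)
                    contributing.append((peptide, site))
    return CirfessResult(
        accession=protein.accession,
        score=len(contributing),
        contributing=tuple(contributing),
        topology_source=source,
    )
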