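"""PSM curation: deamidation-in-sequon evidence, capture specificity,
master-protein resolution, surface classification, and orientation inference.

The central idea: PNGase F converts a glycosylated asparagine to aspartate
(+0.984 Da deamidation), so a deamidated N inside the sequon N-X-S/T is the
MS-observable mark of a former N-glycosite.  The fraction of spectra (or
proteins) carrying that mark measures how specific the surface capture was,
and the mapped sites drive both classification and transmembrane-orientation
inference.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .glyco_digest import DEAMIDATION, CirfessResult, find_scm_sites
from .proteome_io import ProteinRecord, TopologyAnnotation

#: modification-name → mass delta, for dialects that omit deltas
KNOWN_MOD_DELTAS = {
    "deamidated": DEAMIDATION,
    "deamidation": DEAMIDATION,
    "carbamidomethyl": 57.02146,
    "oxidation": 15.994915,
}

DEAMIDATION_TOLERANCE = 0.01


class PsmError(ValueError):
    """Raised for malformed PSM tables or unmappable peptides."""


@dataclass(frozen=True)
class Modification:
    position: int  # 1-based position within the peptide
    name: str
    delta: float

    def is_deamidation(self) -> bool:
        return (
            self.name.lower().startswith("deamid")
            or abs(self.delta - DEAMIDATION) <= DEAMIDATION_TOLERANCE
        )


@dataclass(frozen=True)
class PsmRecord:
    spectrum_id: str
    peptide: str
    modifications: tuple[Modification, ...]
    accessions: tuple[str, ...]
    intensity: float | None = None
    run_id: str | None = None

    def __post_init__(self) -> None:
        for mod in self.modifications:
            if not 1 <= mod.position <= len(self.peptide):
                raise PsmError(
                    f"{self.spectrum_id}: modification position {mod.position} "
                    f"outside peptide of length {len(self.peptide)}"
                )


@dataclass(frozen=True)
class GlycositeEvidence:
    """A deamidated sequon asparagine mapped to protein coordinates."""

    accession: str
    position: int  # protein coordinate of the N
    motif: str
    psm_ids: tuple[str, ...]
    ambiguous: bool = False  # peptide maps to >1 position in this protein


@dataclass
class ProteinEvidenceSummary:
    accession: str
    n_psms_total: int = 0
    n_psms_scm: int = 0
    n_unique_peptides: int = 0
    glycosites: list[GlycositeEvidence] = field(default_factory=list)
    grouped_accessions: tuple[str, ...] = ()
    cirfess_score: int = 0
    spc_score: int = 0
    signal_peptide: bool = False


@dataclass(frozen=True)
class ClassificationResult:
    accession: str
    is_surface: bool
    branch: str  # cirfess_positive | spc_consensus | signal_peptide | none


@dataclass(frozen=True)
class SpecificityReport:
    psm_level: float
    protein_level: float
    n_psms_scm: int
    n_psms_total: int
    n_proteins_scm: int
    n_proteins_total: int


@dataclass(frozen=True)
class OrientationVerdict:
    accession: str
    inferred: str  # N-out | N-in | undetermined | conflict
    database: str | None
    status: str  # consistent | conflict | undetermined
    excluded_sites: tuple[int, ...] = ()  # glycosites inside a TM segment


# ---------------------------------------------------------------------------
# PSM table parsing

_PD_MOD_RE = re.compile(r"(?:\d+x)?(?P<name>[A-Za-z][\w\-]*)\s*\[(?P<sites>[^\]]*)\]")
_PD_SITE_RE = re.compile(r"[A-Z](?P<pos>\d+)")


def _parse_mods_pd(text: str, context: str) -> list[Modification]:
    """ProteomeDiscoverer-style strings, e.g. ``1xDeamidated [N4]``."""
    mods: list[Modification] = []
    for match in _PD_MOD_RE.finditer(text):
        name = match.group("name")
        delta = KNOWN_MOD_DELTAS.get(name.lower())
        if delta is None:
            raise PsmError(f"{context}: unknown modification name {name!r}")
        for site in _PD_SITE_RE.finditer(match.group("sites")):
            mods.append(Modification(int(site.group("pos")), name, delta))
    if text.strip() and not mods:
        raise PsmError(f"{context}: unparseable modification string {text!r}")
    return mods


def _parse_mods_generic(text: str, context: str) -> list[Modification]:
    """``position|name|delta`` entries separated by semicolons."""
    mods: list[Modification] = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split("|")
        if len(parts) != 3:
            raise PsmError(f"{context}: bad modification entry {chunk!r}")
        mods.append(Modification(int(parts[0]), parts[1], float(parts[2])))
    return mods


_DIALECTS = {
    "generic": _parse_mods_generic,
    "pd": _parse_mods_pd,
}

_REQUIRED_COLUMNS = {"spectrum_id", "peptide", "proteins"}


def parse_psm_table(
    path: str | Path, dialect: str = "generic"
) -> tuple[list[PsmRecord], int]:
    """Parse a search-engine PSM export.

    Required columns: ``spectrum_id``, ``peptide``, ``proteins``
    (semicolon-separated accessions); optional ``modifications``,
    ``intensity``, ``run``.  Returns the parsed records and the number of
    rows dropped for unparseable modification strings.
    """
    if dialect not in _DIALECTS:
        raise PsmError(f"unknown dialect {dialect!r}")
    parse_mods = _DIALECTS[dialect]
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise PsmError(f"{path}: missing columns {sorted(missing)}")

    records: list[PsmRecord] = []
    n_bad = 0
    for row in table.itertuples(index=False):
        mods_text = getattr(row, "modifications", None)
        if mods_text is None or pd.isna(mods_text):
            mods_text = ""
        intensity = getattr(row, "intensity", None)
        run = getattr(row, "run", None)
        try:
            mods = parse_mods(str(mods_text), str(row.spectrum_id))
            record = PsmRecord(
                spectrum_id=str(row.spectrum_id),
                peptide=str(row.peptide).upper(),
                modifications=tuple(mods),
                accessions=tuple(str(row.proteins).split(";")),
                intensity=None if intensity is None or pd.isna(intensity) else float(intensity),
                run_id=None if run is None or pd.isna(run) else str(run),
            )
        except (PsmError, ValueError):
            n_bad += 1
            continue
        records.append(record)
    return records, n_bad


# ---------------------------------------------------------------------------
# Glycosite evidence

def flag_scm_deamidation(
    psm: PsmRecord,
    proteins: Mapping[str, ProteinRecord],
    include_nxc: bool = False,
) -> list[GlycositeEvidence]:
    """Map each deamidated asparagine of a PSM to sequon evidence.

    The sequon is evaluated in protein context, so a motif window may extend
    past the peptide's C-terminus.  Peptides matching multiple positions in
    one protein yield evidence at every position, flagged ambiguous.
    """
    deamidated = [
        m
        for m in psm.modifications
        if m.is_deamidation() and psm.peptide[m.position - 1] == "N"
    ]
    if not deamidated:
        return []
    evidence: list[GlycositeEvidence] = []
    located_anywhere = False
    for accession in psm.accessions:
        protein = proteins.get(accession)
        if protein is None:
            continue
        offsets = [
            m.start() for m in re.finditer(re.escape(psm.peptide), protein.sequence)
        ]
        if not offsets:
            continue
        located_anywhere = True
        ambiguous = len(offsets) > 1
        site_positions = {
            s.position
            for s in find_scm_sites(protein.sequence, include_nxc, accession)
        }
        for offset in offsets:
            for mod in deamidated:
                position = offset + mod.position  # 1-based protein coordinate
                if position in site_positions:
                    evidence.append(
                        GlycositeEvidence(
                            accession=accession,
                            position=position,
                            motif=protein.sequence[position - 1 : position + 2],
                            psm_ids=(psm.spectrum_id,),
                            ambiguous=ambiguous,
                        )
                    )
    if not located_anywhere:
        raise PsmError(
            f"{psm.spectrum_id}: peptide {psm.peptide!r} not found in any listed protein"
        )
    return evidence


# ---------------------------------------------------------------------------
# Master-protein resolution

def assign_master_proteins(
    psms: Sequence[PsmRecord],
    proteins: Mapping[str, ProteinRecord],
    include_nxc: bool = False,
) -> dict[str, ProteinEvidenceSummary]:
    """Resolve protein groups to master accessions and tally evidence.

    A protein is a master when it is supported by at least one peptide unique
    to it (proteins with identical peptide sets form one group represented by
    the lexicographically smallest accession).  Proteins supported only by
    shared peptides are grouped under the master with the largest peptide
    overlap and do not receive their own summary.
    """
    if not psms:
        raise PsmError("empty PSM list")

    peptides_of: dict[str, set[str]] = defaultdict(set)
    for psm in psms:
        for accession in psm.accessions:
            peptides_of[accession].add(psm.peptide)

    # collapse identical peptide sets to one representative
    by_peptide_set: dict[frozenset[str], list[str]] = defaultdict(list)
    for accession, peps in peptides_of.items():
        by_peptide_set[frozenset(peps)].append(accession)
    representative: dict[str, str] = {}
    for members in by_peptide_set.values():
        rep = min(members)
        for member in members:
            representative[member] = rep

    # peptide → set of representatives containing it
    groups_with: dict[str, set[str]] = defaultdict(set)
    for accession, peps in peptides_of.items():
        for pep in peps:
            groups_with[pep].add(representative[accession])

    masters = sorted(
        {
            rep
            for rep in set(representative.values())
            if any(len(groups_with[p]) == 1 for p in peptides_of[rep])
        }
    )
    if not masters:
        # degenerate: every peptide shared across all groups; keep smallest
        masters = [min(representative.values())]
    master_set = set(masters)

    # attach non-master groups to the master with largest peptide overlap
    attachment: dict[str, str] = {m: m for m in masters}
    for rep in set(representative.values()) - master_set:
        overlaps = sorted(
            masters,
            key=lambda m: (-len(peptides_of[rep] & peptides_of[m]), m),
        )
        attachment[rep] = overlaps[0]

    grouped_under: dict[str, list[str]] = defaultdict(list)
    for accession, rep in representative.items():
        master = attachment[rep]
        if accession != master:
            grouped_under[master].append(accession)

    summaries = {
        m: ProteinEvidenceSummary(
            accession=m, grouped_accessions=tuple(sorted(grouped_under[m]))
        )
        for m in masters
    }

    # unique peptides per master: peptides present in exactly that group
    for master in masters:
        summaries[master].n_unique_peptides = sum(
            1 for p in peptides_of[master] if len(groups_with[p]) == 1
        )

    site_index: dict[tuple[str, int], GlycositeEvidence] = {}
    for psm in psms:
        try:
            evidence = flag_scm_deamidation(psm, proteins, include_nxc)
        except PsmError:
            evidence = []
        evidence_masters = set()
        psm_masters = {
            attachment[representative[a]]
            for a in psm.accessions
            if a in representative
        }
        for ev in evidence:
            if ev.accession not in representative:
                continue
            master = attachment[representative[ev.accession]]
            if ev.accession != master:
                continue  # site coordinates only meaningful on the master itself
            evidence_masters.add(master)
            key = (master, ev.position)
            prior = site_index.get(key)
            if prior is None:
                site_index[key] = ev
            else:
                site_index[key] = GlycositeEvidence(
                    accession=master,
                    position=ev.position,
                    motif=ev.motif,
                    psm_ids=tuple(sorted(set(prior.psm_ids) | set(ev.psm_ids))),
                    ambiguous=prior.ambiguous or ev.ambiguous,
                )
        for master in psm_masters:
            summaries[master].n_psms_total += 1
        for master in evidence_masters & psm_masters:
            summaries[master].n_psms_scm += 1

    for (master, _position), ev in sorted(site_index.items()):
        summaries[master].glycosites.append(ev)
    return summaries


def compute_specificity(
    summaries: Mapping[str, ProteinEvidenceSummary],
    psms: Sequence[PsmRecord],
    proteins: Mapping[str, ProteinRecord],
    include_nxc: bool = False,
) -> SpecificityReport:
    """Capture specificity: deamidation-in-sequon PSMs (or master proteins)
    as a percentage of all PSMs (or masters)."""
    if not psms:
        raise PsmError("zero PSM denominator")
    n_psms_scm = 0
    for psm in psms:
        try:
            if flag_scm_deamidation(psm, proteins, include_nxc):
                n_psms_scm += 1
        except PsmError:
            pass
    n_proteins_total = len(summaries)
    if n_proteins_total == 0:
        raise PsmError("zero protein denominator")
    n_proteins_scm = sum(1 for s in summaries.values() if s.glycosites)
    return SpecificityReport(
        psm_level=100.0 * n_psms_scm / len(psms),
        protein_level=100.0 * n_proteins_scm / n_proteins_total,
        n_psms_scm=n_psms_scm,
        n_psms_total=len(psms),
        n_proteins_scm=n_proteins_scm,
        n_proteins_total=n_proteins_total,
    )


# ---------------------------------------------------------------------------
# Classification

def classify_surface(summary: ProteinEvidenceSummary) -> ClassificationResult:
    """Surface call: detectability score > 0, or score 0 with SPC 3-4, or
    score 0 with a predicted signal peptide.  The branch records the first
    satisfied clause in that order."""
    if summary.cirfess_score > 0:
        return ClassificationResult(summary.accession, True, "cirfess_positive")
    if summary.spc_score in (3, 4):
        return ClassificationResult(summary.accession, True, "spc_consensus")
    if summary.signal_peptide:
        return ClassificationResult(summary.accession, True, "signal_peptide")
    return ClassificationResult(summary.accession, False, "none")


# ---------------------------------------------------------------------------
# Orientation inference

def infer_orientation(
    glycosites: Iterable[int],
    topology: TopologyAnnotation,
    database_orientation: str | None = None,
) -> OrientationVerdict:
    """Infer the N-terminal side of a membrane protein from glycosite parity.

    Glycosites are extracellular, and sides alternate across transmembrane
    segments; a glycosite in the k-th inter-TM loop (counting the N-terminal
    segment as loop 0) therefore implies N-out when k is even and N-in when k
    is odd.  Sites agreeing on one parity give a verdict; both parities give a
    conflict; sites inside a TM segment are excluded from the vote.
    """
    tm = sorted(topology.regions_with_label("transmembrane"))
    if not tm:
        raise ValueError(f"{topology.accession}: no transmembrane segment")
    excluded: list[int] = []
    parities: set[int] = set()
    for position in sorted(set(glycosites)):
        if any(s <= position <= e for s, e in tm):
            excluded.append(position)
            continue
        loop = sum(1 for s, _e in tm if position > s)
        parities.add(loop % 2)
    if not parities:
        inferred = "undetermined"
    elif parities == {0}:
        inferred = "N-out"
    elif parities == {1}:
        inferred = "N-in"
    else:
        inferred = "conflict"

    if inferred in ("undetermined", "conflict") or database_orientation is None:
        status = "conflict" if inferred == "conflict" else "undetermined"
    else:
        status = "consistent" if inferred == database_orientation else "conflict"
    return OrientationVerdict(
        accession=topology.accession,
        inferred=inferred,
        database=database_orientation,
        status=status,
        excluded_sites=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Report bundle

def curation_report(
    summaries: Mapping[str, ProteinEvidenceSummary],
    classifications: Mapping[str, ClassificationResult],
    specificity: SpecificityReport | None = None,
) -> dict[str, pd.DataFrame | SpecificityReport | None]:
    """Assemble curation output: the sequon-evidence ("SCM") table over all
    masters with at least one deamidated sequon peptide, the classified
    subset ("SCM Filtered"), and the per-site glycosite table."""
    scm_rows = []
    filtered_rows = []
    site_rows = []
    for accession in sorted(summaries):
        summary = summaries[accession]
        if not summary.glycosites:
            continue
        verdict = classifications.get(accession)
        row = {
            "accession": accession,
            "n_psms_total": summary.n_psms_total,
            "n_psms_scm": summary.n_psms_scm,
            "n_unique_peptides": summary.n_unique_peptides,
            "n_glycosites": len(summary.glycosites),
            "cirfess_score": summary.cirfess_score,
            "spc_score": summary.spc_score,
            "signal_peptide": summary.signal_peptide,
            "is_surface": bool(verdict and verdict.is_surface),
            "branch": verdict.branch if verdict else "none",
        }
        scm_rows.append(row)
        if verdict and verdict.is_surface:
            filtered_rows.append(row)
        for site in summary.glycosites:
            site_rows.append(
                {
                    "accession": accession,
                    "position": site.position,
                    "motif": site.motif,
                    "n_psms": len(site.psm_ids),
                    "ambiguous": site.ambiguous,
                }
            )
    columns = [
        "accession", "n_psms_total", "n_psms_scm", "n_unique_peptides",
        "n_glycosites", "cirfess_score", "spc_score", "signal_peptide",
        "is_surface", "branch",
    ]
    site_columns = ["accession", "position", "motif", "n_psms", "ambiguous"]
    return {
        "scm": pd.DataFrame(scm_rows, columns=columns),
        "scm_filtered": pd.DataFrame(filtered_rows, columns=columns),
        "glycosites": pd.DataFrame(site_rows, columns=site_columns),
        "specificity": specificity,
    }
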