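"""Candidate-marker prioritization across cell types or regions.

Scores combine abundance dispersion across groups (Gini coefficient), a
log-scaled signal-strength component, and — for the surface-aware score —
the surface-prediction-consensus (SPC) integer normalized to [0, 1].  The
"omni" score drops the SPC component for samples where consensus predictions
are unavailable or untrusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class AbundanceProfile:
    accession: str
    values: tuple[float, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.groups):
            raise ValueError(f"{self.accession}: values/groups length mismatch")
        if len(self.values) < 2:
            raise ValueError(f"{self.accession}: need at least 2 groups")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(f"{self.accession}: values must be finite and >= 0")


@dataclass(frozen=True)
class MarkerScore:
    accession: str
    gini: float
    signal: float
    spc_component: float
    genie_score: float
    omni_score: float


def gini(values: Sequence[float]) -> float:
    """Population Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 mean).

    Scale-invariant; 0 for a uniform vector, (n-1)/n for a one-hot vector.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("values must be finite and >= 0")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero vector has undefined dispersion")
    # O(n log n) equivalent of the pairwise-difference double sum
    sorted_x = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(np.sum((2 * ranks - n - 1) * sorted_x) / (n * total))


def signal_strength(values: Sequence[float], cap_log2: float = 30.0) -> float:
    """Scaled abundance strength: min(log2(1 + max(values)), cap) / cap."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    return float(min(np.log2(1.0 + x.max(initial=0.0)), cap_log2) / cap_log2)


def score_markers(
    profiles: Iterable[AbundanceProfile],
    spc_scores: Mapping[str, int] | None = None,
    mode: str = "genie",
    cap_log2: float = 30.0,
) -> list[MarkerScore]:
    """Rank proteins by dispersion x strength (x SPC/4 in genie mode).

    Descending by the selected score; ties broken by accession.
    """
    if mode not in ("genie", "omni"):
        raise ValueError(f"unknown mode {mode!r}")
    profiles = list(profiles)
    group_sets = {p.groups for p in profiles}
    if len(group_sets) > 1:
        raise ValueError("profiles must share group labels")
    spc_scores = spc_scores or {}
    scores: list[MarkerScore] = []
    for profile in profiles:
        x = np.asarray(profile.values, dtype=float)
        g = gini(x) if x.sum() > 0 else 0.0
        s = signal_strength(x, cap_log2)
        spc_component = spc_scores.get(profile.accession, 0) / 4.0
        scores.append(
            MarkerScore(
                accession=profile.accession,
                gini=g,
                signal=s,
                spc_component=spc_component,
                genie_score=spc_component * g * s,
                omni_score=g * s,
            )
        )
    key = (lambda m: (-m.genie_score, m.accession)) if mode == "genie" else (
        lambda m: (-m.omni_score, m.accession)
    )
    return sorted(scores, key=key)


def restricted_markers(
    presence: Mapping[str, Mapping[str, bool]],
    target_group: str,
    external_catalogs: Sequence[Iterable[str]] = (),
) -> list[str]:
    """Proteins present in the target group, absent from every other group
    and from every external catalog.

    ``presence`` maps accession → {group: present}.  This mirrors the
    cell-type-restricted marker search: candidates seen only in the target
    cell type and never in any reference surfaceome catalog.
    """
    groups = {g for row in presence.values() for g in row}
    if target_group not in groups:
        raise KeyError(f"target group {target_group!r} not in presence matrix")
    catalog_union: set[str] = set()
    for catalog in external_catalogs:
        catalog_union.update(catalog)
    out = []
    for accession in sorted(presence):
        row = presence[accession]
        if not row.get(target_group, False):
            continue
        if any(row.get(g, False) for g in groups if g != target_group):
            continue
        if accession in catalog_union:
            continue
        out.append(accession)
    return out
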