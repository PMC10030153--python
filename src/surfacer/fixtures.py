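"""Synthetic proteomes, PSM tables, and intensity matrices with known truth.

Every generator is a pure function of (parameters, seed): the same call
produces byte-identical files.  Sequences are built from weighted residue
sampling with planted cleavage sites and sequons rather than natural-sequence
mimicry, so the ground truth (surface status, decision branch, glycosites,
differential effects, censoring) is exact by construction.

Surface proteins are planted on one of the three classification branches:
most carry a detectable extracellular sequon peptide (detectability score
> 0); the rest are split between SPC-consensus (score 3-4) and
signal-peptide evidence.  Proteins on the latter two branches are built
without asparagine so their detectability score is provably zero and the
planted branch is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glyco_digest import DEAMIDATION, digest

#: filler residues: no K/R (cleavage), N (sequons), P (cleavage suppression),
#: X (unknown); C excluded to keep planted peptides light
_FILLER = "ADEFGHILMQSTVWY"
_HYDROPHOBIC = "AILVF"
#: mixture of decision branches among planted surface proteins
BRANCH_MIXTURE = (("cirfess_positive", 0.6), ("spc_consensus", 0.25), ("signal_peptide", 0.15))


@dataclass(frozen=True)
class FixtureBundle:
    directory: Path
    fasta: Path
    topology: Path
    surface_predictions: Path
    truth: Path
    psm_table: Path | None = None
    intensity: Path | None = None
    design: Path | None = None

    def load_truth(self) -> dict:
        return json.loads(self.truth.read_text())


def _filler(rng: np.random.Generator, n: int, alphabet: str = _FILLER) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _write_fasta(records: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for accession, sequence in records:
            fh.write(f">{accession} synthetic\n")
            for i in range(0, len(sequence), 60):
                fh.write(sequence[i : i + 60] + "\n")


def _plant_sequon_peptide(rng: np.random.Generator) -> tuple[str, int]:
    """A short tryptic peptide carrying one sequon; returns (sequence,
    0-based offset of the N within the peptide)."""
    pre = _filler(rng, int(rng.integers(2, 5)))
    x = _filler(rng, 1)
    third = "T" if rng.random() < 0.5 else "S"
    post = _filler(rng, int(rng.integers(1, 4)))
    return pre + "N" + x + third + post + "K", len(pre)


def generate_proteome(
    n: int,
    surface_fraction: float,
    seed: int,
    out_dir: str | Path,
) -> FixtureBundle:
    """Generate a FASTA database plus topology and surface-prediction tables.

    Exactly ``round(n * surface_fraction)`` proteins are surface-positive,
    assigned to decision branches per :data:`BRANCH_MIXTURE`; the rest carry
    none of the three evidence types.  Truth (per-protein status, branch,
    planted peptide and glycosite, orientation) goes to ``truth.json``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= surface_fraction <= 1.0:
        raise ValueError("surface_fraction must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_surface = round(n * surface_fraction)
    branch_labels = [b for b, _w in BRANCH_MIXTURE]
    branch_weights = np.array([w for _b, w in BRANCH_MIXTURE])
    branches = list(
        rng.choice(branch_labels, size=n_surface, p=branch_weights / branch_weights.sum())
    ) + ["none"] * (n - n_surface)

    records: list[tuple[str, str]] = []
    topology_rows: list[dict] = []
    surface_rows: list[dict] = []
    truth_proteins: dict[str, dict] = {}

    for i, branch in enumerate(branches):
        accession = f"SYN{i:04d}"
        entry: dict = {"branch": branch, "is_surface": branch != "none"}
        if branch == "cirfess_positive":
            peptide, n_offset = _plant_sequon_peptide(rng)
            ecto_pre = _filler(rng, int(rng.integers(8, 20))) + "K"
            ecto_post = _filler(rng, int(rng.integers(4, 12)))
            ecto = ecto_pre + peptide + ecto_post
            tm = _filler(rng, 21, _HYDROPHOBIC)
            tail = _filler(rng, int(rng.integers(8, 20)))
            sequence = ecto + tm + tail
            glycosite = len(ecto_pre) + n_offset + 1  # 1-based protein coordinate
            topology_rows += [
                dict(accession=accession, predictor="predictor-A", start=1,
                     end=len(ecto), label="extracellular"),
                dict(accession=accession, predictor="predictor-A",
                     start=len(ecto) + 1, end=len(ecto) + 21, label="transmembrane"),
                dict(accession=accession, predictor="predictor-A",
                     start=len(ecto) + 22, end=len(sequence), label="cytoplasmic"),
            ]
            if rng.random() < 0.5:  # second predictor with a shifted boundary
                shift = int(rng.integers(1, 4))
                topology_rows += [
                    dict(accession=accession, predictor="predictor-B", start=1,
                         end=len(ecto) - shift, label="extracellular"),
                    dict(accession=accession, predictor="predictor-B",
                         start=len(ecto) - shift + 1, end=len(ecto) + 21,
                         label="transmembrane"),
                ]
            spc = int(rng.integers(0, 5))
            sp_calls = [bool(rng.random() < 0.3) for _ in range(3)]
            entry.update(
                planted_peptide=peptide,
                glycosite=glycosite,
                orientation="N-out",
                tm_start=len(ecto) + 1,
                tm_end=len(ecto) + 21,
            )
        elif branch == "spc_consensus":
            sequence = _insert_cleavages(rng, _filler(rng, int(rng.integers(50, 90))))
            spc = int(rng.integers(3, 5))
            sp_calls = [False, False, False]
        elif branch == "signal_peptide":
            sequence = _insert_cleavages(rng, _filler(rng, int(rng.integers(50, 90))))
            spc = int(rng.integers(0, 3))
            positive = int(rng.integers(0, 3))
            sp_calls = [j == positive or rng.random() < 0.3 for j in range(3)]
            topology_rows.append(
                dict(accession=accession, predictor="predictor-A", start=1,
                     end=20, label="signal_peptide")
            )
        else:  # non-surface: may contain sequons, but never extracellular ones
            body = "".join(
                rng.choice(list(_FILLER + "NKR"), size=int(rng.integers(50, 90)))
            )
            sequence = body
            spc = int(rng.integers(0, 3))
            sp_calls = [False, False, False]
            if rng.random() < 0.5:
                tm_start = int(rng.integers(5, max(6, len(sequence) - 25)))
                topology_rows += [
                    dict(accession=accession, predictor="predictor-A",
                         start=tm_start, end=tm_start + 20, label="transmembrane"),
                    dict(accession=accession, predictor="predictor-A",
                         start=tm_start + 21, end=len(sequence), label="cytoplasmic"),
                ]
        records.append((accession, sequence))
        surface_rows.append(
            dict(
                accession=accession,
                spc_score=spc,
                signal_peptide_1=str(sp_calls[0]).lower(),
                signal_peptide_2=str(sp_calls[1]).lower(),
                signal_peptide_3=str(sp_calls[2]).lower(),
            )
        )
        entry.update(spc_score=spc, signal_peptide=any(sp_calls), length=len(sequence))
        truth_proteins[accession] = entry

    fasta = out_dir / "proteome.fasta"
    topology = out_dir / "topology.tsv"
    surface = out_dir / "surface_predictions.tsv"
    truth_path = out_dir / "truth.json"
    _write_fasta(records, fasta)
    pd.DataFrame(
        topology_rows, columns=["accession", "predictor", "start", "end", "label"]
    ).to_csv(topology, sep="\t", index=False)
    pd.DataFrame(surface_rows).to_csv(surface, sep="\t", index=False)
    truth = {
        "parameters": {"n": n, "surface_fraction": surface_fraction, "seed": seed},
        "proteins": truth_proteins,
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return FixtureBundle(
        directory=out_dir,
        fasta=fasta,
        topology=topology,
        surface_predictions=surface,
        truth=truth_path,
    )


def _insert_cleavages(rng: np.random.Generator, body: str) -> str:
    """Sprinkle K residues so digestion yields several peptides."""
    chars = list(body)
    for pos in rng.choice(len(chars), size=max(1, len(chars) // 15), replace=False):
        chars[int(pos)] = "K"
    return "".join(chars)


def generate_psm_table(
    bundle: FixtureBundle,
    n_psms: int,
    scm_specificity: float = 0.8,
    deamidation_rate: float = 0.05,
    n_runs: int = 3,
    seed: int = 0,
) -> Path:
    """Emit a PSM table whose capture specificity is known by construction.

    Each PSM is, with probability ``scm_specificity``, a planted sequon
    peptide carrying a deamidated asparagine (a true capture event); otherwise
    a background tryptic peptide with no sequon deamidation.  Background PSMs
    may carry an irrelevant glutamine deamidation at ``deamidation_rate`` to
    exercise the residue check.
    """
    if n_psms < 1:
        raise ValueError("n_psms must be >= 1")
    rng = np.random.default_rng(seed)
    truth = bundle.load_truth()
    proteins = truth["proteins"]
    sequences = _read_fasta_sequences(bundle.fasta)

    scm_pool = [
        (acc, entry["planted_peptide"], entry["glycosite"])
        for acc, entry in sorted(proteins.items())
        if entry["branch"] == "cirfess_positive"
    ]
    if not scm_pool:
        raise ValueError("bundle has no sequon-positive proteins")
    background_pool: list[tuple[str, str]] = []
    for acc in sorted(sequences):
        for pep in digest(sequences[acc], 0, acc):
            if len(pep) >= 6 and "N" not in pep.sequence:
                background_pool.append((acc, pep.sequence))

    rows = []
    for i in range(n_psms):
        run = f"run{1 + int(rng.integers(0, n_runs))}"
        intensity = float(np.round(2.0 ** rng.normal(22.0, 1.5), 2))
        if rng.random() < scm_specificity:
            acc, peptide, glycosite = scm_pool[int(rng.integers(0, len(scm_pool)))]
            offset = sequences[acc].find(peptide)
            pos_in_peptide = glycosite - offset  # 1-based
            mods = f"{pos_in_peptide}|Deamidated|{DEAMIDATION}"
        else:
            acc, peptide = background_pool[int(rng.integers(0, len(background_pool)))]
            mods = ""
            if rng.random() < deamidation_rate and "Q" in peptide:
                q_pos = peptide.index("Q") + 1
                mods = f"{q_pos}|Deamidated|{DEAMIDATION}"
        rows.append(
            dict(
                spectrum_id=f"spec{i:06d}",
                peptide=peptide,
                modifications=mods,
                proteins=acc,
                intensity=intensity,
                run=run,
            )
        )
    path = bundle.directory / "psms.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def _read_fasta_sequences(path: Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    accession = None
    parts: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if accession is not None:
                sequences[accession] = "".join(parts)
            accession = line[1:].split()[0]
            parts = []
        else:
            parts.append(line.strip())
    if accession is not None:
        sequences[accession] = "".join(parts)
    return sequences


def generate_intensity_matrix(
    n_proteins: int,
    n_features_per_protein: int = 3,
    groups: dict[str, int] | None = None,
    effect_log2: float = 2.0,
    de_fraction: float = 0.1,
    sigma: float = 0.3,
    censor_quantile: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Simulate a feature x run raw-intensity matrix with known effects.

    log2 intensities are Normal(protein mean + feature offset + run shift +
    group effect, sigma); the group effect (``effect_log2``, random sign)
    applies to a ``de_fraction`` subset of proteins in the second group.
    Entries below each feature's ``censor_quantile`` quantile are removed
    (left-censoring).  Run shifts are Normal(0, 0.5) so equalize-median
    normalization has real work to do.

    Returns (raw matrix with (protein, feature) index, run → group design,
    truth dict); with ``out_dir`` the three files are also written as TSV/JSON.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    groups = groups or {"groupA": 4, "groupB": 4}
    if len(groups) != 2 or any(v < 2 for v in groups.values()):
        raise ValueError("need exactly 2 groups with >= 2 runs each")
    rng = np.random.default_rng(seed)
    group_names = list(groups)
    runs = [
        (f"{g}_r{j + 1}", g) for g in group_names for j in range(groups[g])
    ]
    run_names = [r for r, _g in runs]
    design = dict(runs)
    run_shift = {r: rng.normal(0.0, 0.5) for r in run_names}

    n_de = round(n_proteins * de_fraction)
    de_index = rng.choice(n_proteins, size=n_de, replace=False)
    effects = np.zeros(n_proteins)
    effects[de_index] = effect_log2 * rng.choice([-1.0, 1.0], size=n_de)

    index = []
    data = []
    for p in range(n_proteins):
        protein_mean = rng.normal(22.0, 2.0)
        for f in range(n_features_per_protein):
            feature_offset = rng.normal(0.0, 1.0)
            row = []
            for run, group in runs:
                value = (
                    protein_mean
                    + feature_offset
                    + run_shift[run]
                    + (effects[p] if group == group_names[1] else 0.0)
                    + rng.normal(0.0, sigma)
                )
                row.append(value)
            index.append((f"PROT{p:04d}", f"feat{f}"))
            data.append(row)
    log_matrix = pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(index, names=["protein", "feature"]),
        columns=run_names,
    )
    if censor_quantile > 0:
        cutoffs = log_matrix.quantile(censor_quantile, axis=1)
        log_matrix = log_matrix.where(log_matrix.ge(cutoffs, axis=0))
    raw = (2.0 ** log_matrix).round(4)

    truth = {
        "parameters": dict(
            n_proteins=n_proteins,
            n_features_per_protein=n_features_per_protein,
            groups=groups,
            effect_log2=effect_log2,
            de_fraction=de_fraction,
            sigma=sigma,
            censor_quantile=censor_quantile,
            seed=seed,
        ),
        "de_proteins": {
            f"PROT{int(p):04d}": float(effects[int(p)]) for p in sorted(de_index)
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out_dir / "intensities.tsv", sep="\t")
        pd.DataFrame(
            [{"run": r, "group": g} for r, g in design.items()]
        ).to_csv(out_dir / "design.tsv", sep="\t", index=False)
        (out_dir / "quant_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True)
        )
    return raw, design, truth
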