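"""Label-free quantification: normalization, summarization, imputation,
differential testing, and replicate QC.

The workflow mirrors a standard MS statistics pipeline: feature intensities
are log2-transformed, runs are equalize-median normalized, each protein's
feature x run block is summarized to run-level values by Tukey's median
polish, left-censored missing values are imputed with a censored-normal
accelerated-failure-time fit on the log2 scale, and two-group differences
are tested per protein with Benjamini-Hochberg adjustment.

In-memory containers are pandas DataFrames: feature matrices carry a
(protein, feature) MultiIndex over run columns; run-summary matrices carry a
protein index over the same runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialResult:
    accession: str
    log2fc: float
    p_value: float
    adj_p: float
    significant: bool


@dataclass(frozen=True)
class QcReport:
    median_cv_percent: dict[str, float]
    median_pearson: dict[str, float]
    pairwise_pearson: dict[str, dict[tuple[str, str], float]]
    skipped_sets: tuple[str, ...]


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing stays missing; non-positive entries become
    missing (counted and logged)."""
    values = matrix.to_numpy(dtype=float, copy=True)
    nonpositive = np.isfinite(values) & (values <= 0)
    if nonpositive.any():
        logger.warning(
            "%d non-positive intensities treated as missing", int(nonpositive.sum())
        )
        values[nonpositive] = np.nan
    out = np.full_like(values, np.nan)
    mask = np.isfinite(values)
    out[mask] = np.log2(values[mask])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def equalize_medians(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift every run so all run medians equal the median of run medians.

    A pure per-column shift: within-run differences are untouched.
    """
    run_medians = log_matrix.median(axis=0, skipna=True)
    if run_medians.isna().any():
        empty = list(log_matrix.columns[run_medians.isna()])
        raise ValueError(f"runs with no observed values: {empty}")
    target = float(run_medians.median())
    return log_matrix + (target - run_medians)


def median_polish(
    block: pd.DataFrame, tol: float = 1e-6, max_iter: int = 100
) -> tuple[pd.Series, pd.DataFrame]:
    """Tukey's median polish of one protein's feature x run block.

    Decomposes the block into overall + feature + run effects + residuals by
    alternately sweeping row and column medians (missing entries ignored).
    Returns (run-level summaries = overall + run effect, residuals).
    """
    z = block.to_numpy(dtype=float, copy=True)
    if not np.isfinite(z).any():
        raise ValueError("all-missing block")
    n_rows, n_cols = z.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    last_size = np.nansum(np.abs(z))
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            rdelta = np.nanmedian(z, axis=1)
        rdelta = np.where(np.isfinite(rdelta), rdelta, 0.0)
        z -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        overall += delta
        col_eff -= delta

        with np.errstate(all="ignore"):
            cdelta = np.nanmedian(z, axis=0)
        cdelta = np.where(np.isfinite(cdelta), cdelta, np.nan)
        z -= np.where(np.isfinite(cdelta), cdelta, 0.0)[None, :]
        col_eff += np.where(np.isfinite(cdelta), cdelta, 0.0)
        delta = np.median(row_eff)
        overall += delta
        row_eff -= delta

        size = np.nansum(np.abs(z))
        if abs(last_size - size) <= tol * max(size, 1.0):
            break
        last_size = size
    summaries = pd.Series(overall + col_eff, index=block.columns)
    # a run with no observation for this protein has no defined summary
    observed_runs = np.isfinite(block.to_numpy(dtype=float)).any(axis=0)
    summaries[~observed_runs] = np.nan
    residuals = pd.DataFrame(z, index=block.index, columns=block.columns)
    return summaries, residuals


def summarize_runs(feature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-polish every protein block of a (protein, feature) x run matrix
    into a protein x run summary matrix."""
    proteins = feature_matrix.index.get_level_values(0).unique()
    rows = {}
    for protein in proteins:
        block = feature_matrix.xs(protein, level=0, drop_level=True)
        if isinstance(block, pd.Series):
            block = block.to_frame().T
        summaries, _residuals = median_polish(block)
        rows[protein] = summaries
    return pd.DataFrame.from_dict(rows, orient="index")[feature_matrix.columns]


# ---------------------------------------------------------------------------
# Censored imputation

_RIDGE = 0.01  # pins unidentified effects: a run with only censored cells has
# an improper MLE (its effect drifts to -inf), so effects carry a weak penalty


def _censored_normal_fit(
    block: np.ndarray, thresholds: np.ndarray
) -> np.ndarray | None:
    """Fit y ~ mu + feature + run with normal error, treating missing cells as
    left-censored at their feature threshold; return the fitted cell means."""
    n_f, n_r = block.shape
    observed = np.isfinite(block)
    censorable = ~observed & np.isfinite(thresholds)[:, None]
    n_obs = int(observed.sum())
    if n_obs < 2:
        return None

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, float]:
        mu = theta[0]
        alpha = np.concatenate([[0.0], theta[1 : n_f]])
        beta = np.concatenate([[0.0], theta[n_f : n_f + n_r - 1]])
        pred = mu + alpha[:, None] + beta[None, :]
        return pred, theta[-1]

    def negloglik(theta: np.ndarray) -> float:
        pred, log_sigma = unpack(theta)
        sigma = np.exp(log_sigma)
        nll = -np.sum(stats.norm.logpdf(block[observed], pred[observed], sigma))
        if censorable.any():
            thr = np.broadcast_to(thresholds[:, None], block.shape)[censorable]
            nll -= np.sum(
                stats.norm.logcdf((thr - pred[censorable]) / sigma)
            )
        nll += _RIDGE * float(np.sum(theta[1:-1] ** 2))
        return float(nll) if np.isfinite(nll) else 1e12

    theta0 = np.zeros(n_f + n_r)
    theta0[0] = np.nanmean(block)
    observed_sd = np.nanstd(block)
    theta0[-1] = np.log(max(observed_sd, 0.1))
    result = optimize.minimize(negloglik, theta0, method="L-BFGS-B")
    pred, _ = unpack(result.x)
    return pred


def impute_censored(
    log_matrix: pd.DataFrame,
    thresholds: Mapping[tuple, float] | None = None,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Impute left-censored missing values per protein.

    Missing entries are treated as censored at the per-feature minimum
    observed value (or an explicit per-feature threshold map).  Imputed
    values are the accelerated-failure-time model's cell predictions,
    truncated so they never exceed the censoring threshold.  Proteins with
    fewer than two observed values are left unimputed and returned flagged.
    A matrix without missing entries is a fixed point.
    """
    if not log_matrix.isna().any().any():
        return log_matrix.copy(), []
    out = log_matrix.copy()
    flagged: list[tuple] = []
    for protein in log_matrix.index.get_level_values(0).unique():
        block = log_matrix.xs(protein, level=0, drop_level=True)
        if isinstance(block, pd.Series):
            block = block.to_frame().T
        values = block.to_numpy(dtype=float)
        if not np.isnan(values).any():
            continue
        if thresholds is None:
            observed_any = np.isfinite(values).any(axis=1)
            thr = np.full(values.shape[0], np.nan)
            if observed_any.any():
                thr[observed_any] = np.nanmin(values[observed_any], axis=1)
        else:
            thr = np.array(
                [thresholds.get((protein, f), np.nan) for f in block.index]
            )
        pred = _censored_normal_fit(values, thr)
        if pred is None:
            flagged.append(protein)
            continue
        censored = np.isnan(values) & np.isfinite(thr)[:, None]
        filled = values.copy()
        thr_grid = np.broadcast_to(thr[:, None], values.shape)
        filled[censored] = np.minimum(pred[censored], thr_grid[censored])
        out.loc[(protein,), :] = filled
    return out, flagged


# ---------------------------------------------------------------------------
# Differential testing

def differential_test(
    run_summaries: pd.DataFrame,
    design: Mapping[str, str],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    group_order: Sequence[str] | None = None,
    fc_scale: str = "log2",
) -> list[DifferentialResult]:
    """Two-group equal-variance t-test per protein on run-level summaries.

    log2fc is mean(second group) - mean(first group).  P values are
    Benjamini-Hochberg adjusted across all tested proteins; a protein is
    significant when |log2fc| >= fc_threshold (log2 scale; ``fc_scale="ratio"``
    reads the threshold as a raw fold change) and adjusted P < alpha.
    """
    groups = sorted(set(design.values())) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    runs_by_group = {
        g: [r for r in run_summaries.columns if design.get(r) == g] for g in groups
    }
    for g, runs in runs_by_group.items():
        if not runs:
            raise ValueError(f"group {g!r} has no runs")
    if fc_scale == "log2":
        log2_threshold = fc_threshold
    elif fc_scale == "ratio":
        log2_threshold = float(np.log2(fc_threshold))
    else:
        raise ValueError(f"unknown fc_scale {fc_scale!r}")

    accessions, fcs, ps = [], [], []
    for accession, row in run_summaries.iterrows():
        a = row[runs_by_group[groups[0]]].dropna().to_numpy(dtype=float)
        b = row[runs_by_group[groups[1]]].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        fc = float(b.mean() - a.mean())
        if len(a) >= 2 and len(b) >= 2:
            p = float(stats.ttest_ind(b, a, equal_var=True).pvalue)
        else:
            p = np.nan
        accessions.append(str(accession))
        fcs.append(fc)
        ps.append(p)

    tested = [i for i, p in enumerate(ps) if np.isfinite(p)]
    adj = np.full(len(ps), np.nan)
    if tested:
        adj[tested] = multipletests(
            [ps[i] for i in tested], method="fdr_bh"
        )[1]
    results = []
    for i, accession in enumerate(accessions):
        significant = (
            np.isfinite(adj[i])
            and abs(fcs[i]) >= log2_threshold
            and adj[i] < alpha
        )
        results.append(
            DifferentialResult(accession, fcs[i], ps[i], float(adj[i]), bool(significant))
        )
    return results


def replicate_qc(
    raw_matrix: pd.DataFrame, replicate_sets: Mapping[str, Sequence[str]]
) -> QcReport:
    """Replicate agreement: median per-feature %CV on raw intensities and
    pairwise Pearson correlation of log2 intensities.

    Replicate sets of size one are skipped with a warning.
    """
    median_cv: dict[str, float] = {}
    median_r: dict[str, float] = {}
    pairwise: dict[str, dict[tuple[str, str], float]] = {}
    skipped: list[str] = []
    for label, runs in replicate_sets.items():
        if len(runs) < 2:
            logger.warning("replicate set %r has <2 members; skipped", label)
            skipped.append(label)
            continue
        sub = raw_matrix[list(runs)].to_numpy(dtype=float)
        observed = np.isfinite(sub).sum(axis=1) >= 2
        means = np.nanmean(sub[observed], axis=1)
        sds = np.nanstd(sub[observed], axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cvs = 100.0 * sds / means
        median_cv[label] = float(np.nanmedian(cvs)) if observed.any() else np.nan

        log_sub = log2_transform(raw_matrix[list(runs)])
        correlations: dict[tuple[str, str], float] = {}
        for i, run_a in enumerate(runs):
            for run_b in runs[i + 1 :]:
                pair = log_sub[[run_a, run_b]].dropna()
                if len(pair) >= 2:
                    correlations[(run_a, run_b)] = float(
                        stats.pearsonr(pair[run_a], pair[run_b]).statistic
                    )
        pairwise[label] = correlations
        median_r[label] = (
            float(np.median(list(correlations.values()))) if correlations else np.nan
        )
    return QcReport(median_cv, median_r, pairwise, tuple(skipped))
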