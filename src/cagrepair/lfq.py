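"""Label-free proteomics differential abundance.

Implements the Perseus-style analysis stage for two-group LFQ intensity
matrices: a valid-values filter, log10 transform, missing-value
imputation from a per-sample downshifted normal distribution
(Normal(mean - downshift*sd, (width*sd)^2), the standard model for
missing-not-at-random low-abundance dropouts), an equal-variance
two-sample t-test per protein, Benjamini-Hochberg q-values (seeded
permutation FDR available as an option), and the significance call
q < 0.05 AND |fold change| >= 1.5 on the linear scale.

Sign convention: ``difference`` is mean(test group) - mean(reference
group) of log10 intensities; ``fold_change`` is the signed linear ratio
(+r for enriched in the test group, -r for depleted, |r| >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LfqMatrix",
    "filter_valid",
    "log_transform",
    "impute",
    "differential",
    "run_lfq",
]


@dataclass
class LfqMatrix:
    """Protein x sample intensity matrix with a two-group design.

    ``data``: DataFrame, proteins as index, samples as columns, NaN for
    missing.  ``groups``: sample -> group label; exactly two groups, each
    with at least two samples.  ``log_transformed`` tracks the scale.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.groups)
        if missing:
            raise ValueError("samples without group label: %s" % sorted(missing))
        labels = sorted(set(self.groups[s] for s in self.data.columns))
        if len(labels) != 2:
            raise ValueError("exactly two groups required, got %s" % labels)
        for g in labels:
            if sum(self.groups[s] == g for s in self.data.columns) < 2:
                raise ValueError("each group needs >= 2 samples")

    def group_columns(self) -> tuple[str, list[str], str, list[str]]:
        labels = sorted(set(self.groups[s] for s in self.data.columns))
        ref, test = labels[0], labels[1]
        ref_cols = [s for s in self.data.columns if self.groups[s] == ref]
        test_cols = [s for s in self.data.columns if self.groups[s] == test]
        return test, test_cols, ref, ref_cols


def filter_valid(
    matrix: LfqMatrix, min_valid: int = 3, require: str = "either"
) -> LfqMatrix:
    """Drop proteins with too few valid (non-missing) values.

    ``require="either"`` keeps a protein when at least one group has
    ``min_valid`` valid values — i.e. a protein is dropped only when it
    fails in *both* groups (the literal reading of the filter rule; a
    5-vs-0 protein is kept).  ``require="both"`` is the stricter
    alternative, demanding ``min_valid`` in each group.
    """
    if require not in ("either", "both"):
        raise ValueError("require must be 'either' or 'both'")
    _, test_cols, _, ref_cols = matrix.group_columns()
    v1 = matrix.data[ref_cols].notna().sum(axis=1)
    v2 = matrix.data[test_cols].notna().sum(axis=1)
    if require == "either":
        keep = (v1 >= min_valid) | (v2 >= min_valid)
    else:
        keep = (v1 >= min_valid) & (v2 >= min_valid)
    return LfqMatrix(matrix.data.loc[keep], matrix.groups, matrix.log_transformed)


def log_transform(matrix: LfqMatrix, base: float = 10.0) -> LfqMatrix:
    """Log-transform linear intensities; non-positive values become NaN."""
    if matrix.log_transformed:
        return matrix
    data = matrix.data.where(matrix.data > 0)
    out = np.log(data) / np.log(base)
    return LfqMatrix(out, matrix.groups, log_transformed=True)


def impute(
    matrix: LfqMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
    per_sample: bool = True,
) -> LfqMatrix:
    """Impute missing log intensities from a downshifted normal.

    Per sample (column), missing entries are drawn from
    Normal(mean_s - downshift*sd_s, (width*sd_s)^2) where mean_s/sd_s are
    the column's observed moments; with ``per_sample=False`` the moments
    are taken over the whole matrix.  Deterministic given ``seed``; a
    column with fewer than two observed values raises.
    """
    if not matrix.log_transformed:
        raise ValueError("impute operates on log-transformed intensities")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    if not per_sample:
        obs = data.values[~np.isnan(data.values)]
        if obs.size < 2:
            raise ValueError("not enough observed values to impute")
        g_mean, g_sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
    for col in data.columns:
        x = data[col]
        mask = x.isna()
        if not mask.any():
            continue
        if per_sample:
            obs = x.dropna()
            if len(obs) < 2:
                raise ValueError("sample %r has < 2 observed values" % col)
            mean_s, sd_s = float(obs.mean()), float(obs.std(ddof=1))
        else:
            mean_s, sd_s = g_mean, g_sd
        draws = rng.normal(mean_s - downshift * sd_s, width * sd_s, size=int(mask.sum()))
        data.loc[mask, col] = draws
    return LfqMatrix(data, matrix.groups, log_transformed=True)


def differential(
    matrix: LfqMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    equal_var: bool = True,
    fdr: str = "bh",
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-protein two-sample t-test with FDR control.

    Returns a DataFrame indexed by protein with columns difference (log10
    mean difference, test - reference), fold_change (signed linear), p, q,
    significant, n_valid_test, n_valid_ref.  ``fdr`` is "bh"
    (Benjamini-Hochberg) or "permutation" (seeded group-label
    permutations).  Swapping the group labels negates every difference.
    """
    if not matrix.log_transformed:
        raise ValueError("differential operates on log-transformed intensities")
    test, test_cols, ref, ref_cols = matrix.group_columns()
    a = matrix.data[test_cols].values
    b = matrix.data[ref_cols].values
    diff = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0
    if fdr == "bh":
        q = multipletests(p, method="fdr_bh")[1]
    elif fdr == "permutation":
        q = _permutation_fdr(matrix.data[test_cols + ref_cols].values,
                             len(test_cols), np.abs(t), equal_var,
                             n_permutations, seed)
    else:
        raise ValueError("fdr must be 'bh' or 'permutation'")
    log_base = 10.0
    fold = np.where(diff >= 0, log_base ** diff, -(log_base ** (-diff)))
    significant = (q < alpha) & (log_base ** np.abs(diff) >= fc_threshold)
    return pd.DataFrame(
        {
            "difference": diff,
            "fold_change": fold,
            "p": p,
            "q": q,
            "significant": significant,
            "n_valid_%s" % test: np.sum(~np.isnan(a), axis=1),
            "n_valid_%s" % ref: np.sum(~np.isnan(b), axis=1),
        },
        index=matrix.data.index,
    )


def _permutation_fdr(values, n_test, abs_t, equal_var, n_permutations, seed):
    """Permutation estimate of the FDR at each protein's |t| threshold."""
    rng = np.random.default_rng(seed)
    n_samples = values.shape[1]
    null_exceed = np.zeros_like(abs_t, dtype=float)
    order = np.argsort(-abs_t)
    sorted_abs = abs_t[order]
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        a = values[:, perm[:n_test]]
        b = values[:, perm[n_test:]]
        t_perm, _ = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
        t_perm = np.abs(np.asarray(t_perm, dtype=float))
        t_perm = t_perm[np.isfinite(t_perm)]
        # count permuted statistics >= each observed threshold
        counts = len(t_perm) - np.searchsorted(np.sort(t_perm), sorted_abs, side="left")
        null_exceed[order] += counts
    null_mean = null_exceed / n_permutations
    observed = np.arange(1, len(sorted_abs) + 1)  # of sorted thresholds
    q_sorted = np.minimum.accumulate((null_mean[order] / observed)[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_lfq(
    data: pd.DataFrame,
    groups: dict[str, str],
    min_valid: int = 3,
    require: str = "either",
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
    **diff_kwargs,
) -> pd.DataFrame:
    """Filter -> log10 -> impute -> differential, in one call."""
    m = LfqMatrix(data, groups)
    m = filter_valid(m, min_valid=min_valid, require=require)
    m = log_transform(m)
    m = impute(m, width=width, downshift=downshift, seed=seed)
    return differential(m, seed=seed, **diff_kwargs)
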