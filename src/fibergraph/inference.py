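"""Two-group inference: nuisance regression, permutation tests, FDR.

The procedure mirrors the standard connectome group-comparison chain: each
network measure is first regressed on the nuisance covariates (age, gender,
education, intracranial volume) by ordinary least squares; the residuals are
then compared between groups with a label-permutation test on the difference
of group means; and p-values within each family (global measures, 90 nodes,
tested edges) are corrected by the Benjamini-Hochberg false discovery rate.

The group difference sign convention is ``first group - second group``
(AD - NC by default), so a deficit in the patient group is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cohort import Subject, covariate_frame
from .matrices import ConnectivityMatrix
from .metrics import (
    compute_global_measures,
    compute_nodal_measures,
    identify_hubs,
    nodal_efficiency,
    shortest_paths,
)

__all__ = [
    "regress_covariates",
    "permutation_test",
    "fdr_correct",
    "compare_global",
    "compare_regional",
    "compare_local",
    "GLOBAL_MEASURES",
]

#: Global measures reported in a group comparison, in table order.
GLOBAL_MEASURES = ("e_glob", "e_loc", "gamma", "lam", "sigma")

_TIE_EPS = 1e-12


def regress_covariates(
    values: np.ndarray | Sequence[float], covariates: pd.DataFrame
) -> np.ndarray:
    """OLS residuals of a measure on intercept + nuisance covariates.

    The residuals are exactly orthogonal to every covariate column (and to
    the intercept, hence mean zero).  Raises on a rank-deficient design,
    naming the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("measure vector contains non-finite values")
    X = covariates.to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"measure length {y.shape[0]} != cohort size {X.shape[0]}"
        )
    design = sm.add_constant(X, has_constant="add")
    if y.shape[0] <= design.shape[1]:
        raise ValueError(
            f"cohort size {y.shape[0]} too small for "
            f"{design.shape[1] - 1} covariates + intercept"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cols = list(covariates.columns)
        involved = [
            cols[c - 1]
            for c in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, c, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {involved}")
    resid = np.asarray(sm.OLS(y, design).fit().resid)
    # a measure fully explained by the design (e.g. constant) leaves only
    # rounding noise; snap it to exact zero so permutation p-values tie at 1
    scale = max(1.0, float(np.max(np.abs(y))))
    if np.max(np.abs(resid)) <= 1e-10 * scale:
        resid = np.zeros_like(resid)
    return resid


def _group_masks(
    groups: Sequence[str], group_labels: tuple[str, str] | None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    groups = np.asarray(groups)
    present = list(dict.fromkeys(groups))
    if group_labels is None:
        if len(present) != 2:
            raise ValueError(
                f"need exactly two group labels, found {present}"
            )
        group_labels = (present[0], present[1])
    a, b = group_labels
    mask_a = groups == a
    mask_b = groups == b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"each group needs >= 2 subjects (got {a}: {int(mask_a.sum())}, "
            f"{b}: {int(mask_b.sum())})"
        )
    return mask_a, mask_b, group_labels


def _permutation_pvalues(
    residuals: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_perm: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed permutation p for each column of a residual matrix.

    All columns share the same label permutations, as they belong to one
    family of tests on the same subjects.  Returns ``(p, t_obs)`` where the
    statistic is the difference of group means and
    ``p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1)``.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    if R.shape[0] != mask_a.size:
        R = R.T
    n = mask_a.size
    w = np.zeros(n)
    w[mask_a] = 1.0 / mask_a.sum()
    w[mask_b] = -1.0 / mask_b.sum()
    t_obs = w @ R
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    for k in range(n_perm):
        perms[k] = rng.permutation(n)
    t_perm = w[perms] @ R  # (n_perm, n_columns)
    thresh = np.abs(t_obs) - _TIE_EPS * np.maximum(1.0, np.abs(t_obs))
    exceed = (np.abs(t_perm) >= thresh).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return p, t_obs


def permutation_test(
    residuals: np.ndarray | Sequence[float],
    groups: Sequence[str],
    n_perm: int = 5000,
    seed: int | None = None,
    group_labels: tuple[str, str] | None = None,
) -> tuple[float, float]:
    """Two-tailed label-permutation test on the difference of group means.

    Returns ``(p_value, observed_difference)`` with the difference signed
    as ``group_labels[0] - group_labels[1]``.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    mask_a, mask_b, _ = _group_masks(groups, group_labels)
    p, t_obs = _permutation_pvalues(
        np.asarray(residuals, dtype=float).reshape(-1, 1),
        mask_a,
        mask_b,
        n_perm,
        seed,
    )
    return float(p[0]), float(t_obs[0])


def fdr_correct(p_values: np.ndarray | Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    flags, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return flags


def _comparison_row(
    name: str,
    raw: np.ndarray,
    resid: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    labels: tuple[str, str],
    p: float,
) -> dict:
    a, b = labels
    return {
        "measure": name,
        f"mean_{a}": float(raw[mask_a].mean()),
        f"sd_{a}": float(raw[mask_a].std(ddof=1)),
        f"mean_{b}": float(raw[mask_b].mean()),
        f"sd_{b}": float(raw[mask_b].std(ddof=1)),
        "difference": float(resid[mask_a].mean() - resid[mask_b].mean()),
        "p_value": p,
    }


def _cohort_arrays(cohort: Sequence[Subject]):
    groups = [s.group for s in cohort]
    covs = covariate_frame(cohort)
    return groups, covs


@dataclass(frozen=True)
class GlobalComparison:
    """Table-shaped result of the global-level group comparison."""

    table: pd.DataFrame


def compare_global(
    cohort: Sequence[Subject],
    measures: Sequence[str] = GLOBAL_MEASURES,
    n_nulls: int = 100,
    swap_fraction: float = 0.5,
    n_iter: int = 1000,
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int | None = None,
    group_labels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Group comparison of global network measures.

    For each requested measure the table reports raw group means +/- SD,
    the covariate-regressed group difference (first label minus second), the
    permutation p-value and the FDR flag across the measure family.  The
    small-world ratios require a null ensemble (``n_nulls > 0``).
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    groups, covs = _cohort_arrays(cohort)
    mask_a, mask_b, labels = _group_masks(groups, group_labels)
    needs_nulls = any(m in ("gamma", "lam", "sigma") for m in measures)
    if needs_nulls and n_nulls < 1:
        raise ValueError("small-world measures need n_nulls >= 1")
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(len(cohort) + 1)
    perm_seed = int(subj_seeds[-1])
    values = {m: np.empty(len(cohort)) for m in measures}
    for idx, subj in enumerate(cohort):
        gm = compute_global_measures(
            subj.matrix,
            n_nulls=n_nulls if needs_nulls else 0,
            swap_fraction=swap_fraction,
            n_iter=n_iter,
            seed=int(subj_seeds[idx]),
        )
        for m in measures:
            values[m][idx] = getattr(gm, m)
    resid = {m: regress_covariates(values[m], covs) for m in measures}
    R = np.column_stack([resid[m] for m in measures])
    p, _ = _permutation_pvalues(R, mask_a, mask_b, n_perm, perm_seed)
    rows = [
        _comparison_row(m, values[m], resid[m], mask_a, mask_b, labels, float(p[k]))
        for k, m in enumerate(measures)
    ]
    table = pd.DataFrame(rows)
    table["significant"] = fdr_correct(table["p_value"].to_numpy(), q)
    return table


def _group_mean_matrix(
    cohort: Sequence[Subject], mask: np.ndarray
) -> ConnectivityMatrix:
    stack = np.stack([s.matrix.weights for s, m in zip(cohort, mask) if m])
    return ConnectivityMatrix(stack.mean(axis=0))


def compare_regional(
    cohort: Sequence[Subject],
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int | None = None,
    group_labels: tuple[str, str] | None = None,
    atlas_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Per-node comparison of nodal efficiency, plus per-group hub lists.

    Returns a 90-row table (one per region) with raw group means +/- SD,
    regressed difference, permutation p and FDR flag, and a dict mapping
    each group label to the 1-based indices of its hubs, computed on the
    group-mean network.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    groups, covs = _cohort_arrays(cohort)
    mask_a, mask_b, labels = _group_masks(groups, group_labels)
    eff = np.stack(
        [nodal_efficiency(shortest_paths(s.matrix)) for s in cohort]
    )  # (n_subjects, n_nodes)
    n_nodes = eff.shape[1]
    resid = np.column_stack(
        [regress_covariates(eff[:, j], covs) for j in range(n_nodes)]
    )
    p, _ = _permutation_pvalues(resid, mask_a, mask_b, n_perm, seed)
    flags = fdr_correct(p, q)
    rows = []
    for j in range(n_nodes):
        row = _comparison_row(
            atlas_labels[j] if atlas_labels is not None else f"node_{j + 1}",
            eff[:, j],
            resid[:, j],
            mask_a,
            mask_b,
            labels,
            float(p[j]),
        )
        row["node"] = j + 1
        row["significant"] = bool(flags[j])
        rows.append(row)
    table = pd.DataFrame(rows)
    hubs = {}
    for label, mask in zip(labels, (mask_a, mask_b)):
        mean_net = _group_mean_matrix(cohort, mask)
        hub_flags = identify_hubs(nodal_efficiency(shortest_paths(mean_net)))
        hubs[label] = [int(i) + 1 for i in np.nonzero(hub_flags)[0]]
    return table, hubs


def compare_local(
    cohort: Sequence[Subject],
    min_prevalence: float = 0.5,
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int | None = None,
    group_labels: tuple[str, str] | None = None,
    atlas_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-connection comparison of fiber counts.

    An edge qualifies for testing when it is present (nonzero after
    thresholding) in at least ``min_prevalence`` of the subjects of at
    least one group.  The table reports, per qualifying edge, raw group
    means +/- SD, regressed difference, permutation p, the uncorrected
    p < 0.05 flag and the FDR flag, and a direction label ("stronger in
    <first group>" / "weaker in <first group>").
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    groups, covs = _cohort_arrays(cohort)
    mask_a, mask_b, labels = _group_masks(groups, group_labels)
    stack = np.stack([s.matrix.weights for s in cohort])
    n = stack.shape[1]
    iu, jv = np.triu_indices(n, k=1)
    present = stack[:, iu, jv] > 0  # (n_subjects, n_pairs)
    prev_a = present[mask_a].mean(axis=0)
    prev_b = present[mask_b].mean(axis=0)
    qualifying = np.nonzero(
        (prev_a >= min_prevalence) | (prev_b >= min_prevalence)
    )[0]
    if qualifying.size == 0:
        return pd.DataFrame(
            columns=["edge", "node_a", "node_b", "p_value", "significant"]
        )
    counts = stack[:, iu[qualifying], jv[qualifying]]
    resid = np.column_stack(
        [
            regress_covariates(counts[:, k], covs)
            for k in range(qualifying.size)
        ]
    )
    p, t_obs = _permutation_pvalues(resid, mask_a, mask_b, n_perm, seed)
    flags = fdr_correct(p, q)
    a_label = labels[0]
    rows = []
    for k, edge_idx in enumerate(qualifying):
        i, j = int(iu[edge_idx]), int(jv[edge_idx])
        if atlas_labels is not None:
            edge_name = f"{atlas_labels[i]}-{atlas_labels[j]}"
        else:
            edge_name = f"{i + 1}-{j + 1}"
        row = _comparison_row(
            edge_name, counts[:, k], resid[:, k], mask_a, mask_b, labels, float(p[k])
        )
        row["node_a"] = i + 1
        row["node_b"] = j + 1
        row["edge"] = row.pop("measure")
        row["direction"] = (
            f"stronger in {a_label}" if t_obs[k] > 0 else f"weaker in {a_label}"
        )
        row["significant_uncorrected"] = bool(p[k] < 0.05)
        row["significant"] = bool(flags[k])
        rows.append(row)
    return pd.DataFrame(rows)
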