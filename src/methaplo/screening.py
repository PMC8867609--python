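"""Differentially methylated CpG (DMC) screening on array-style cohorts.

Pipeline per cohort: blacklist-flag probe removal, high-missingness probe
removal (>10%), probe-wise kNN imputation, optional normalization hook,
optional restriction to a gene list, then a per-probe two-sample t-test
with the conjunctive selection rule p < 0.05 and |delta beta| > 0.015
(both strict). Selections from two cohorts are intersected, reporting
direction concordance.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import BetaMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_THRESH = 0.05
DEFAULT_DELTA_THRESH = 0.015
DEFAULT_MAX_PROBE_MISSING = 0.10
DEFAULT_KNN_K = 10

_XY_CHROMS = {"chrX", "chrY", "X", "Y"}


def probe_blacklist_filter(bm: BetaMatrix) -> BetaMatrix:
    """Drop probes carrying any trouble flag or located on X/Y.

    Removal counts per criterion are logged at INFO level.
    """
    ann = bm.annotations
    criteria = {
        "bead": ann["bead_flag"] == 1,
        "detection": ann["detection_flag"] == 1,
        "non_cpg": ann["cpg_flag"] == 0,
        "snp": ann["snp_flag"] == 1,
        "multihit": ann["multihit_flag"] == 1,
        "xy_chrom": ann["chrom"].isin(_XY_CHROMS),
    }
    bad = pd.Series(False, index=ann.index)
    for name, mask in criteria.items():
        logger.info("blacklist filter %s: %d probes flagged", name, int(mask.sum()))
        bad |= mask
    logger.info("blacklist filter: %d of %d probes removed", int(bad.sum()), len(ann))
    return bm.select_probes(ann.index[~bad])


def drop_high_missing_probes(
    bm: BetaMatrix, threshold: float = DEFAULT_MAX_PROBE_MISSING
) -> BetaMatrix:
    """Drop probes with missing fraction strictly greater than *threshold*."""
    frac = bm.values.isna().mean(axis=1)
    keep = frac <= threshold
    logger.info("missingness filter: %d probes removed", int((~keep).sum()))
    return bm.select_probes(bm.values.index[keep])


def knn_impute(bm: BetaMatrix, k: int = DEFAULT_KNN_K) -> BetaMatrix:
    """Fill missing betas from the k nearest probes (probes as items).

    Distance between probes is plain Euclidean over jointly observed
    samples; a missing cell is replaced by the unweighted mean of the same
    sample's values at the k nearest probes observed there. Imputed values
    are clipped to [0, 1]; observed cells are never altered.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    vals = bm.values.to_numpy(dtype=float).copy()
    missing_rows = np.flatnonzero(np.isnan(vals).any(axis=1))
    if missing_rows.size == 0:
        return bm
    obs = ~np.isnan(vals)
    for i in missing_rows:
        row = vals[i]
        row_obs = obs[i]
        # squared Euclidean over jointly observed samples, per candidate probe
        diff = vals - row  # (n_probes, n_samples), NaNs propagate
        joint = obs & row_obs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d2 = np.nansum(np.where(joint, diff * diff, 0.0), axis=1)
        n_joint = joint.sum(axis=1)
        for s in np.flatnonzero(~row_obs):
            candidates = np.flatnonzero(obs[:, s] & (n_joint > 0))
            candidates = candidates[candidates != i]
            if candidates.size == 0:
                continue
            if candidates.size < k:
                warnings.warn(
                    f"probe {bm.values.index[i]!r}: only {candidates.size} "
                    f"neighbor candidates (< k={k}); using all",
                    stacklevel=2,
                )
                chosen = candidates
            else:
                order = np.argsort(d2[candidates], kind="stable")
                chosen = candidates[order[:k]]
            vals[i, s] = float(np.clip(np.mean(vals[chosen, s]), 0.0, 1.0))
    out = bm.values.copy()
    out[:] = vals
    return BetaMatrix(annotations=bm.annotations.copy(), values=out,
                      groups=bm.groups.copy())


def normalize(bm: BetaMatrix,
              method: Callable[[BetaMatrix], BetaMatrix] | None = None) -> BetaMatrix:
    """Normalization hook; identity by default (externally normalized input)."""
    return bm if method is None else method(bm)


def restrict_to_genes(bm: BetaMatrix, genes: Iterable[str]) -> BetaMatrix:
    """Keep probes whose gene annotation is in *genes*."""
    gene_set = set(genes)
    keep = bm.annotations["gene"].isin(gene_set)
    return bm.select_probes(bm.annotations.index[keep])


def read_gene_list(path) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def dmc_test(
    bm: BetaMatrix,
    p_thresh: float = DEFAULT_P_THRESH,
    delta_thresh: float = DEFAULT_DELTA_THRESH,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-probe two-sample t-test between cases and controls.

    Returns a DataFrame indexed by probe_id with mean_beta_case,
    mean_beta_control, delta_beta (case - control), t, p_value, direction
    and the conjunctive ``selected`` flag (both inequalities strict).
    Pooled-variance Student's t by default; Welch via ``welch=True``.
    """
    cases = bm.values[bm.case_ids()].to_numpy(dtype=float)
    controls = bm.values[bm.control_ids()].to_numpy(dtype=float)
    if cases.shape[1] < 2 or controls.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group")
    if np.isnan(cases).any() or np.isnan(controls).any():
        raise ValidationError("dmc_test requires a complete (imputed) matrix")

    mean_case = cases.mean(axis=1)
    mean_ctrl = controls.mean(axis=1)
    delta = mean_case - mean_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(
            cases, controls, axis=1, equal_var=not welch
        )

    # degenerate probes: zero variance in both groups
    var_case = cases.var(axis=1, ddof=1)
    var_ctrl = controls.var(axis=1, ddof=1)
    degenerate = (var_case == 0) & (var_ctrl == 0)
    equal_means = degenerate & (delta == 0)
    unequal_means = degenerate & (delta != 0)
    p_val = np.where(equal_means, 1.0, p_val)
    t_stat = np.where(equal_means, 0.0, t_stat)
    if unequal_means.any():
        warnings.warn(
            f"{int(unequal_means.sum())} probes with zero variance in both "
            "groups but unequal means; reporting p = 0",
            stacklevel=2,
        )
        p_val = np.where(unequal_means, 0.0, p_val)
        t_stat = np.where(unequal_means, np.sign(delta) * np.inf, t_stat)

    selected = (p_val < p_thresh) & (np.abs(delta) > delta_thresh)
    return pd.DataFrame(
        {
            "mean_beta_case": mean_case,
            "mean_beta_control": mean_ctrl,
            "delta_beta": delta,
            "t": t_stat,
            "p_value": p_val,
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "selected": selected,
        },
        index=bm.values.index,
    )


def intersect_dmcs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Probes selected in both cohorts, with direction concordance.

    Direction is reported from cohort A; discordant probes are flagged,
    not dropped. Hypo/hyper summary counts are logged.
    """
    sel_a = a.index[a["selected"]]
    sel_b = b.index[b["selected"]]
    common = sel_a.intersection(sel_b)
    out = pd.DataFrame(
        {
            "delta_beta_a": a.loc[common, "delta_beta"],
            "delta_beta_b": b.loc[common, "delta_beta"],
            "p_value_a": a.loc[common, "p_value"],
            "p_value_b": b.loc[common, "p_value"],
            "direction": a.loc[common, "direction"],
            "concordant": (
                a.loc[common, "direction"] == b.loc[common, "direction"]
            ),
        }
    )
    n_hyper = int((out["direction"] == "hyper").sum())
    n_hypo = int((out["direction"] == "hypo").sum())
    logger.info(
        "DMC intersection: %d probes (%d hyper, %d hypo, %d discordant)",
        len(out), n_hyper, n_hypo, int((~out["concordant"]).sum()),
    )
    return out


def screen_cohorts(
    bm1: BetaMatrix,
    bm2: BetaMatrix,
    genes: Iterable[str] | None = None,
    p_thresh: float = DEFAULT_P_THRESH,
    delta_thresh: float = DEFAULT_DELTA_THRESH,
    max_probe_missing: float = DEFAULT_MAX_PROBE_MISSING,
    k: int = DEFAULT_KNN_K,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full two-cohort screen; returns (dmc_a, dmc_b, intersection)."""
    results = []
    for bm in (bm1, bm2):
        bm = drop_high_missing_probes(bm, max_probe_missing)
        bm = knn_impute(bm, k=k)
        bm = probe_blacklist_filter(bm)
        bm = normalize(bm)
        if genes is not None:
            bm = restrict_to_genes(bm, genes)
        results.append(dmc_test(bm, p_thresh, delta_thresh, welch=welch))
    return results[0], results[1], intersect_dmcs(results[0], results[1])
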