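"""Seed-based structural covariance (SC) interaction mapping.

SC asks whether the across-subject coupling between a seed region's mean
GMV and voxel-wise GMV differs between two patient groups.  Per voxel j
the model

    seed_i = b0 + b1 * voxel_ij + b2 * group_i + b3 * (voxel_ij * group_i)
             + covariates + error

is fit by least squares with the seed mean GMV as the response, and the
interaction coefficient b3 is tested by a Student t.  Group is coded
NAD=0 / AD=1, so reduced coupling in the anxious-depressed group appears
as negative b3.  Voxel-wise Benjamini-Hochberg FDR over the two-sided
interaction p-values selects significant voxels, which are then grouped
into clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr
from .vbm import (
    CONNECTIVITY_26,
    Cluster,
    StatMap,
    _clusters_from_binary,
    _flatten,
    extract_cluster_gmv,
)

__all__ = ["seed_series", "interaction_map", "sc_significant_clusters"]


def seed_series(stack, seed_cluster) -> np.ndarray:
    """Per-subject mean GMV over the seed voxels (same contract as
    :func:`anxvbm.vbm.extract_cluster_gmv`, re-exported for pipeline clarity)."""
    return extract_cluster_gmv(stack, seed_cluster)


def _covariate_columns(cohort: pd.DataFrame,
                       covariate_names=("age", "sex", "education")) -> np.ndarray:
    cols = []
    for c in covariate_names:
        if c == "sex":
            cols.append((cohort["sex"].to_numpy() == "M").astype(float))
        else:
            cols.append(cohort[c].to_numpy(float))
    if "site" in cohort:
        sites = cohort["site"].to_numpy()
        for s in sorted(pd.unique(sites))[1:]:
            cols.append((sites == s).astype(float))
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def interaction_map(
    stack,
    seed_values: np.ndarray,
    cohort: pd.DataFrame,
    groups: tuple[str, str] = ("NAD", "AD"),
    mask: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    exclude_voxels: np.ndarray | None = None,
) -> StatMap:
    """t-map of the seed-by-group interaction slope over in-mask voxels.

    ``groups`` is (reference, coded-1): with the default, AD is coded 1 and a
    lower AD coupling slope yields negative t.  Only subjects of the two
    groups may be present in ``cohort``/``stack``.  ``exclude_voxels``
    (typically the seed) are removed from the search volume; voxels whose
    GMV is constant across subjects are set undefined and counted.
    """
    arr, shape = _flatten(stack)
    n = arr.shape[0]
    if len(cohort) != n or len(seed_values) != n:
        raise ValueError("stack, cohort and seed series must be aligned")
    glabels = cohort["group"].to_numpy()
    extra = set(glabels) - set(groups)
    if extra:
        raise ValueError(f"subjects outside the compared groups: {sorted(extra)}")
    g = (glabels == groups[1]).astype(float)
    if covariates is None:
        covariates = _covariate_columns(cohort)
    covariates = np.atleast_2d(np.asarray(covariates, float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    if covariates.size == 0:
        covariates = covariates.reshape(n, 0)

    if mask is None:
        mask = np.ones(shape, dtype=bool)
    search = mask.copy()
    if exclude_voxels is not None:
        search &= ~exclude_voxels
    V = arr[:, search]                       # n x v voxel GMV
    y = np.asarray(seed_values, float)

    # fixed columns: intercept, group, covariates; varying: Tj and Tj*group
    fixed = np.column_stack([np.ones(n), g, covariates])
    p = fixed.shape[1] + 2
    dfe = n - p
    if dfe <= 0:
        raise ValueError("too few subjects for the interaction model")
    nvox = V.shape[1]
    tvals = np.full(nvox, np.nan)
    betas = np.full(nvox, np.nan)
    b3_col = 1 + 1  # position of Tj*group in [Tj, Tj*g, fixed...] below
    for j in range(nvox):
        tj = V[:, j]
        if np.ptp(tj) <= 1e-12 * (abs(tj).max() + 1.0):
            continue
        X = np.column_stack([tj, tj * g, fixed])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            continue
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / dfe
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        if se == 0.0 or not np.isfinite(se):
            continue
        tvals[j] = beta[1] / se
        betas[j] = beta[1]
    vol = np.full(shape, np.nan)
    vol[search] = tvals
    sm = StatMap(vol, "t", float(dfe), search,
                 n_undefined=int(np.isnan(tvals).sum()))
    bvol = np.full(shape, np.nan)
    bvol[search] = betas
    sm.beta_interaction = bvol  # slope-difference estimate (group-1 minus reference)
    return sm


def sc_significant_clusters(
    statmap: StatMap,
    q: float = 0.05,
    connectivity: np.ndarray = CONNECTIVITY_26,
    affine: np.ndarray | None = None,
) -> list[Cluster]:
    """Voxel-wise BH-FDR on the interaction map, then clustering of survivors.

    Each surviving cluster carries the sign of the interaction slope at its
    peak in ``label``: "lower coupling in coded group" for negative peaks.
    """
    if affine is None:
        affine = np.eye(4)
    inside = statmap.mask & np.isfinite(statmap.values)
    if q <= 0 or not inside.any():
        return []
    p = statmap.p_values()[inside]
    rejected, _ = bh_fdr(p, q)
    survivors = np.zeros(statmap.values.shape, dtype=bool)
    survivors[inside] = rejected
    clusters = []
    for signed in (survivors & (statmap.values > 0), survivors & (statmap.values < 0)):
        clusters.extend(
            _clusters_from_binary(signed, statmap.values, affine, connectivity)
        )
    for c in clusters:
        c.label = (
            "lower coupling in coded group" if c.peak_value < 0
            else "higher coupling in coded group"
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters
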