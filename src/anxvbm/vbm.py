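"""Mass-univariate voxel-wise GMV inference with cluster-level correction.

The group model is a per-voxel ANCOVA: GMV ~ intercept + group + age +
sex + education + site, tested by a partial F on the group block.  Post-hoc
pairwise contrasts are t-maps on the same covariate-adjusted model.
Multiple-comparison control follows the dual-threshold convention: an
uncorrected voxel-forming threshold (p < 0.001 by default), connected
clusters under 26-neighbour connectivity, a permutation null of cluster
sizes (group labels shuffled within site strata), and Benjamini-Hochberg
FDR over the observed clusters' size p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .stats import bh_fdr, partial_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "StatMap",
    "Cluster",
    "build_design",
    "voxelwise_ancova",
    "posthoc_t",
    "label_clusters",
    "dual_threshold_clusters",
    "extract_cluster_gmv",
    "roi_clinical_correlation",
    "age_stratified_rerun",
]

# 3x3x3 structuring element including diagonals (vertex connectivity)
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class DesignMatrix:
    """Covariate-adjusted group design aligned to an image stack."""

    matrix: np.ndarray           # n_subjects x n_columns
    column_names: list[str]
    group_columns: list[str]     # names of the group-indicator columns
    groups: np.ndarray           # per-subject group label
    sites: np.ndarray            # per-subject site label (strata for permutation)
    metadata: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def group_block_index(self) -> np.ndarray:
        return np.array([self.column_names.index(c) for c in self.group_columns])


@dataclass
class StatMap:
    """Voxel-wise statistic image on a mask."""

    values: np.ndarray           # 3D, NaN outside mask / undefined voxels
    kind: str                    # "t" or "F"
    df: float | tuple[float, float]
    mask: np.ndarray
    n_undefined: int = 0

    def p_values(self) -> np.ndarray:
        """Voxel-wise uncorrected p (two-sided for t)."""
        p = np.full(self.values.shape, np.nan)
        inside = self.mask & np.isfinite(self.values)
        v = self.values[inside]
        if self.kind == "F":
            p[inside] = sps.f.sf(v, *self.df)
        else:
            p[inside] = 2.0 * sps.t.sf(np.abs(v), self.df)
        return p


@dataclass
class Cluster:
    voxel_indices: np.ndarray    # k x 3 integer voxel coordinates
    size: int
    peak_value: float
    peak_index: tuple[int, int, int]
    peak_mni: tuple[float, float, float]
    p_value: float | None = None
    p_adjusted: float | None = None
    label: str | None = None


def build_design(
    cohort: pd.DataFrame,
    covariate_names: tuple[str, ...] = ("age", "sex", "education"),
    group_coding: str | None = None,
    include_site: bool = True,
) -> DesignMatrix:
    """Build the ANCOVA design: intercept, k-1 group dummies, covariates.

    ``group_coding`` names the reference group (default: HC if present,
    else the first label in sorted order).  Sex is coded F=0/M=1; site is
    expanded to s-1 dummy columns against the first site.  Every coding
    choice is recorded in ``metadata``.
    """
    for c in covariate_names:
        if c not in cohort or cohort[c].isna().any():
            raise ValueError(f"covariate {c!r} missing for at least one subject")
    groups = cohort["group"].to_numpy()
    labels = sorted(pd.unique(groups))
    ref = group_coding or ("HC" if "HC" in labels else labels[0])
    if ref not in labels:
        raise ValueError(f"reference group {ref!r} not present")
    cols, names = [np.ones(len(cohort))], ["intercept"]
    group_cols = []
    for g in labels:
        if g == ref:
            continue
        cols.append((groups == g).astype(float))
        names.append(f"group[{g}]")
        group_cols.append(f"group[{g}]")
    for c in covariate_names:
        if c == "sex":
            cols.append((cohort["sex"].to_numpy() == "M").astype(float))
        else:
            cols.append(cohort[c].to_numpy(float))
        names.append(c)
    sites = cohort["site"].to_numpy() if "site" in cohort else np.array(["site0"] * len(cohort))
    site_levels = sorted(pd.unique(sites))
    if include_site and len(site_levels) > 1:
        for s in site_levels[1:]:
            cols.append((sites == s).astype(float))
            names.append(f"site[{s}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # find first offending column for the error message
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"design is rank deficient at column {names[j]!r}")
        raise ValueError("design is rank deficient")
    meta = {
        "reference_group": ref,
        "sex_coding": "F=0, M=1",
        "site_reference": site_levels[0],
        "covariates": list(covariate_names),
    }
    return DesignMatrix(X, names, group_cols, groups, sites, meta)


def _flatten(stack) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Accept an (n, x, y, z) array or list of 3D arrays; return (n, v) view info."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 4:
        raise ValueError("stack must be n_subjects x 3D grid")
    return arr, arr.shape[1:]


def _fit_rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y's columns on X via an orthonormal basis."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)  # explicit residuals avoid cancellation
    return np.einsum("ij,ij->j", resid, resid)


def voxelwise_ancova(stack, design: DesignMatrix, mask: np.ndarray) -> StatMap:
    """Partial F-map for the group effect at every in-mask voxel.

    Compares the full model to the model with the group columns removed;
    df = (k-1, n - rank(full)).  Voxels with (near-)zero full-model residual
    variance are set undefined and counted.
    """
    arr, shape = _flatten(stack)
    n = arr.shape[0]
    if design.matrix.shape[0] != n:
        raise ValueError("design rows do not match image stack")
    Y = arr[:, mask]  # n x v
    X = design.matrix
    gidx = design.group_block_index()
    keep = np.setdiff1d(np.arange(X.shape[1]), gidx)
    X0 = X[:, keep]
    rss1 = _fit_rss(X, Y)
    rss0 = _fit_rss(X0, Y)
    q = len(gidx)
    dfe = n - np.linalg.matrix_rank(X)
    scale = np.ptp(Y, axis=0) ** 2 + 1.0
    bad = rss1 <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / q) / (rss1 / dfe)
    f[bad] = np.nan
    vol = np.full(shape, np.nan)
    vol[mask] = f
    return StatMap(vol, "F", (float(q), float(dfe)), mask, n_undefined=int(bad.sum()))


def posthoc_t(stack, design: DesignMatrix, contrast_pair: tuple[str, str],
              mask: np.ndarray) -> StatMap:
    """t-map of the pairwise group contrast on the covariate-adjusted model.

    Positive t means the first-named group has larger adjusted GMV.
    """
    a, b = contrast_pair
    ref = design.metadata.get("reference_group")
    for g in (a, b):
        if g != ref and f"group[{g}]" not in design.column_names:
            raise ValueError(f"unknown group {g!r} in contrast")
    X = design.matrix
    n, p = X.shape
    c = np.zeros(p)
    if a != ref:
        c[design.column_names.index(f"group[{a}]")] += 1.0
    if b != ref:
        c[design.column_names.index(f"group[{b}]")] -= 1.0
    arr, shape = _flatten(stack)
    Y = arr[:, mask]
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", X @ beta, Y)
    dfe = n - np.linalg.matrix_rank(X)
    sigma2 = rss / dfe
    cvar = float(c @ XtX_inv @ c)
    scale = np.ptp(Y, axis=0) ** 2 + 1.0
    bad = rss <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * cvar)
    t[bad] = np.nan
    vol = np.full(shape, np.nan)
    vol[mask] = t
    return StatMap(vol, "t", float(dfe), mask, n_undefined=int(bad.sum()))


def label_clusters(binary: np.ndarray, connectivity: np.ndarray = CONNECTIVITY_26):
    """Connected components of a binary volume; returns (labels, n)."""
    return ndimage.label(binary, structure=connectivity)


def _clusters_from_binary(binary, statmap_values, affine, connectivity):
    labels, n = label_clusters(binary, connectivity)
    out = []
    for k in range(1, n + 1):
        idx = np.argwhere(labels == k)
        vals = statmap_values[tuple(idx.T)]
        absvals = np.abs(vals)
        # deterministic peak: max |stat|, ties broken by lowest linear index
        best = int(np.argmax(absvals))
        peak_idx = tuple(int(v) for v in idx[best])
        mni = affine @ np.array([*peak_idx, 1.0])
        out.append(
            Cluster(
                voxel_indices=idx,
                size=int(len(idx)),
                peak_value=float(vals[best]),
                peak_index=peak_idx,
                peak_mni=tuple(float(v) for v in mni[:3]),
            )
        )
    return out


def _supra_binaries(statmap: StatMap, voxel_p: float):
    """Supra-threshold binaries; t-maps split by sign so clusters are unimodal."""
    p = statmap.p_values()
    supra = statmap.mask & np.isfinite(statmap.values) & (p < voxel_p)
    if statmap.kind == "t":
        return [supra & (statmap.values > 0), supra & (statmap.values < 0)]
    return [supra]


def _permute_groups_within_sites(rng, design: DesignMatrix) -> DesignMatrix:
    """Shuffle group labels within site strata and rebuild the group columns."""
    perm = np.arange(len(design.groups))
    for s in np.unique(design.sites):
        idx = np.where(design.sites == s)[0]
        perm[idx] = idx[rng.permutation(len(idx))]
    X = design.matrix.copy()
    gidx = design.group_block_index()
    X[:, gidx] = design.matrix[perm][:, gidx]
    return DesignMatrix(
        X, design.column_names, design.group_columns,
        design.groups[perm], design.sites, design.metadata,
    )


def dual_threshold_clusters(
    statmap: StatMap,
    stack,
    design: DesignMatrix,
    voxel_p: float = 0.001,
    cluster_q: float = 0.05,
    n_perm: int = 100,
    connectivity: np.ndarray = CONNECTIVITY_26,
    affine: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    contrast_pair: tuple[str, str] | None = None,
) -> list[Cluster]:
    """Dual-threshold cluster inference with a permutation size null.

    Candidate clusters form at uncorrected voxel p < ``voxel_p``.  Group
    labels are permuted within site strata ``n_perm`` times, the map refit
    and re-thresholded, and all null cluster sizes pooled (permutations
    producing no cluster contribute a size of 0).  Each observed cluster
    gets p = (1 + #{null >= size}) / (1 + #null), and Benjamini-Hochberg at
    ``cluster_q`` over those p-values selects the survivors.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if affine is None:
        affine = np.eye(4)
    observed: list[Cluster] = []
    for binary in _supra_binaries(statmap, voxel_p):
        observed.extend(_clusters_from_binary(binary, statmap.values, affine, connectivity))
    if not observed:
        return []

    def _refit(d: DesignMatrix) -> StatMap:
        if statmap.kind == "F":
            return voxelwise_ancova(stack, d, statmap.mask)
        return posthoc_t(stack, d, contrast_pair, statmap.mask)

    if statmap.kind == "t" and contrast_pair is None:
        raise ValueError("contrast_pair required to permute a t-map")
    null_sizes: list[int] = []
    for _ in range(n_perm):
        pd_ = _permute_groups_within_sites(rng, design)
        pm = _refit(pd_)
        sizes = []
        for binary in _supra_binaries(pm, voxel_p):
            labels, nlab = label_clusters(binary, connectivity)
            if nlab:
                sizes.extend(np.bincount(labels.ravel())[1:].tolist())
        null_sizes.extend(sizes if sizes else [0])
    null_arr = np.asarray(null_sizes)
    pvals = np.array(
        [(1.0 + np.sum(null_arr >= c.size)) / (1.0 + len(null_arr)) for c in observed]
    )
    rejected, adjusted = bh_fdr(pvals, cluster_q)
    survivors = []
    for c, p, pa, rej in zip(observed, pvals, adjusted, rejected):
        c.p_value = float(p)
        c.p_adjusted = float(pa)
        if rej:
            survivors.append(c)
    survivors.sort(key=lambda c: -c.size)
    return survivors


def extract_cluster_gmv(stack, cluster: Cluster) -> np.ndarray:
    """Per-subject mean GMV over the cluster's voxels, in stack order."""
    if cluster.size == 0:
        raise ValueError("empty cluster")
    arr, shape = _flatten(stack)
    idx = cluster.voxel_indices
    if np.any(idx < 0) or np.any(idx >= np.array(shape)):
        raise ValueError("cluster voxels outside the image grid")
    return arr[:, idx[:, 0], idx[:, 1], idx[:, 2]].mean(axis=1)


def roi_clinical_correlation(
    roi_values: np.ndarray,
    hama: np.ndarray,
    cohort: pd.DataFrame,
    covariate_names: tuple[str, ...] = ("age", "sex", "education"),
    include_site: bool = True,
) -> tuple[float, float]:
    """Partial correlation of cluster GMV with anxiety score in patients.

    Controls age, sex, education and site (dummy-coded).  Callers restrict
    the inputs to the patient subjects (AD+NAD) before calling.
    """
    cols = []
    for c in covariate_names:
        if c == "sex":
            cols.append((cohort["sex"].to_numpy() == "M").astype(float))
        else:
            cols.append(cohort[c].to_numpy(float))
    if include_site and "site" in cohort:
        sites = cohort["site"].to_numpy()
        levels = sorted(pd.unique(sites))
        for s in levels[1:]:
            cols.append((sites == s).astype(float))
    Z = np.column_stack(cols) if cols else None
    if Z is not None and len(roi_values) < Z.shape[1] + 3:
        raise ValueError("too few subjects for the covariate design")
    return partial_correlation(np.asarray(roi_values, float), np.asarray(hama, float), Z)


def age_stratified_rerun(
    stack,
    cohort: pd.DataFrame,
    mask: np.ndarray,
    bounds: tuple[float, float] = (25.0, 40.0),
    voxel_p: float = 0.001,
    cluster_q: float = 0.05,
    n_perm: int = 100,
    affine: np.ndarray | None = None,
    rng_seed: int = 0,
) -> dict[str, list[Cluster]]:
    """Re-run the full ANCOVA + cluster procedure within age strata.

    Strata are ``age < lo``, ``lo <= age <= hi`` (closed middle interval)
    and ``age > hi``; age stays in the within-stratum model.  Strata with
    fewer than two subjects in any group are skipped with a warning.
    """
    lo, hi = bounds
    arr, _ = _flatten(stack)
    age = cohort["age"].to_numpy(float)
    strata = {
        f"age<{lo:g}": age < lo,
        f"{lo:g}<=age<={hi:g}": (age >= lo) & (age <= hi),
        f"age>{hi:g}": age > hi,
    }
    reports: dict[str, list[Cluster]] = {}
    for name, sel in strata.items():
        sub = cohort.loc[sel].reset_index(drop=True)
        counts = sub["group"].value_counts()
        if len(sub) == 0 or counts.size < 2 or counts.min() < 2:
            warnings.warn(f"stratum {name!r} skipped: too few subjects per group")
            continue
        # drop site dummies / constant covariates if the stratum collapses
        include_site = sub["site"].nunique() > 1 if "site" in sub else False
        covs = tuple(c for c in ("age", "sex", "education") if sub[c].nunique() > 1)
        try:
            design = build_design(sub, covariate_names=covs, include_site=include_site)
        except ValueError as e:
            warnings.warn(f"stratum {name!r} skipped: {e}")
            continue
        sm = voxelwise_ancova(arr[sel], design, mask)
        reports[name] = dual_threshold_clusters(
            sm, arr[sel], design, voxel_p, cluster_q, n_perm,
            affine=affine, rng=np.random.default_rng(rng_seed),
        )
    return reports
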