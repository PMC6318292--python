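"""Mass-univariate voxel-based lesion-symptom mapping (VLSM).

At every voxel with sufficient lesion overlap, participants are split into
lesioned and spared groups and compared on a behavioral variable with the
Brunner-Munzel rank test — a test of the relative effect
``P(X > Y) + 1/2 P(X = Y)`` that tolerates unequal variances and ties. The
standardized statistic is referred by default to Student's t with the
small-sample (Welch-type) degrees of freedom — at the overlap threshold
the lesioned group is small, where the large-sample normal reference is
anticonservative — with normal and exact-permutation references
available. The voxelwise p-values are thresholded with Benjamini-Hochberg
FDR over the analyzed voxels only, so the critical z is derived from the
data rather than fixed.

Sign convention: positive z means the lesioned group is stochastically
*larger* on the variable. Deficit variables (e.g. punishment sensitivity)
therefore produce negative z in damaged territory, while error counts
produce positive z; callers interpret the sign.

A voxel is flagged as having insufficient power when even the most extreme
possible assignment of the observed behavioral values to its lesioned
group (complete separation) could not reach the current significance
cutoff — an explicit, testable analogue of the power shading used by
lesion-mapping GUIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BMResult",
    "StatMap",
    "DensityMap",
    "DegenerateStatisticError",
    "brunner_munzel",
    "run_vlsm",
    "conjunction",
    "density_map",
    "residualize",
    "ResidualizeResult",
]

logger = logging.getLogger(__name__)


class DegenerateStatisticError(ValueError):
    """Variance estimate of the rank statistic is zero with no separation."""


@dataclass(frozen=True)
class BMResult:
    z: float
    p: float
    relative_effect: float  # P(X > Y) + 0.5 P(X = Y)
    df: float = float("nan")  # Welch-type df (t reference only)


def _relative_effect(ranks: np.ndarray, n1: int, n2: int) -> float:
    return (ranks[:n1].mean() - (n1 + 1) / 2.0) / n2


def brunner_munzel(
    x: Sequence[float],
    y: Sequence[float],
    reference: str = "t",
    alternative: str = "two-sided",
    n_perm: int = 20_000,
    max_exhaustive: int = 200_000,
    seed: int = 0,
) -> BMResult:
    """Brunner-Munzel test of ``x`` (lesioned) vs ``y`` (spared).

    Midranks handle ties. ``reference`` selects the null distribution of
    the standardized statistic:

    ``"t"`` (default)
        Student t with the Welch-type degrees of freedom of Brunner and
        Munzel's small-sample approximation; recommended whenever one
        group is small, as is typical at the overlap threshold of a
        lesion map.
    ``"normal"``
        Large-sample standard normal.
    ``"permutation"``
        p from the permutation distribution of the relative effect —
        exhaustive when the number of group assignments is at most
        ``max_exhaustive``, otherwise ``n_perm`` seeded Monte-Carlo
        draws. Exact under exchangeability; the appropriate choice when
        both groups are very small (n around 10), where any asymptotic p
        can be off by several percentage points.

    ``alternative`` sets sidedness: ``"two-sided"``, ``"greater"``
    (lesioned group stochastically larger, e.g. error counts) or
    ``"less"`` (lesioned group smaller, e.g. a deficit on a parameter).

    Complete separation with a degenerate variance estimate yields
    ``z = +/-inf``; zero variance without separation (all observations
    tied) raises :class:`DegenerateStatisticError`.
    """
    if reference not in ("t", "normal", "permutation"):
        raise ValueError("reference must be 't', 'normal' or 'permutation'")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1, r2 = ranks[:n1], ranks[n1:]
    r1m, r2m = r1.mean(), r2.mean()
    effect = _relative_effect(ranks, n1, n2)
    s1 = np.sum((r1 - stats.rankdata(x) - r1m + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    s2 = np.sum((r2 - stats.rankdata(y) - r2m + (n2 + 1) / 2.0) ** 2) / (n2 - 1)
    denom = n * np.sqrt(n1 * s1 + n2 * s2)
    if denom == 0.0 and effect == 0.5:
        raise DegenerateStatisticError("all observations tied; statistic undefined")
    if denom == 0.0:
        z = np.inf if effect > 0.5 else -np.inf
    else:
        z = n1 * n2 * (r1m - r2m) / denom
    df = np.nan
    if reference == "permutation":
        p = _permutation_pvalue(pooled, n1, n2, effect, alternative, n_perm, max_exhaustive, seed)
        return BMResult(z=float(z), p=float(p), relative_effect=float(effect))
    if reference == "t" and np.isfinite(z):
        df_den = (n1 * s1) ** 2 / (n1 - 1) + (n2 * s2) ** 2 / (n2 - 1)
        df = (n1 * s1 + n2 * s2) ** 2 / df_den
        dist = stats.t(df)
    else:
        dist = stats.norm
    if np.isinf(z):
        extreme = {"two-sided": True, "greater": z > 0, "less": z < 0}[alternative]
        p = 0.0 if extreme else 1.0
    elif alternative == "two-sided":
        p = 2.0 * dist.sf(abs(z))
    elif alternative == "greater":
        p = dist.sf(z)
    else:
        p = dist.cdf(z)
    return BMResult(z=float(z), p=float(p), relative_effect=float(effect), df=float(df))


def _permutation_pvalue(
    pooled: np.ndarray, n1: int, n2: int, observed_effect: float, alternative: str,
    n_perm: int, max_exhaustive: int, seed: int,
) -> float:
    from itertools import combinations
    from math import comb

    n = n1 + n2
    ranks_all = stats.rankdata(pooled)  # midranks are permutation-invariant
    tol = 1e-12

    def extreme(eff: float) -> bool:
        if alternative == "two-sided":
            return abs(eff - 0.5) >= abs(observed_effect - 0.5) - tol
        if alternative == "greater":
            return eff >= observed_effect - tol
        return eff <= observed_effect + tol

    if comb(n, n1) <= max_exhaustive:
        count = total = 0
        for combo in combinations(range(n), n1):
            eff = (ranks_all[list(combo)].mean() - (n1 + 1) / 2.0) / n2
            total += 1
            if extreme(eff):
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        sel = rng.permutation(n)[:n1]
        eff = (ranks_all[sel].mean() - (n1 + 1) / 2.0) / n2
        if extreme(eff):
            count += 1
    # include the identity assignment so the MC p is never 0
    return (count + 1) / (n_perm + 1)


@dataclass
class StatMap:
    """Voxelwise statistics on the template grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    z: np.ndarray  # float, NaN outside analyzed voxels
    p: np.ndarray  # float, NaN outside analyzed voxels
    significant: np.ndarray  # bool: passes FDR
    analyzed: np.ndarray  # bool: overlap >= min_overlap and statistic defined
    low_power: np.ndarray  # bool: analyzed but cannot reach the cutoff
    n_lesioned: np.ndarray  # int: per-voxel lesion overlap
    fdr_q: float
    min_overlap: int
    alternative: str
    p_crit: float  # BH-derived p cutoff (NaN if nothing significant)
    z_crit: float  # equivalent-normal quantile of p_crit (or of the minimal BH hurdle)
    reference: str = "t"

    def peak_table(self, n_peaks: int = 10) -> pd.DataFrame:
        """Top significant voxels by |z| with index and world coordinates."""
        idx = np.argwhere(self.significant)
        if len(idx) == 0:
            return pd.DataFrame(columns=["i", "j", "k", "x", "y", "z_mm", "z", "p"])
        zvals = self.z[tuple(idx.T)]
        order = np.argsort(-np.abs(zvals))[:n_peaks]
        rows = []
        for o in order:
            i, j, k = idx[o]
            world = self.affine @ np.array([i, j, k, 1.0])
            rows.append(
                {"i": int(i), "j": int(j), "k": int(k),
                 "x": world[0], "y": world[1], "z_mm": world[2],
                 "z": float(self.z[i, j, k]), "p": float(self.p[i, j, k])}
            )
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path, prefix: str = "vlsm") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, data, dtype in [
            ("z", self.z, np.float32),
            ("sig", self.significant, np.uint8),
            ("analyzed", self.analyzed, np.uint8),
            ("low_power", self.low_power, np.uint8),
            ("overlap", self.n_lesioned, np.int16),
        ]:
            img = nib.Nifti1Image(np.asarray(data, dtype=dtype), self.affine)
            nib.save(img, outdir / f"{prefix}_{name}.nii.gz")


def _min_achievable_p(y_sorted: np.ndarray, n1: int, alternative: str, reference: str) -> float:
    """Smallest p achievable for group sizes (n1, n-n1): the most extreme
    assignment puts the top-n1 or bottom-n1 values in the lesioned group."""
    best = 1.0
    for xs, ys in ((y_sorted[-n1:], y_sorted[:-n1]), (y_sorted[:n1], y_sorted[n1:])):
        try:
            best = min(best, brunner_munzel(xs, ys, reference=reference, alternative=alternative).p)
        except DegenerateStatisticError:
            continue
    return best


def run_vlsm(
    masks: np.ndarray,
    y: Sequence[float],
    affine: np.ndarray | None = None,
    min_overlap: int = 12,
    fdr_q: float = 0.01,
    alternative: str = "two-sided",
    reference: str = "t",
) -> StatMap:
    """Voxelwise Brunner-Munzel map of ``y`` over a stack of lesion masks.

    Parameters
    ----------
    masks : (n_participants, nx, ny, nz) boolean array
        Binary lesion masks on a shared grid.
    y : (n_participants,) behavioral variable
        Model parameter or WCST score; must be defined for everyone.
    min_overlap : int
        Voxels lesioned in fewer participants are excluded from analysis.
    fdr_q : float
        Benjamini-Hochberg level applied over the analyzed voxels.
    alternative : str
        Sidedness of the voxelwise test; ``"less"`` maps deficits
        (lesioned group lower on ``y``), ``"greater"`` maps elevations
        (e.g. error counts), ``"two-sided"`` maps both.
    reference : str
        ``"t"`` (default, small-sample approximation — the overlap
        threshold makes the lesioned group small) or ``"normal"``.
    """
    masks = np.asarray(masks, dtype=bool)
    y = np.asarray(y, dtype=float)
    if masks.ndim != 4 or masks.shape[0] != len(y):
        raise ValueError("masks must be (n_participants, nx, ny, nz) matching len(y)")
    if np.any(~np.isfinite(y)):
        raise ValueError("behavioral variable contains non-finite values")
    n, shape = masks.shape[0], masks.shape[1:]
    affine = np.eye(4) if affine is None else np.asarray(affine)

    flat = masks.reshape(n, -1)
    counts = flat.sum(axis=0)
    analyzed_flat = (counts >= min_overlap) & (counts <= n - 2)
    z_flat = np.full(flat.shape[1], np.nan)
    p_flat = np.full(flat.shape[1], np.nan)

    cols = np.flatnonzero(analyzed_flat)
    if len(cols) == 0:
        logger.warning("no voxel reaches the minimum lesion overlap of %d", min_overlap)
    else:
        # many voxels share the same lesioned set; test each pattern once
        patterns, inverse = np.unique(flat[:, cols], axis=1, return_inverse=True)
        for k in range(patterns.shape[1]):
            sel = patterns[:, k]
            try:
                res = brunner_munzel(y[sel], y[~sel], reference=reference, alternative=alternative)
                zk, pk = res.z, res.p
            except DegenerateStatisticError:
                zk, pk = np.nan, np.nan
            here = cols[inverse == k]
            z_flat[here] = zk
            p_flat[here] = pk
        undefined = np.isnan(p_flat[cols])
        if undefined.any():
            analyzed_flat[cols[undefined]] = False
            cols = cols[~undefined]

    sig_flat = np.zeros(flat.shape[1], dtype=bool)
    p_crit = np.nan
    tail_div = 2.0 if alternative == "two-sided" else 1.0
    if len(cols) > 0:
        reject, _, _, _ = multipletests(p_flat[cols], alpha=fdr_q, method="fdr_bh")
        sig_flat[cols] = reject
        if reject.any():
            p_crit = float(p_flat[cols][reject].max())
            z_crit = float(stats.norm.isf(p_crit / tail_div))
        else:
            z_crit = float(stats.norm.isf(fdr_q / len(cols) / tail_div))
    else:
        z_crit = np.inf

    # power flag: can this voxel's group sizes reach the cutoff at all?
    low_power_flat = np.zeros(flat.shape[1], dtype=bool)
    if len(cols) > 0:
        p_cutoff = p_crit if np.isfinite(p_crit) else fdr_q / len(cols)
        y_sorted = np.sort(y)
        cache: dict[int, float] = {}
        for c in cols:
            n1 = int(counts[c])
            if n1 not in cache:
                cache[n1] = _min_achievable_p(y_sorted, n1, alternative, reference)
            low_power_flat[c] = cache[n1] > p_cutoff

    return StatMap(
        shape=tuple(shape),
        affine=affine,
        z=z_flat.reshape(shape),
        p=p_flat.reshape(shape),
        significant=sig_flat.reshape(shape),
        analyzed=analyzed_flat.reshape(shape),
        low_power=low_power_flat.reshape(shape),
        n_lesioned=counts.reshape(shape).astype(np.int64),
        fdr_q=fdr_q,
        min_overlap=min_overlap,
        alternative=alternative,
        reference=reference,
        p_crit=p_crit,
        z_crit=z_crit,
    )


def conjunction(map_a: StatMap, map_b: StatMap) -> np.ndarray:
    """Three-valued overlay of two thresholded maps.

    Returns an int8 volume: 0 neither, 1 only ``map_a``, 2 only ``map_b``,
    3 both. This is descriptive overlap, not an interaction statistic.
    """
    if map_a.shape != map_b.shape or not np.allclose(map_a.affine, map_b.affine):
        raise ValueError("maps must share grid and affine")
    out = np.zeros(map_a.shape, dtype=np.int8)
    out[map_a.significant & ~map_b.significant] = 1
    out[~map_a.significant & map_b.significant] = 2
    out[map_a.significant & map_b.significant] = 3
    return out


@dataclass(frozen=True)
class DensityMap:
    counts: np.ndarray
    threshold: int
    mask: np.ndarray  # counts > threshold


def density_map(masks: np.ndarray, threshold: int = 8) -> DensityMap:
    """Per-voxel lesion counts and the ``count > threshold`` mask."""
    masks = np.asarray(masks, dtype=bool)
    counts = masks.sum(axis=0).astype(np.int64)
    return DensityMap(counts=counts, threshold=threshold, mask=counts > threshold)


@dataclass
class ResidualizeResult:
    residuals: pd.Series  # NaN where covariate rows were dropped
    correlation: float  # Pearson r between residuals and original variable
    dropped: list[str]
    columns: list[str]


def residualize(variable: pd.Series, covariates: pd.DataFrame) -> ResidualizeResult:
    """Least-squares residuals of ``variable`` on ``covariates`` + intercept.

    Rows with missing covariates are dropped (and reported); a
    rank-deficient design raises with the names of the collinear columns.
    Also reports the Pearson correlation between the residuals and the
    original variable — near 1 indicates the confounds carry little of the
    variable's variance.
    """
    covariates = covariates.loc[variable.index]
    keep = covariates.notna().all(axis=1) & variable.notna()
    dropped = [str(i) for i in variable.index[~keep]]
    if dropped:
        logger.warning("residualize: dropping %d rows with missing values", len(dropped))
    X = covariates.loc[keep].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [
            col
            for j, col in enumerate(covariates.columns)
            if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    yv = variable.loc[keep].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    out = pd.Series(np.nan, index=variable.index, name=f"{variable.name}_resid")
    out.loc[keep] = resid
    if np.std(resid) > 0 and np.std(yv) > 0:
        corr = float(stats.pearsonr(resid, yv).statistic)
    else:
        corr = np.nan
    return ResidualizeResult(residuals=out, correlation=corr, dropped=dropped, columns=list(covariates.columns))
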