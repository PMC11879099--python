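"""Community stability (AVD), nutrient distances, Mantel tests and regressions.

The average variation degree (AVD) summarizes how far each sample's taxon
abundances deviate from their group means in units of the within-group
standard deviation; lower AVD means a more stable community. Soil-nutrient
structure enters as a Euclidean distance matrix over z-scored covariates,
related to community matrices via Mantel tests, and the stochasticity-
stability linkage is an ordinary least squares fit of pairwise NST values on
pairwise nutrient distances (or on pairwise AVD differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    NoUsableTaxaError,
    ValidationError,
)
from .types import SOIL_VARS, CommunityTable
from .assembly import NstResult


# ---------------------------------------------------------------------------
# AVD
# ---------------------------------------------------------------------------

@dataclass
class AvdReport:
    """Per-sample AVD within one group."""

    group: str
    per_sample: pd.Series
    n_taxa_used: int
    n_taxa_excluded: int

    @property
    def mean(self) -> float:
        return float(self.per_sample.mean())

    @property
    def sd(self) -> float:
        return float(self.per_sample.std(ddof=1))


def avd(table: CommunityTable, groups: pd.Series) -> dict[str, AvdReport]:
    """Average variation degree per sample, grouped.

    Within each group, on relative abundances: for taxon i with group mean
    ``mu_i`` and sample standard deviation ``sigma_i`` (ddof=1), sample k
    contributes ``|x_ik - mu_i| / sigma_i``; AVD of sample k is the mean of
    these contributions over the taxa with positive sigma. Zero-variance
    taxa are excluded (and counted) rather than treated as 0/0 = 0.
    """
    groups = pd.Series(groups).loc[table.sample_ids]
    rel = table.relative_abundance()
    out: dict[str, AvdReport] = {}
    for g in groups.unique():
        sub = rel.loc[groups[groups == g].index]
        if sub.shape[0] < 2:  # sample sd needs >= 2; significance tests need >= 3
            raise InsufficientDataError(f"group {g!r} needs >= 2 samples for AVD")
        mu = sub.mean(axis=0)
        sigma = sub.std(axis=0, ddof=1)
        usable = sigma[sigma > 0].index
        if len(usable) == 0:
            raise NoUsableTaxaError(f"group {g!r}: all taxa have zero variance")
        z = (sub[usable] - mu[usable]).abs() / sigma[usable]
        per_sample = z.mean(axis=1)
        out[str(g)] = AvdReport(
            group=str(g),
            per_sample=per_sample,
            n_taxa_used=len(usable),
            n_taxa_excluded=int(table.n_taxa - len(usable)),
        )
    return out


def avd_difference(a: AvdReport, b: AvdReport) -> dict:
    """Two-sided Welch t-test between two groups' per-sample AVD values."""
    t, p = stats.ttest_ind(a.per_sample, b.per_sample, equal_var=False)
    return {"t": float(t), "p_value": float(p), "mean_a": a.mean, "mean_b": b.mean}


# ---------------------------------------------------------------------------
# nutrient distance
# ---------------------------------------------------------------------------

def nutrient_distance(frame: pd.DataFrame, variables=SOIL_VARS) -> DistanceMatrix:
    """Euclidean distance over z-scored soil covariates.

    Each variable is standardized to mean 0, sd 1 across samples (dropping
    zero-variance variables with a warning), making the distances invariant
    to affine rescaling of any input variable.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValidationError(f"variables not in frame: {missing}")
    if frame.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples")
    x = frame[variables].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        warnings.warn(f"zero-variance variables dropped: {dropped}")
    if not keep.any():
        raise ValidationError("all variables have zero variance")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in frame.index])


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    flavor: str
    seed: int


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    flavor: str = "pearson",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the (Pearson or Spearman) correlation of the off-diagonal vectors;
    the null permutes the sample labels of the second matrix;
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)`` (two-sided).
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValidationError("distance matrices have different sample IDs")
        d2 = d2.filter(d1.ids)
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if flavor not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation flavor {flavor!r}")
    a = np.asarray(d1.data, dtype=float)
    b = np.asarray(d2.data, dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va = a[iu]
    if flavor == "spearman":
        va = stats.rankdata(va)

    def corr(mat: np.ndarray) -> float:
        vb = mat[iu]
        if flavor == "spearman":
            vb = stats.rankdata(vb)
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(b[np.ix_(perm, perm)])) >= abs(r_obs):
            hits += 1
    return MantelResult(
        r=r_obs, p_value=(1 + hits) / (1 + n_perm), n_perm=n_perm, flavor=flavor, seed=seed
    )


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """OLS line with 95% confidence band and optional interpretation notes."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided slope p
    conf_band: pd.DataFrame  # columns x, fit, lo, hi
    n: int
    notes: str = ""


def linear_fit(x, y, notes: str = "") -> RegressionFit:
    """Ordinary least squares y ~ x with a 95% confidence band.

    The band is the pointwise confidence interval of the fitted mean,
    evaluated on a grid spanning the observed x range.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y lengths differ")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression inputs")
    if x.std() == 0:
        raise DegenerateFitError("zero variance in x")
    if y.std() == 0:
        raise DegenerateFitError("zero variance in y")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = pd.DataFrame(
        {"x": grid, "fit": pred["mean"], "lo": pred["mean_ci_lower"], "hi": pred["mean_ci_upper"]}
    )
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        conf_band=band,
        n=len(x),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# pairwise NST vs nutrient distance / AVD differences
# ---------------------------------------------------------------------------

def _pairwise_nst_frame(nst_results) -> pd.DataFrame:
    if isinstance(nst_results, NstResult):
        nst_results = {nst_results.group: nst_results}
    frames = []
    for g, res in nst_results.items():
        f = res.pairs[["sample_i", "sample_j", "NST"]].copy()
        f["group"] = g
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def pnst_nutrient_regression(nst_results, nutrient: DistanceMatrix) -> RegressionFit:
    """Regress pairwise NST on pairwise nutrient distance.

    Pair-level fit over all within-group sample pairs; pairs sharing a
    sample are not independent, which is recorded in the fit's notes (a
    Mantel-style permutation on the same pairs is the recommended guard).
    """
    pairs = _pairwise_nst_frame(nst_results)
    ids = set(nutrient.ids)
    pairs = pairs[pairs.sample_i.isin(ids) & pairs.sample_j.isin(ids)]
    if len(pairs) == 0:
        raise ValidationError("no sample pairs shared between NST results and nutrient matrix")
    x = np.array([nutrient[i, j] for i, j in zip(pairs.sample_i, pairs.sample_j)])
    y = pairs["NST"].to_numpy(dtype=float)
    return linear_fit(
        x, y, notes="pair-level fit; pairs sharing a sample are not independent"
    )


def pnst_avd_regression(nst_results, avd_reports: dict[str, AvdReport]) -> RegressionFit:
    """Regress pairwise NST on pairwise absolute AVD differences.

    "AVD differences" are read as |AVD_k - AVD_l| for each within-group
    sample pair, matched to that pair's NST (the only pairing that puts both
    quantities on sample pairs); this interpretation is recorded in notes.
    """
    pairs = _pairwise_nst_frame(nst_results)
    per_sample = pd.concat([r.per_sample for r in avd_reports.values()])
    have = set(per_sample.index)
    pairs = pairs[pairs.sample_i.isin(have) & pairs.sample_j.isin(have)]
    if len(pairs) == 0:
        raise ValidationError("no sample pairs shared between NST results and AVD reports")
    x = np.abs(
        per_sample.loc[pairs.sample_i].to_numpy() - per_sample.loc[pairs.sample_j].to_numpy()
    )
    y = pairs["NST"].to_numpy(dtype=float)
    return linear_fit(
        x, y, notes="AVD differences interpreted as pairwise |AVD_k - AVD_l|"
    )
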