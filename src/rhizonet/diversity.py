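"""Alpha/beta diversity, ordination and multivariate group tests.

Covers the community-structure comparisons of the pipeline: per-sample
richness, Shannon entropy (natural log) and Faith's phylogenetic diversity;
Bray–Curtis dissimilarity; principal coordinates analysis; PERMANOVA and MRPP
permutation tests; shared/unique taxon partitions (Venn counts) with ternary
relative-abundance coordinates; and a one-way ANOVA + Tukey HSD helper for
the soil/biomass covariates.

PERMANOVA and MRPP are implemented here with explicit seeding and the
``p = (1 + exceedances) / (1 + n_perm)`` convention; scikit-bio's
implementations serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .errors import InsufficientDataError, MissingTaxonError, ValidationError
from .types import CommunityTable


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CommunityTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample richness, Shannon index and (optionally) Faith's PD.

    Richness counts taxa with positive abundance; Shannon is ``-sum p ln p``
    over nonzero relative abundances (natural log); Faith's PD is the total
    branch length of the rooted subtree spanning the sample's observed taxa,
    including the path to the root. Empty samples yield zeros with a warning.
    """
    counts = table.counts.to_numpy(dtype=float)
    rich = (counts > 0).sum(axis=1)
    shannon = np.zeros(table.n_samples)
    for k in range(table.n_samples):
        row = counts[k]
        total = row.sum()
        if total == 0:
            warnings.warn(f"sample {table.sample_ids[k]!r} is empty; diversity set to 0")
            continue
        p = row[row > 0] / total
        shannon[k] = float(-(p * np.log(p)).sum())
    out = pd.DataFrame(
        {"richness": rich, "shannon": shannon}, index=table.sample_ids
    )
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        observed = set(table.counts.columns[(counts > 0).any(axis=0)])
        missing = sorted(observed - tips)
        if missing:
            raise MissingTaxonError(f"taxa absent from the phylogeny: {missing[:5]}")
        pd_vals = np.zeros(table.n_samples)
        for k in range(table.n_samples):
            row = counts[k]
            if row.sum() == 0:
                continue
            pd_vals[k] = _skbio_faith_pd(row, table.taxon_ids, tree)
        out["faith_pd"] = pd_vals
    return out


# ---------------------------------------------------------------------------
# beta diversity & ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity on counts.

    ``d(a, b) = 1 - 2 sum_i min(a_i, b_i) / (sum a + sum b)``, in [0, 1].
    A pair of all-zero samples gets distance 0 with a warning.
    """
    if table.n_samples < 2:
        raise InsufficientDataError("need at least 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    zero_rows = counts.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(counts, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn("all-zero samples present; their mutual distances set to 0")
        d = np.nan_to_num(d, nan=1.0)
        zz = np.ix_(np.flatnonzero(zero_rows), np.flatnonzero(zero_rows))
        d[zz] = 0.0
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA embedding: per-sample coordinates and eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x axes, columns PCo1, PCo2, ...
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers ``-D^2 / 2`` and eigendecomposes. Axes are ordered by
    nonincreasing eigenvalue; coordinates are returned for positive
    eigenvalues only, and ``proportion_explained`` is taken over the
    positive part of the spectrum (negative eigenvalues are reported in
    ``eigenvalues`` but excluded from the denominator).
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# permutation group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Outcome of a permutation test on a distance matrix."""

    statistic_name: str
    statistic: float
    p_value: float
    permutations: int
    seed: int
    effect: float | None = None  # MRPP chance-corrected A


def _check_groups(dist: DistanceMatrix, groups) -> np.ndarray:
    labels = pd.Series(groups)
    labels = labels.loc[list(dist.ids)].to_numpy()
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = values[counts < 2].tolist()
        raise ValidationError(f"groups of size 1 not allowed: {small}")
    return labels


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> GroupTestResult:
    """Permutational multivariate analysis of variance (one factor).

    Pseudo-F from the within/among decomposition of squared distances;
    the null distribution permutes sample labels,
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    labels = _check_groups(dist, groups)
    codes, uniques = pd.factorize(labels)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniques))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniques)) >= f_obs:
            hits += 1
    return GroupTestResult("pseudo-F", float(f_obs), (1 + hits) / (1 + n_perm), n_perm, seed)


def _mrpp_delta(d: np.ndarray, codes: np.ndarray, n_groups: int, n: int) -> float:
    delta = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(len(idx), 1)].mean()
        delta += (len(idx) / n) * mean_within
    return delta


def mrpp(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> GroupTestResult:
    """Multi-response permutation procedure.

    Observed delta is the group-size-weighted mean within-group distance;
    significance is the fraction of label permutations with delta at most the
    observed; the chance-corrected effect is ``A = 1 - delta / E[delta]``
    with the expectation taken over the permutation distribution.
    """
    labels = _check_groups(dist, groups)
    codes, uniques = pd.factorize(labels)
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    delta_obs = _mrpp_delta(d, codes, len(uniques), n)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for r in range(n_perm):
        perm_deltas[r] = _mrpp_delta(d, rng.permutation(codes), len(uniques), n)
    hits = int((perm_deltas <= delta_obs).sum())
    expected = perm_deltas.mean()
    a = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return GroupTestResult(
        "delta", float(delta_obs), (1 + hits) / (1 + n_perm), n_perm, seed, effect=float(a)
    )


# ---------------------------------------------------------------------------
# shared/unique taxa (Venn counts) and ternary proportions
# ---------------------------------------------------------------------------

@dataclass
class SetPartition:
    """Shared/unique taxon counts per group combination plus ternary shares.

    ``counts`` maps a frozenset of group labels to the number of taxa present
    in exactly those groups; ``proportions`` gives each taxon's share of
    group-level relative abundance (rows sum to 1 over groups).
    """

    counts: dict[frozenset, int]
    proportions: pd.DataFrame
    groups: list[str]

    def unique(self, group: str) -> int:
        return self.counts.get(frozenset([group]), 0)

    def shared_all(self) -> int:
        return self.counts.get(frozenset(self.groups), 0)

    def total_observed(self, group: str) -> int:
        return sum(c for k, c in self.counts.items() if group in k)


def shared_unique_otus(table: CommunityTable, groups) -> SetPartition:
    """Partition taxa by the exact combination of groups they occur in.

    A taxon is "present" in a group when its summed count there is nonzero.
    Also returns, per taxon, the proportion of its mean relative abundance
    contributed by each group (the ternary-plot coordinates for 3 groups).
    """
    labels = pd.Series(groups)
    missing = set(table.sample_ids) - set(labels.index.astype(str))
    if missing:
        raise ValidationError(f"group labels missing for samples: {sorted(missing)[:5]}")
    labels = labels.loc[table.sample_ids]
    names = [str(g) for g in pd.unique(labels)]
    if not 2 <= len(names) <= 4:
        raise ValidationError("shared/unique partition supports 2-4 groups")
    rel = table.relative_abundance()
    group_mean = rel.groupby(labels.to_numpy()).mean()  # groups x taxa
    presence = table.counts.groupby(labels.to_numpy()).sum() > 0
    counts: dict[frozenset, int] = {}
    for taxon in table.taxon_ids:
        combo = frozenset(g for g in names if presence.loc[g, taxon])
        if combo:
            counts[combo] = counts.get(combo, 0) + 1
    totals = group_mean.sum(axis=0)
    observed = totals[totals > 0].index
    proportions = (group_mean[observed] / totals[observed]).T
    proportions.columns = [str(c) for c in proportions.columns]
    return SetPartition(counts=counts, proportions=proportions, groups=names)


# ---------------------------------------------------------------------------
# covariate ANOVA (soil / biomass year comparisons)
# ---------------------------------------------------------------------------

def anova_tukey(values: pd.Series, groups: pd.Series) -> dict:
    """One-way ANOVA plus Tukey HSD pairwise letters-style comparison.

    Convenience for year-wise comparison of soil covariates or biomass on
    the sample frame; returns the F statistic, its p, and the Tukey table.
    """
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = groups.loc[values.index]
    arrays = [values[groups == g].to_numpy(dtype=float) for g in pd.unique(groups)]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups for ANOVA")
    f, p = f_oneway(*arrays)
    tukey = pairwise_tukeyhsd(values.to_numpy(dtype=float), groups.astype(str).to_numpy())
    tukey_df = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return {"F": float(f), "p_value": float(p), "tukey": tukey_df}
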