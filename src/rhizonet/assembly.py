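"""Niche breadth and phylogenetic assembly stochasticity.

Implements Levins' niche breadth (B) and its community mean (Bcom), the
between-sample mean nearest taxon distance (betaMNTD), and the phylogenetic
normalized stochasticity ratio (pNST). pNST compares observed phylogenetic
turnover with a null ensemble in which tip labels are shuffled across the
whole phylogeny; values range over [0, 1], with > 0.5 read as dominance of
stochastic assembly processes and < 0.5 as dominance of deterministic
(selection-driven) processes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import ConfigurationError, InsufficientDataError, MissingTaxonError, ValidationError
from .types import CommunityTable


@dataclass
class NicheBreadthReport:
    """Per-taxon Levins B and the community-level mean Bcom for one group."""

    group: str
    b_values: pd.Series  # indexed by taxon ID, taxa occurring in the group only
    bcom: float
    n_samples: int


def levins_breadth(table: CommunityTable, groups: pd.Series) -> dict[str, NicheBreadthReport]:
    """Levins niche breadth per taxon and its community mean per group.

    For taxon j within a group, ``p_ij`` is the share of the taxon's
    group-total abundance found in sample i, and ``B_j = 1 / sum_i p_ij^2``.
    B ranges from 1 (taxon confined to one sample) to the group's sample
    count (taxon spread evenly). ``Bcom`` is the arithmetic mean of B over
    taxa with nonzero group abundance.
    """
    groups = _align_groups(table, groups)
    out: dict[str, NicheBreadthReport] = {}
    for g in groups.unique():
        sub = table.counts.loc[groups[groups == g].index]
        if sub.shape[0] < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 samples")
        totals = sub.sum(axis=0)
        present = totals[totals > 0].index
        p = sub[present] / totals[present]
        b = 1.0 / (p**2).sum(axis=0)
        out[g] = NicheBreadthReport(
            group=str(g), b_values=b, bcom=float(b.mean()), n_samples=sub.shape[0]
        )
    return out


def _align_groups(table: CommunityTable, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    missing = set(table.sample_ids) - set(groups.index.astype(str))
    if missing:
        raise ValidationError(f"group labels missing for samples: {sorted(missing)[:5]}")
    return groups.loc[table.sample_ids]


def _patristic_matrix(table: CommunityTable, tree: TreeNode) -> np.ndarray:
    """Tip-to-tip distances ordered as the table's taxa; errors on absent tips."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise MissingTaxonError(f"taxa absent from the phylogeny: {missing[:5]}")
    dm = tree.tip_tip_distances()
    order = [dm.index(t) for t in table.taxon_ids]
    return dm.data[np.ix_(order, order)]


def _pair_mntd(
    dist: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    w_a: np.ndarray,
    w_b: np.ndarray,
    weighted: bool,
) -> float:
    """Mean nearest-taxon distance between two samples, averaged both ways."""
    sub = dist[np.ix_(idx_a, idx_b)]
    near_a = sub.min(axis=1)
    near_b = sub.min(axis=0)
    if weighted:
        d_ab = float(near_a @ (w_a / w_a.sum()))
        d_ba = float(near_b @ (w_b / w_b.sum()))
    else:
        d_ab = float(near_a.mean())
        d_ba = float(near_b.mean())
    return 0.5 * (d_ab + d_ba)


def beta_mntd(
    table: CommunityTable, tree: TreeNode, abundance_weighted: bool = True
) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance (betaMNTD).

    For each ordered sample pair, each taxon present in one sample
    contributes its patristic distance to the nearest taxon present in the
    other sample (zero if shared); contributions are abundance-weighted when
    flagged, and the two directions are averaged. Symmetric, zero on
    identical samples.
    """
    dist = _patristic_matrix(table, tree)
    counts = table.counts.to_numpy(dtype=float)
    n = table.n_samples
    present = [np.flatnonzero(counts[i] > 0) for i in range(n)]
    weights = [counts[i][present[i]] for i in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_mntd(dist, present[i], present[j], weights[i], weights[j], abundance_weighted)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=table.sample_ids)


@dataclass
class NstResult:
    """Pairwise and group-level stochasticity ratios for one group.

    ``pairs`` has one row per within-group sample pair with the observed
    scaled dissimilarity, the null mean/sd, and the ST and NST ratios;
    ``pnst`` is the group mean NST in [0, 1] (``pnst_percent`` rescales it).
    """

    group: str
    pairs: pd.DataFrame
    pnst: float
    null_model: str
    n_nulls: int
    seed: int
    abundance_weighted: bool = True

    @property
    def pnst_percent(self) -> float:
        return 100.0 * self.pnst


def pnst(
    table: CommunityTable,
    tree: TreeNode,
    groups: pd.Series,
    n_nulls: int = 1000,
    null_model: str = "taxa_shuffle",
    seed: int = 0,
    abundance_weighted: bool = True,
) -> dict[str, NstResult]:
    """Phylogenetic normalized stochasticity ratio per group.

    Observed within-group betaMNTD values and a null ensemble (tip labels
    shuffled across the whole phylogeny, abundances untouched) are jointly
    scaled to [0, 1] by their common maximum. For each pair with observed
    dissimilarity D and null expectation E (Dmax = 1 after scaling):

    * ST — the stochasticity ratio: when the pair is more similar than its
      null expectation (D < E), ST = (1 - E) / (1 - D), the ratio of expected
      to observed similarity; when more dissimilar, ST = E / D, the ratio of
      expected to observed dissimilarity. ST = 1 means purely stochastic.
    * NST — normalized so the deterministic extremes hit exactly zero:
      if D <= E (selection toward similarity), NST = D / E, reaching 0 at
      D = 0; if D > E (selection toward divergence),
      NST = (Dmax - D) / (Dmax - E), reaching 0 at D = Dmax. At D = E both
      branches give 1 (fully stochastic).

    Group pNST is the mean NST over within-group pairs. Pairs whose null has
    zero variance and zero mean are dropped with a warning.
    """
    if null_model != "taxa_shuffle":
        raise ConfigurationError(f"unknown null model {null_model!r}")
    if n_nulls < 2:
        raise ConfigurationError("n_nulls must be >= 2")
    groups = _align_groups(table, groups)
    dist = _patristic_matrix(table, tree)
    counts = table.counts.to_numpy(dtype=float)
    sample_ids = table.sample_ids
    pos = {s: k for k, s in enumerate(sample_ids)}

    group_pairs: dict[str, list[tuple[int, int]]] = {}
    for g in groups.unique():
        members = [pos[s] for s in groups[groups == g].index]
        if len(members) < 3:
            raise InsufficientDataError(f"group {g!r} has fewer than 3 samples")
        group_pairs[str(g)] = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    all_pairs = [p for pairs in group_pairs.values() for p in pairs]

    present = [np.flatnonzero(counts[i] > 0) for i in range(len(sample_ids))]
    weights = [counts[i][present[i]] for i in range(len(sample_ids))]

    def pairwise(d: np.ndarray) -> np.ndarray:
        return np.array(
            [
                _pair_mntd(d, present[i], present[j], weights[i], weights[j], abundance_weighted)
                for (i, j) in all_pairs
            ]
        )

    obs = pairwise(dist)
    rng = np.random.default_rng(seed)
    n_taxa = dist.shape[0]
    nulls = np.empty((n_nulls, len(all_pairs)))
    for r in range(n_nulls):
        perm = rng.permutation(n_taxa)
        nulls[r] = pairwise(dist[np.ix_(perm, perm)])

    # per-pair scaling: each pair's Dmax is the maximum of its observed and
    # null values, so a pair observed beyond its whole null ensemble sits at
    # the deterministic-divergence extreme (NST = 0) on its own scale
    d_max = np.maximum(obs, nulls.max(axis=0))
    d_max = np.where(d_max > 0, d_max, 1.0)
    obs_s = obs / d_max
    nulls_s = nulls / d_max
    e_mean = nulls_s.mean(axis=0)
    e_sd = nulls_s.std(axis=0, ddof=1)

    results: dict[str, NstResult] = {}
    offset = 0
    for g, pairs in group_pairs.items():
        rows = []
        for k, (i, j) in enumerate(pairs):
            idx = offset + k
            d, e, sd = obs_s[idx], e_mean[idx], e_sd[idx]
            if e == 0.0 and sd == 0.0 and d == 0.0:
                warnings.warn(f"degenerate null for pair ({sample_ids[i]}, {sample_ids[j]}); dropped")
                continue
            if d <= e:
                # selection toward similarity: expected/observed similarity,
                # normalized stochasticity D/E -> 0 at identical communities
                st = (1.0 - e) / (1.0 - d) if d < 1.0 else 1.0
                nst = d / e if e > 0 else 0.0
            else:
                # selection toward divergence: expected/observed dissimilarity,
                # normalized (Dmax - D)/(Dmax - E) -> 0 at maximal divergence
                st = e / d
                nst = (1.0 - d) / (1.0 - e) if e < 1.0 else 1.0
            rows.append(
                {
                    "sample_i": sample_ids[i],
                    "sample_j": sample_ids[j],
                    "D_obs": d,
                    "null_mean": e,
                    "null_sd": sd,
                    "ST": min(st, 1.0),
                    "NST": float(np.clip(nst, 0.0, 1.0)),
                }
            )
        offset += len(pairs)
        pairs_df = pd.DataFrame(rows)
        results[g] = NstResult(
            group=g,
            pairs=pairs_df,
            pnst=float(pairs_df["NST"].mean()) if len(pairs_df) else float("nan"),
            null_model=null_model,
            n_nulls=n_nulls,
            seed=seed,
            abundance_weighted=abundance_weighted,
        )
    return results


def pnst_group_difference(
    res_a: NstResult, res_b: NstResult, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Two-sided bootstrap test for a difference in group pNST.

    Resamples each group's within-group pairwise NST values with replacement
    and reports the bootstrap p for pNST(a) != pNST(b).
    """
    rng = np.random.default_rng(seed)
    a = res_a.pairs["NST"].to_numpy()
    b = res_b.pairs["NST"].to_numpy()
    obs = a.mean() - b.mean()
    boots = np.empty(n_boot)
    for r in range(n_boot):
        boots[r] = rng.choice(a, len(a)).mean() - rng.choice(b, len(b)).mean()
    # two-sided: how often the bootstrap difference crosses zero
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    return {
        "diff": float(obs),
        "p_value": float(min(max(p, 1.0 / n_boot), 1.0)),
        "n_boot": n_boot,
        "seed": seed,
    }
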