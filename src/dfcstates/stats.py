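"""Covariate-adjusted permutation inference for group contrasts.

Group comparisons of temporal and graph metrics use a Freedman-Lane-style
permutation test: the outcome is residualized on intercept + nuisance
covariates (age, gender), the group-mean difference of residuals is the
statistic, and the null is built by permuting the residuals across subjects.
Multiple comparisons are handled by Benjamini-Hochberg FDR within declared
families, and edge-wise network contrasts by the network-based statistic
(NBS): a primary edge-level threshold followed by permutation inference on
the size of connected suprathreshold components.

Clinical association uses Spearman partial correlation: rank-transform,
residualize both variables on the covariates, and correlate the residuals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "StatsInputError",
    "DesignMatrix",
    "PermutationResult",
    "FDRResult",
    "NBSResult",
    "PartialCorrelationResult",
    "covariate_adjust",
    "permutation_test",
    "permutation_test_many",
    "fdr_bh",
    "nbs",
    "spearman_partial",
    "demographics_tests",
]


class StatsInputError(ValueError):
    """Invalid statistical design or data."""


@dataclass
class DesignMatrix:
    """Subjects, group labels and nuisance covariates for one contrast."""

    subject_ids: list[str]
    groups: np.ndarray
    covariates: pd.DataFrame  # columns e.g. age, gender

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        if self.covariates.isna().any().any():
            raise StatsInputError("covariates contain missing values")
        labels, counts = np.unique(self.groups, return_counts=True)
        if labels.size < 2:
            raise StatsInputError("at least two groups are required")
        if counts.min() < 2:
            raise StatsInputError("every group needs at least 2 subjects")


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        x = np.ones((n, 1))
        return x
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise StatsInputError("covariate rows must match the number of subjects")
    x = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the offending column for the user
        for j in range(1, x.shape[1]):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(x):
                name = (
                    covariates.columns[j - 1]
                    if isinstance(covariates, pd.DataFrame)
                    else f"column {j - 1}"
                )
                raise StatsInputError(f"collinear covariate: {name}")
        raise StatsInputError("rank-deficient covariate design")
    return x


def covariate_adjust(
    values: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> np.ndarray:
    """Least-squares residuals of the outcome on intercept + covariates."""
    y = np.asarray(values, dtype=float)
    x = _design(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


@dataclass
class PermutationResult:
    observed_stat: float
    p_value: float
    n_perm: int
    seed: Optional[int]
    null_stats: np.ndarray = field(default_factory=lambda: np.array([]))


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def permutation_test(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence | None = 0,
    keep_null: bool = False,
) -> PermutationResult:
    """Freedman-Lane permutation test of a two-group mean difference.

    The outcome is residualized on intercept + covariates; the statistic is
    the group-mean difference of residuals; the null permutes residuals over
    subjects. Two-sided p with add-one correction:
    ``p = (1 + #{|null| >= |obs|}) / (n_perm + 1)``.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise StatsInputError("permutation_test compares exactly two groups")
    if min((groups == g).sum() for g in labels) < 2:
        raise StatsInputError("both groups need at least 2 subjects")
    if np.ptp(y) == 0:
        logger.info("constant outcome; permutation p set to 1")
        return PermutationResult(0.0, 1.0, n_perm, None)
    resid = covariate_adjust(y, covariates)
    in_a = groups == labels[0]
    w = in_a / in_a.sum() - (~in_a) / (~in_a).sum()
    observed = float(resid @ w)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    perms = _perm_indices(rng, y.size, n_perm)
    null = w[perms] @ resid  # permute the group-contrast weights over subjects
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    return PermutationResult(
        observed_stat=observed,
        p_value=float(p),
        n_perm=n_perm,
        seed=None,
        null_stats=null if keep_null else np.array([]),
    )


def permutation_test_many(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Freedman-Lane tests for many outcomes sharing one design.

    ``values`` is (n_subjects, n_outcomes); one shared permutation schedule
    is applied to every outcome. Returns (observed_stats, p_values).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise StatsInputError("values must be (n_subjects, n_outcomes)")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise StatsInputError("permutation_test_many compares exactly two groups")
    n = y.shape[0]
    x = _design(covariates, n)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    in_a = groups == labels[0]
    w = in_a / in_a.sum() - (~in_a) / (~in_a).sum()
    observed = w @ resid
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    perms = _perm_indices(rng, n, n_perm)
    null = np.einsum("pn,nm->pm", w[perms].astype(float), resid)
    exceed = np.count_nonzero(np.abs(null) >= np.abs(observed)[None, :] - 1e-12, axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    constant = np.ptp(y, axis=0) == 0
    p[constant] = 1.0
    observed[constant] = 0.0
    return observed, p


@dataclass
class FDRResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    q: float
    family: str = ""


def fdr_bh(p_values: Sequence[float], q: float = 0.05, family: str = "") -> FDRResult:
    """Benjamini-Hochberg step-up FDR correction."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRResult(p, p.copy(), np.zeros(0, dtype=bool), q, family)
    if np.any((p < 0) | (p > 1)):
        raise StatsInputError("p-values must lie in [0, 1]")
    rejected, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(raw_p=p, adjusted_p=adjusted, rejected=rejected, q=q, family=family)


@dataclass
class NBSResult:
    edge_p: np.ndarray
    suprathreshold_edges: list[tuple[int, int]]
    components: list[dict]
    max_null_component: np.ndarray
    edge_alpha: float
    comp_alpha: float
    n_iter: int

    @property
    def significant_components(self) -> list[dict]:
        return [c for c in self.components if c["p_corrected"] < self.comp_alpha]


def _edge_t_stats(resid: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per edge on residualized outcomes."""
    na, nb = int(in_a.sum()), int((~in_a).sum())
    ma = resid[in_a].mean(axis=0)
    mb = resid[~in_a].mean(axis=0)
    va = resid[in_a].var(axis=0, ddof=1)
    vb = resid[~in_a].var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _max_component_edges(edge_mask: np.ndarray, pairs: np.ndarray, n_nodes: int) -> int:
    if not edge_mask.any():
        return 0
    g = nx.Graph()
    g.add_edges_from(pairs[edge_mask])
    return max(
        g.subgraph(c).number_of_edges() for c in nx.connected_components(g)
    )


def nbs(
    edge_values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_nodes: Optional[int] = None,
    edge_alpha: float = 0.001,
    comp_alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> NBSResult:
    """Network-based statistic for edge-wise group contrasts.

    ``edge_values`` is (n_subjects, n_edges) over the row-major strict upper
    triangle of an ``n_nodes`` network. Edges are screened with a primary
    two-sided t-test (on covariate-adjusted values) at ``edge_alpha``;
    connected components of the surviving edges are then assigned
    familywise-corrected p-values from the permutation distribution of the
    maximal component size (edge count), with add-one correction and a
    permutation schedule shared across edges.
    """
    y = np.asarray(edge_values, dtype=float)
    if y.ndim != 2:
        raise StatsInputError("edge_values must be (n_subjects, n_edges)")
    n_subj, n_edges = y.shape
    if n_nodes is None:
        n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_nodes * (n_nodes - 1) // 2 != n_edges:
        raise StatsInputError("edge count is not N(N-1)/2 for any integer N")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2 or min((groups == g).sum() for g in labels) < 2:
        raise StatsInputError("NBS compares two groups with >= 2 subjects each")
    iu = np.triu_indices(n_nodes, k=1)
    pairs = np.column_stack(iu)
    x = _design(covariates, n_subj)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    in_a = groups == labels[0]
    df = n_subj - 2
    t_obs = _edge_t_stats(resid, in_a)
    edge_p = 2.0 * sps.t.sf(np.abs(t_obs), df)
    supra = edge_p < edge_alpha
    supra_edges = [tuple(e) for e in pairs[supra]]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    t_crit = sps.t.isf(edge_alpha / 2.0, df)
    max_null = np.zeros(n_iter, dtype=np.int64)
    for i in range(n_iter):
        perm = rng.permutation(n_subj)
        t_null = _edge_t_stats(resid[perm], in_a)
        max_null[i] = _max_component_edges(np.abs(t_null) > t_crit, pairs, n_nodes)

    components: list[dict] = []
    if supra.any():
        g = nx.Graph()
        g.add_edges_from(supra_edges)
        for nodes in nx.connected_components(g):
            sub = g.subgraph(nodes)
            size = sub.number_of_edges()
            p_corr = (1.0 + np.count_nonzero(max_null >= size)) / (n_iter + 1.0)
            components.append(
                {
                    "nodes": sorted(nodes),
                    "edges": sorted(tuple(sorted(e)) for e in sub.edges),
                    "n_edges": size,
                    "p_corrected": float(p_corr),
                }
            )
        components.sort(key=lambda c: -c["n_edges"])
    return NBSResult(
        edge_p=edge_p,
        suprathreshold_edges=supra_edges,
        components=components,
        max_null_component=max_null,
        edge_alpha=edge_alpha,
        comp_alpha=comp_alpha,
        n_iter=n_iter,
    )


@dataclass
class PartialCorrelationResult:
    rho: float
    p_value: float
    n: int
    covariates: list[str]


def spearman_partial(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> PartialCorrelationResult:
    """Spearman partial correlation controlling for nuisance covariates.

    Both variables are rank-transformed (average ranks on ties),
    residualized on intercept + covariates, and the residuals' Pearson
    correlation is reported with a t-based p on ``n - 2 - k`` degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        keep = np.ptp(c, axis=0) > 0  # constant covariates carry no information
        if not keep.all():
            logger.info("dropping %d constant covariate column(s)", (~keep).sum())
            if isinstance(covariates, pd.DataFrame):
                covariates = covariates.loc[:, keep]
            else:
                covariates = c[:, keep]
            if np.asarray(covariates).shape[1] == 0:
                covariates = None
        k = 0 if covariates is None else np.asarray(covariates).shape[1]
    else:
        k = 0
    if n <= k + 2:
        raise StatsInputError("need n > number of covariates + 2")
    rx = covariate_adjust(sps.rankdata(x), covariates)
    ry = covariate_adjust(sps.rankdata(y), covariates)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise StatsInputError("zero residual variance; correlation undefined")
    rho = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    names = (
        list(covariates.columns)
        if isinstance(covariates, pd.DataFrame)
        else [] if covariates is None else [f"c{i}" for i in range(k)]
    )
    return PartialCorrelationResult(rho=rho, p_value=p, n=n, covariates=names)


def demographics_tests(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Cohort-description tests.

    Kruskal-Wallis for age across all groups, chi-square (no continuity
    correction) for the gender x group table, and Mann-Whitney U (two-sided,
    tie-corrected normal approximation for n > 8) for NRS between the HZ and
    PHN groups when those columns/groups are present.
    """
    required = {"group", "age", "gender"}
    missing = required - set(table.columns)
    if missing:
        raise StatsInputError(f"missing columns: {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    groups = [g["age"].to_numpy() for _, g in table.groupby("group")]
    h, p = sps.kruskal(*groups)
    out["age_kruskal"] = {"statistic": float(h), "p_value": float(p)}
    contingency = pd.crosstab(table["gender"], table["group"]).to_numpy()
    chi2, p, dof, _ = sps.chi2_contingency(contingency, correction=False)
    out["gender_chi2"] = {"statistic": float(chi2), "p_value": float(p), "dof": float(dof)}
    if "nrs" in table.columns:
        hz = table.loc[(table["group"] == "HZ") & table["nrs"].notna(), "nrs"]
        phn = table.loc[(table["group"] == "PHN") & table["nrs"].notna(), "nrs"]
        if len(hz) >= 2 and len(phn) >= 2:
            u, p = sps.mannwhitneyu(hz, phn, alternative="two-sided")
            out["nrs_mannwhitney"] = {"statistic": float(u), "p_value": float(p)}
    return out
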