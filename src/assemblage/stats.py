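"""Compositional and environmental statistics supporting assembly analysis.

Bray-Curtis dissimilarity, per-sample richness and Pielou evenness,
environmental difference matrices, Mantel tests, abundance-weighted niche
values with a phylogenetic-signal Mantel correlogram, and a sequential
(Type I) PERMANOVA on a dissimilarity matrix.

Conventions
-----------
* Shannon diversity uses the natural log, so Pielou J = H / ln(S).
* Mantel statistics are Pearson correlations between lower-triangle
  entries, with permutation p-values; samples carrying missing values
  are dropped listwise per test, never imputed.
* The Mantel correlogram reports the sign-flipped per-class statistic so
  that positive values at short phylogenetic distances mean phylogenetic
  signal (close relatives have similar niches); progressive Bonferroni
  corrects class k at alpha / k.
* PERMANOVA partitions the Gower-centred total sum of squares
  sequentially in the user-given term order and permutes raw sample
  identities, as in the classical distance-based ANOVA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from assemblage.io import CountTable, PairwiseMatrix, SampleMetadata, ValidationError

__all__ = [
    "NicheValueVector",
    "CorrelogramResult",
    "PermanovaTable",
    "bray_curtis_matrix",
    "richness",
    "pielou_evenness",
    "shannon",
    "env_difference_matrix",
    "mantel",
    "niche_values",
    "mantel_correlogram",
    "permanova",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NicheValueVector:
    """Abundance-weighted mean of an environmental variable per taxon."""

    taxon_ids: tuple[str, ...]
    values: np.ndarray
    variable: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxon_ids),):
            raise ValidationError("niche vector length does not match taxa")
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CorrelogramResult:
    """Per-distance-class Mantel statistics for phylogenetic signal."""

    class_edges: np.ndarray  # (n_classes + 1,) bin edges over (0, max]
    r: np.ndarray  # sign-flipped Mantel statistic per class
    p: np.ndarray
    significant: np.ndarray  # after progressive Bonferroni
    n_pairs: np.ndarray  # pairs per class


@dataclass(frozen=True)
class PermanovaTable:
    """Sequential PERMANOVA results as a DataFrame plus bookkeeping."""

    table: pd.DataFrame  # rows: terms + Residuals + Total
    permutations: int
    seed: int

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.5g}")


# ---------------------------------------------------------------------------
# dissimilarity and alpha diversity


def bray_curtis_matrix(counts: CountTable, normalize: bool = True) -> PairwiseMatrix:
    """Pairwise Bray-Curtis: sum|x - y| / sum(x + y) over taxa.

    Computed on within-sample relative abundances by default, which makes
    the result invariant to per-sample sequencing depth.
    """
    x = counts.relative_abundance() if normalize else counts.matrix
    values = squareform(pdist(x, metric="braycurtis"))
    return PairwiseMatrix(counts.sample_ids, values, kind="dissimilarity")


def richness(counts: CountTable) -> pd.Series:
    """Number of taxa with abundance > 0 per sample."""
    return pd.Series(
        (counts.matrix > 0).sum(axis=1), index=list(counts.sample_ids), name="richness"
    )


def shannon(counts: CountTable) -> pd.Series:
    """Shannon diversity H = -sum p ln p (natural log) per sample."""
    p = counts.relative_abundance()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=list(counts.sample_ids), name="shannon")


def pielou_evenness(counts: CountTable) -> pd.Series:
    """Pielou J = H / ln(S); NaN for single-taxon samples (ln S = 0)."""
    h = shannon(counts)
    s = richness(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = h / np.log(s.astype(float))
    j[s <= 1] = np.nan
    j.name = "pielou_evenness"
    return j


def env_difference_matrix(metadata: SampleMetadata, variable: str) -> PairwiseMatrix:
    """|v_i - v_j| per sample pair; pairs with a missing value are NaN."""
    v = metadata.variable(variable).to_numpy(dtype=float)
    n_present = np.isfinite(v).sum()
    if n_present == 0:
        raise ValidationError(f"variable {variable!r} is missing for every sample")
    if n_present < 3:
        raise ValidationError(f"variable {variable!r} present for fewer than 3 samples")
    diff = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(diff, np.where(np.isfinite(v), 0.0, np.nan))
    return PairwiseMatrix(metadata.sample_ids, diff, kind="env_difference")


# ---------------------------------------------------------------------------
# Mantel machinery


def _drop_missing(m1: PairwiseMatrix, m2: PairwiseMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align two matrices on shared IDs and drop samples with NaN rows."""
    shared = [i for i in m1.ids if i in set(m2.ids)]
    if len(shared) < 4:
        raise ValidationError("Mantel test needs at least 4 shared samples")
    a = m1.select(shared).values.copy()
    b = m2.select(shared).values.copy()
    n = len(shared)
    off = ~np.eye(n, dtype=bool)
    # greedily remove the sample responsible for the most missing pairs
    # until no off-diagonal NaN remains (listwise deletion)
    keep = np.arange(n)
    while True:
        sa = a[np.ix_(keep, keep)]
        sb = b[np.ix_(keep, keep)]
        o = off[np.ix_(keep, keep)]
        bad = ((np.isnan(sa) | np.isnan(sb)) & o).sum(axis=1)
        if bad.max(initial=0) == 0:
            break
        keep = np.delete(keep, int(np.argmax(bad)))
        if keep.size < 4:
            raise ValidationError(
                "fewer than 4 samples remain after dropping missing values"
            )
    kept = [shared[i] for i in keep]
    return a[np.ix_(keep, keep)], b[np.ix_(keep, keep)], kept


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValidationError("zero variance in a Mantel triangle")
    return float((xc @ yc) / denom)


def mantel(
    m1: PairwiseMatrix,
    m2: PairwiseMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two square matrices.

    r is the Pearson correlation of the lower triangles; p is the
    two-sided permutation p-value (1 + #{|r_perm| >= |r_obs|}) /
    (1 + permutations), permuting rows and columns of ``m2`` jointly.
    """
    a, b, _ = _drop_missing(m1, m2)
    n = a.shape[0]
    i, j = np.tril_indices(n, k=-1)
    va, vb = a[i, j], b[i, j]
    r_obs = _pearson(va, vb)
    if permutations < 1:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = _pearson(va, b[perm[i], perm[j]])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# niche values and phylogenetic signal


def niche_values(
    counts: CountTable, metadata: SampleMetadata, variable: str
) -> NicheValueVector:
    """Abundance-weighted mean environmental value per taxon.

    niche_i = sum_s (n_is / sum_s n_is) * v_s. Samples lacking the
    variable are dropped (with a log message) before weighting; taxa with
    zero total abundance over the retained samples are excluded.
    """
    v = metadata.variable(variable)
    keep_samples = [s for s in counts.sample_ids if np.isfinite(v.get(s, np.nan))]
    dropped = [s for s in counts.sample_ids if s not in set(keep_samples)]
    if dropped:
        logger.info("niche_values: dropping %d samples lacking %s", len(dropped), variable)
    if not keep_samples:
        raise ValidationError(f"no samples have a value for {variable!r}")
    x = counts.data.loc[keep_samples].to_numpy(dtype=float)
    vals = v.loc[keep_samples].to_numpy(dtype=float)
    totals = x.sum(axis=0)
    nonzero = totals > 0
    if (~nonzero).any():
        logger.info(
            "niche_values: excluding %d taxa with zero total abundance", int((~nonzero).sum())
        )
    niche = (x[:, nonzero].T @ vals) / totals[nonzero]
    taxa = tuple(t for t, nz in zip(counts.taxon_ids, nonzero) if nz)
    return NicheValueVector(taxa, niche, variable)


def mantel_correlogram(
    tip_dist,
    niche: NicheValueVector,
    n_classes: int | None = None,
    permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> CorrelogramResult:
    """Phylogenetic-signal Mantel correlogram.

    For each phylogenetic distance class k, correlates the class
    indicator matrix with the niche-difference matrix |niche_i - niche_j|
    and flips the sign, so r > 0 in class 1 means taxa at short
    phylogenetic distance have similar niche values. Distance classes are
    of equal width spanning (0, max]; Sturges' rule sets their number
    when unset. Progressive Bonferroni tests class k at alpha / k.
    """
    taxa = [t for t in tip_dist.taxon_ids if t in set(niche.taxon_ids)]
    if len(taxa) < 4:
        raise ValidationError("correlogram needs at least 4 taxa with niche values")
    d = tip_dist.select(taxa).d
    order = {t: k for k, t in enumerate(niche.taxon_ids)}
    nv = niche.values[[order[t] for t in taxa]]
    n = len(taxa)
    i, j = np.tril_indices(n, k=-1)
    pd_vec = d[i, j]
    nd = np.abs(nv[:, None] - nv[None, :])
    nd_vec = nd[i, j]
    n_pairs_total = pd_vec.size
    if n_classes is None:
        n_classes = max(2, int(np.ceil(1 + np.log2(n_pairs_total))))
    dmax = float(pd_vec.max())
    edges = np.linspace(0.0, dmax, n_classes + 1)
    # assign classes over (edge_k, edge_{k+1}]
    cls = np.clip(np.searchsorted(edges, pd_vec, side="left") - 1, 0, n_classes - 1)

    constant_niche = np.allclose(nd_vec, nd_vec[0])
    rng = np.random.default_rng(seed)
    perm_nd = np.empty((permutations, n_pairs_total))
    if not constant_niche:
        for pidx in range(permutations):
            perm = rng.permutation(n)
            perm_nd[pidx] = nd[perm[i], perm[j]]

    r = np.full(n_classes, np.nan)
    p = np.full(n_classes, np.nan)
    npairs = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        member = cls == k
        npairs[k] = int(member.sum())
        if npairs[k] == 0 or npairs[k] == n_pairs_total or constant_niche:
            continue
        ind = member.astype(float)
        r_obs = -_pearson(ind, nd_vec)
        count = 0
        ic = ind - ind.mean()
        ic_norm = math.sqrt(ic @ ic)
        for pidx in range(permutations):
            yv = perm_nd[pidx]
            yc = yv - yv.mean()
            denom = ic_norm * math.sqrt(yc @ yc)
            r_perm = 0.0 if denom == 0 else -(ic @ yc) / denom
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                count += 1
        r[k] = r_obs
        p[k] = (1 + count) / (1 + permutations)
    significant = np.zeros(n_classes, dtype=bool)
    for k in range(n_classes):
        if np.isfinite(p[k]):
            significant[k] = p[k] <= alpha / (k + 1)
    return CorrelogramResult(edges, r, p, significant, npairs)


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    return centering @ a @ centering


def _design_columns(values: pd.Series) -> np.ndarray:
    """Model-matrix columns for one term: dummies if categorical, else centred."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype) or values.dtype == bool:
        dummies = pd.get_dummies(values.astype(str), drop_first=True)
        return dummies.to_numpy(dtype=float)
    v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    return v[:, None]


def permanova(
    dissim: PairwiseMatrix,
    metadata: SampleMetadata,
    terms: list[str],
    permutations: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """Sequential (Type I) PERMANOVA of a dissimilarity matrix.

    Each term's sum of squares is the increase in explained
    Gower-centred SS when its columns are appended to the model, in the
    order given. Pseudo-F tests each term against the residual; p-values
    come from permuting raw sample identities. Samples missing any term
    are dropped listwise. Constant terms get SS 0 and NaN F with a
    warning.
    """
    meta = metadata.data
    shared = [s for s in dissim.ids if s in set(metadata.sample_ids)]
    missing_terms = [t for t in terms if t not in meta.columns]
    if missing_terms:
        raise ValidationError(f"metadata lacks PERMANOVA terms: {missing_terms}")
    sub = meta.loc[shared, terms]
    numeric_like = sub.apply(
        lambda c: pd.to_numeric(c, errors="coerce") if c.dtype != object else c
    )
    keep = ~numeric_like.isna().any(axis=1)
    samples = [s for s, k in zip(shared, keep) if k]
    if len(samples) < 3:
        raise ValidationError("PERMANOVA needs at least 3 complete samples")
    d = dissim.select(samples).values
    g = _gower_center(d)
    n = len(samples)
    ss_total = float(np.trace(g))

    blocks = [np.ones((n, 1))]
    for term in terms:
        blocks.append(_design_columns(meta.loc[samples, term]))

    # cumulative orthonormal bases; SS via trace(H G) = sum(H * G)
    qs: list[np.ndarray] = []
    ranks: list[int] = []
    x = np.empty((n, 0))
    for block in blocks:
        x = np.hstack([x, block])
        q, rmat = np.linalg.qr(x)
        rank = int(np.sum(np.abs(np.diag(rmat)) > 1e-10 * max(1.0, np.abs(rmat).max())))
        qs.append(q[:, :rank])
        ranks.append(rank)

    def term_ss(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        explained = np.array([np.sum((q.T @ gmat) * q.T) for q in qs])
        ss = np.diff(explained)  # per term, after the intercept
        resid = float(np.trace(gmat) - explained[-1])
        return ss, resid

    ss_terms, ss_resid = term_ss(g)
    df_terms = np.diff(np.array(ranks))
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_terms = np.where(df_terms > 0, ss_terms / np.maximum(df_terms, 1), np.nan)
        f_terms = ms_terms / ms_resid
    for t, df in zip(terms, df_terms):
        if df == 0:
            logger.warning("PERMANOVA term %r is constant: SS 0, F undefined", t)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    valid = df_terms > 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp, residp = term_ss(gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = (ssp / np.maximum(df_terms, 1)) / (residp / df_resid)
        exceed += (fp >= f_terms - 1e-12) & valid
    pvals = np.where(valid, (1 + exceed) / (1 + permutations), np.nan)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": int(df_terms[k]),
                "sum_sq": float(ss_terms[k]),
                "mean_sq": float(ms_terms[k]) if df_terms[k] > 0 else float("nan"),
                "F": float(f_terms[k]) if df_terms[k] > 0 else float("nan"),
                "R2": float(ss_terms[k] / ss_total),
                "p": float(pvals[k]) if valid[k] else float("nan"),
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "df": int(df_resid),
            "sum_sq": float(ss_resid),
            "mean_sq": float(ms_resid),
            "F": float("nan"),
            "R2": float(ss_resid / ss_total),
            "p": float("nan"),
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": int(n - 1),
            "sum_sq": float(ss_total),
            "mean_sq": float("nan"),
            "F": float("nan"),
            "R2": 1.0,
            "p": float("nan"),
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaTable(table, permutations, seed)
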