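"""Statistical chain for signature-whistle variability analysis.

Per-SW mean vectors -> fourth-root transform -> Bray-Curtis dissimilarity ->
non-metric MDS ordination and one-way ANOSIM per factor; correlation-matrix
PCA with Kaiser retention of the per-contour feature table; Gaussian linear
mixed models (random intercept per SW-ID, REML) of each retained component
on each factor; and hierarchical clustering of the site-metadata table
(Ward / complete linkage on Euclidean distances) to build the sea-bottom and
demography factors.

ANOSIM and the PCA eigendecomposition are implemented directly from their
defining formulas (rank-based R with permutation p; eigenvectors of the
correlation matrix) so they can be validated against brute-force oracles;
the mixed models are fitted by `statsmodels` MixedLM with denominator
degrees of freedom assigned by the between-within (containment) convention
used by nlme's ``lme``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from sigwhistle.features import PARAM_COLUMNS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-SW means, Bray-Curtis, nMDS
# ---------------------------------------------------------------------------

def mean_feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of the seven parameters per SW-ID (one row per SW).

    Site and region-style grouping columns are carried along (they are
    constant within an SW-ID).
    """
    if features.empty:
        raise ValueError("empty feature table")
    keep = [c for c in ("site",) if c in features.columns]
    agg = {c: "mean" for c in PARAM_COLUMNS}
    agg.update({c: "first" for c in keep})
    return features.groupby("sw_id").agg(agg)[keep + PARAM_COLUMNS]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    metric: str = "braycurtis"
    transform: str = "fourth_root"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("not a valid distance matrix")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def bray_curtis(table: pd.DataFrame, fourth_root: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows, optionally fourth-root first.

    d(x, y) = sum|x' - y'| / sum(x' + y') with x' = x^(1/4) when flagged.
    A pair of all-zero rows has undefined Bray-Curtis distance; it is set to
    0 with a warning.
    """
    x = table[PARAM_COLUMNS].to_numpy(dtype=float) if set(PARAM_COLUMNS) <= set(table.columns) \
        else table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    if fourth_root:
        x = x ** 0.25
    d = pdist(x, metric="braycurtis")
    if np.any(np.isnan(d)):
        log.warning("all-zero row pair: Bray-Curtis distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(list(table.index.astype(str)), squareform(d),
                          transform="fourth_root" if fourth_root else "none")


@dataclass
class OrdinationResult:
    coords: pd.DataFrame   # n x k
    stress: float          # Kruskal stress-1
    n_restarts: int
    seed: int
    converged: bool = True


def nmds(dist: DistanceMatrix, k: int = 2, n_restarts: int = 50,
         seed: int = 0, max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS (best of ``n_restarts`` random starts, Kruskal stress-1).

    Coordinates are normalised to a canonical orientation (centred, rotated
    to principal axes, signs fixed) so that seeded runs are reproducible up
    to the inherent rotation/reflection indeterminacy.
    """
    from sklearn.manifold import MDS

    if dist.n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for a {k}-D ordination")
    mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
              n_init=n_restarts, max_iter=max_iter, random_state=seed,
              normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(dist.matrix)
    stress = float(mds.stress_)
    coords = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(coords, full_matrices=False)
    coords = u * s  # principal-axis rotation
    for j in range(coords.shape[1]):  # sign convention: largest |coord| positive
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    cols = [f"nMDS{j + 1}" for j in range(k)]
    return OrdinationResult(pd.DataFrame(coords, index=dist.labels, columns=cols),
                            stress, n_restarts, seed,
                            converged=mds.n_iter_ < max_iter)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    factor: str = ""


def _distinct_permutations(items: list):
    """Yield the distinct permutations of a multiset (lexicographic order)."""
    pool = sorted(items)
    n = len(pool)
    counts: dict = {}
    for x in pool:
        counts[x] = counts.get(x, 0) + 1
    keys = sorted(counts)
    out: list = [None] * n

    def rec(depth: int):
        if depth == n:
            yield tuple(out)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                out[depth] = k
                yield from rec(depth + 1)
                counts[k] += 1

    yield from rec(0)


def anosim(dist: DistanceMatrix, grouping, n_perm: int = 999,
           seed: int = 0, factor: str = "", method: str = "permutation") -> AnosimResult:
    """One-way ANOSIM on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2 pairwise distances ranked with midranks for ties.  With
    ``method="permutation"`` (default) the one-sided p-value is
    (1 + #{permuted R >= observed}) / (1 + n_perm) over random label
    permutations; ``method="exhaustive"`` enumerates every distinct label
    assignment (small n only) and reports the exact fraction with
    R >= observed.
    """
    labels = np.asarray(list(grouping))
    n = dist.n
    if labels.shape[0] != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    for g, c in zip(uniq, counts):
        if c < 2:
            raise ValueError(f"group {g!r} has fewer than two members")
    ranks = sst.rankdata(dist.condensed())
    m = ranks.size
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return (rb - rw) / (m / 2.0)

    observed = r_stat(labels)
    if method == "exhaustive":
        r_all = np.array([r_stat(np.asarray(p)) for p in
                          _distinct_permutations(list(labels))])
        p = float(np.mean(r_all >= observed - 1e-12))
        return AnosimResult(float(observed), p, len(r_all), factor)
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'exhaustive'")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=labels.dtype)
    for i in range(n_perm):
        perms[i] = rng.permutation(labels)
    within = perms[:, iu] == perms[:, ju]                       # (n_perm, M)
    rw = (within * ranks).sum(axis=1) / within.sum(axis=1)
    rb = ((~within) * ranks).sum(axis=1) / (~within).sum(axis=1)
    r_perm = (rb - rw) / (m / 2.0)
    p = (1.0 + np.sum(r_perm >= observed - 1e-12)) / (1.0 + n_perm)
    return AnosimResult(float(observed), float(p), n_perm, factor)


# ---------------------------------------------------------------------------
# PCA with Kaiser retention
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    loadings: pd.DataFrame        # p x p eigenvectors (columns PC1..PCp)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    n_retained: int
    scores: pd.DataFrame          # n x p

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, :self.n_retained]


def remove_outliers(features: pd.DataFrame, z_max: float = 3.0) -> pd.DataFrame:
    """Drop rows with |robust z| > ``z_max`` on any raw parameter.

    Robust z uses the median and 1.4826*MAD.  The number of removed rows is
    logged (field workflows drop extreme contours before ordination/PCA but
    rarely state the rule; this one is transparent and configurable).
    """
    x = features[PARAM_COLUMNS].to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0) * 1.4826
    mad[mad == 0] = np.inf
    z = np.abs(x - med) / mad
    keep = (z <= z_max).all(axis=1)
    if (~keep).any():
        log.info("outlier removal: dropped %d of %d rows", int((~keep).sum()), len(features))
    return features.loc[keep]


def pca_reduce(table: pd.DataFrame, kaiser: bool = True) -> PcaResult:
    """Correlation-matrix PCA of the seven-parameter table.

    Components are eigenvectors of the correlation matrix, ordered by
    decreasing eigenvalue; with ``kaiser`` only components with eigenvalue
    >= 1 are retained.  Eigenvector signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    cols = [c for c in PARAM_COLUMNS if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least two parameter columns")
    x = table[cols].to_numpy(dtype=float)
    if x.shape[0] < len(cols) + 1:
        raise ValueError("need more observations than parameters")
    sd = x.std(axis=0, ddof=1)
    for c, s in zip(cols, sd):
        if s == 0:
            raise ValueError(f"column {c!r} is constant; cannot standardise")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    n_retained = int(np.sum(eigval >= 1.0)) if kaiser else len(cols)
    pcs = [f"PC{j + 1}" for j in range(len(cols))]
    loadings = pd.DataFrame(eigvec, index=cols, columns=pcs)
    scores = pd.DataFrame(z @ eigvec, index=table.index, columns=pcs)
    return PcaResult(loadings, eigval, eigval / eigval.sum(), n_retained, scores)


def orient_components(pca: PcaResult, conventions: dict[str, tuple[str, int]]) -> PcaResult:
    """Flip component signs to a reporting convention.

    ``conventions`` maps component name -> (parameter, sign): e.g.
    ``{"PC1": ("max_freq", -1)}`` orients PC1 so its max-frequency loading
    is negative.  Eigenvector sign is arbitrary; this pins it for reporting.
    """
    for pc, (param, sign) in conventions.items():
        if np.sign(pca.loadings.loc[param, pc]) != np.sign(sign):
            pca.loadings[pc] = -pca.loadings[pc]
            pca.scores[pc] = -pca.scores[pc]
    return pca


def dominant_component(pca: PcaResult, params: list[str]) -> str:
    """Retained component with the largest mean |loading| on ``params``."""
    retained = pca.loadings.columns[:pca.n_retained]
    weights = pca.loadings.loc[params, retained].abs().mean(axis=0)
    return str(weights.idxmax())


# ---------------------------------------------------------------------------
# Gaussian mixed models with SW-ID random intercepts
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Fixed-effect table and variance components of one mixed model.

    ``fixed_effects`` columns: Value, SE, DF, t-value, p-value (the layout
    of published per-factor model tables); DF follow the between-within
    (containment) convention.
    """

    response: str
    factor: str
    fixed_effects: pd.DataFrame
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    boundary: bool = False
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


def fit_glmm(data: pd.DataFrame, response: str, factor: str,
             group: str = "sw_id", reml: bool = True,
             level_order: list[str] | None = None) -> ModelResult:
    """Gaussian linear mixed model: ``response ~ factor + (1 | group)``.

    REML fit via statsmodels MixedLM.  Denominator DF: a fixed term constant
    within every group is tested against between-group information,
    DF = n_groups - 1 - n_between_terms; terms varying within groups (and
    the intercept) use DF = n_obs - n_groups - n_within_terms.  p-values are
    two-sided t.  A near-zero random-intercept variance is flagged as a
    boundary fit, not an error.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    d = data[[response, factor, group]].dropna().copy()
    levels = level_order or sorted(d[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least two levels")
    d[factor] = pd.Categorical(d[factor].astype(str), categories=levels)
    per_level_groups = d.groupby(factor, observed=True)[group].nunique()
    if (per_level_groups < 2).any():
        bad = per_level_groups[per_level_groups < 2].index.tolist()
        raise ValueError(f"levels {bad} have fewer than two {group} groups")
    dummies = pd.get_dummies(d[factor], drop_first=True, dtype=float)
    exog = pd.concat([pd.Series(1.0, index=d.index, name="Intercept"), dummies], axis=1)
    endog = d[response].astype(float)
    groups = d[group].to_numpy()

    model = sm.MixedLM(endog, exog, groups=groups)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=reml, method=method, maxiter=2000)
            except Exception:
                continue
            if fit.converged:
                break
    if fit is None:
        raise RuntimeError(f"mixed model for {response} ~ {factor} failed to converge")

    n_obs = len(d)
    n_groups = len(np.unique(groups))
    # classify each term: between (constant within all groups) or within
    gidx = pd.Series(groups, index=d.index)
    is_between = {}
    for col in exog.columns:
        if col == "Intercept":
            is_between[col] = False  # containment: intercept at the innermost level
        else:
            nun = exog[col].groupby(gidx).nunique()
            is_between[col] = bool((nun == 1).all())
    n_between = sum(1 for c, b in is_between.items() if b)
    n_within = len(exog.columns) - n_between
    df_between = max(n_groups - 1 - n_between, 1)
    df_within = max(n_obs - n_groups - n_within, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bse_fe = fit.bse_fe
    rows = []
    for col in exog.columns:
        est = float(fit.fe_params[col])
        se = float(bse_fe[col])
        df = df_between if is_between[col] else df_within
        t = est / se
        p = 2.0 * sst.t.sf(abs(t), df)
        rows.append((col, est, se, df, t, p))
    fe = pd.DataFrame(rows, columns=["term", "Value", "SE", "DF", "t-value",
                                     "p-value"]).set_index("term")
    re_sd = float(np.sqrt(fit.cov_re.iloc[0, 0]))
    resid_sd = float(np.sqrt(fit.scale))
    boundary = re_sd < 1e-4 * max(resid_sd, 1e-12)

    resid = np.asarray(fit.resid)
    fitted = np.asarray(fit.fittedvalues)
    sub = slice(None) if resid.size <= 500 else np.sort(
        np.random.default_rng(0).choice(resid.size, 500, replace=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw_p = float(sst.shapiro(resid[sub]).pvalue) if resid.size >= 3 else np.nan
        het = sst.spearmanr(fitted, np.abs(resid))
    diagnostics = {"resid_mean": float(resid.mean()),
                   "shapiro_p": sw_p,
                   "abs_resid_vs_fitted_rho": float(het.statistic),
                   "abs_resid_vs_fitted_p": float(het.pvalue)}
    return ModelResult(response, factor, fe, re_sd, resid_sd, n_obs, n_groups,
                       boundary=boundary, converged=bool(fit.converged),
                       diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# site clustering (sea bottom: Ward; demography: complete linkage)
# ---------------------------------------------------------------------------

@dataclass
class SiteClustering:
    sites: list[str]
    clusters: list[str]
    linkage: str
    n_clusters: int

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.sites, self.clusters))


def encode_site_table(table: pd.DataFrame) -> pd.DataFrame:
    """Encode a mixed-type site table for Euclidean clustering.

    Numeric columns are standardised (zero SD columns set to 0); two-level
    categorical columns become a single 0/1 indicator, wider ones one-hot
    0/1 columns.
    """
    out = {}
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_numeric_dtype(s):
            sd = s.std(ddof=1)
            out[col] = (s - s.mean()) / sd if sd > 0 else s * 0.0
        else:
            cats = sorted(s.astype(str).unique())
            if len(cats) <= 2:
                out[col] = (s.astype(str) == cats[-1]).astype(float)
            else:
                for c in cats:
                    out[f"{col}={c}"] = (s.astype(str) == c).astype(float)
    return pd.DataFrame(out, index=table.index)


def seabottom_clustering(profiles: pd.DataFrame, n_clusters: int = 3) -> SiteClustering:
    """Sea-bottom factor: Ward clustering of habitat indicators and depth."""
    cols = [c for c in profiles.columns if c.startswith("hab_")] + ["depth_max_m"]
    return cluster_sites(profiles[cols], "ward", n_clusters, prefix="H")


def demography_clustering(profiles: pd.DataFrame, n_clusters: int = 4) -> SiteClustering:
    """Demography factor: complete-linkage clustering of the six demographic
    variables (mean and range of population size, mean and range of group
    size, residency pattern, connection with adjacent populations)."""
    t = profiles[["pop_size_mean", "group_size_mean", "residency",
                  "connection"]].copy()
    t["pop_size_range"] = profiles["pop_size_hi"] - profiles["pop_size_lo"]
    t["group_size_range"] = profiles["group_size_max"] - profiles["group_size_min"]
    return cluster_sites(t, "complete", n_clusters, prefix="P")


def cluster_sites(site_table: pd.DataFrame, linkage: str = "ward",
                  n_clusters: int = 3, prefix: str = "C") -> SiteClustering:
    """Agglomerative clustering of sites on Euclidean distances.

    ``linkage`` is ``"ward"`` (used for the sea-bottom factor) or
    ``"complete"`` (demography).  Cluster labels are renumbered by first
    appearance in input order, so results are deterministic.
    """
    if linkage not in ("ward", "complete"):
        raise ValueError("linkage must be 'ward' or 'complete'")
    if n_clusters > len(site_table):
        raise ValueError("n_clusters exceeds the number of sites")
    x = encode_site_table(site_table).to_numpy(dtype=float)
    z = scipy_linkage(x, method=linkage, metric="euclidean")
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    labels = [f"{prefix}{relabel[r]}" for r in raw]
    return SiteClustering(list(site_table.index.astype(str)), labels, linkage,
                          n_clusters)
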