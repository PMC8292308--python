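"""SNP filtering, ordination, genotype-environment association, and F_ST.

The genotype container is a plain individuals x sites matrix coded
0/1/2 (alt-allele dosage) with NaN for missing calls, plus per-site mean
depth and individual -> population / species maps.  On top of it:

* the site-filter cascade (depth, minor-allele count, missingness,
  individual missingness, strict missingness, per-species HWE exact test);
* modal imputation by species, PCA of the centered matrix;
* partial redundancy analysis (RDA) conditioned on ancestry axes, with
  ANOVA-like permutation tests and per-variable variance partitioning on
  the Ezekiel-adjusted R^2 scale;
* pairwise Weir-Cockerham theta (weighted across sites);
* VIF screening and greedy correlation pruning of climate variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GenoMatrix",
    "FilterReport",
    "RdaResult",
    "filter_sites",
    "hwe_exact_test",
    "impute_major",
    "pca_genotypes",
    "partial_rda",
    "permutation_anova",
    "variance_partition",
    "weir_fst",
    "weir_fst_components",
    "vif",
    "correlation_prune",
    "write_vcf",
    "read_vcf",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass
class GenoMatrix:
    """Biallelic genotypes: individuals x sites, {0,1,2,NaN} dosage coding."""

    genotypes: np.ndarray
    mean_depth: np.ndarray
    individuals: list[str]
    populations: np.ndarray
    species: np.ndarray | None = None
    site_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        self.populations = np.asarray(self.populations)
        n, m = self.genotypes.shape
        if self.species is None:
            self.species = self.populations.copy()
        else:
            self.species = np.asarray(self.species)
        if self.site_ids is None:
            self.site_ids = [f"site_{j}" for j in range(m)]
        if len(self.individuals) != n or len(self.populations) != n:
            raise ValueError("individual maps inconsistent with genotype matrix")
        if self.mean_depth.shape != (m,):
            raise ValueError("mean_depth inconsistent with genotype matrix")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotypes must be coded 0/1/2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, mask: np.ndarray) -> "GenoMatrix":
        idx = np.flatnonzero(mask)
        return GenoMatrix(
            self.genotypes[:, idx], self.mean_depth[idx], list(self.individuals),
            self.populations, self.species, [self.site_ids[j] for j in idx],
        )

    def take_individuals(self, mask: np.ndarray) -> "GenoMatrix":
        idx = np.flatnonzero(mask)
        return GenoMatrix(
            self.genotypes[idx], self.mean_depth, [self.individuals[i] for i in idx],
            self.populations[idx], self.species[idx], list(self.site_ids),
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value (conditional on allele counts).

    Sums the conditional probabilities of all heterozygote counts no
    more probable than the observed one (the Wigginton et al. convention).
    Monomorphic sites return p = 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1 or min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("counts must be nonnegative with n >= 1")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h | n, n_a) up to the common normalizer
    hom_a = (n_a - hets) // 2
    hom_b = (n_b - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_a + 1) - gammaln(hets + 1) - gammaln(hom_b + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Site filtering


@dataclass
class FilterReport:
    steps: list[tuple[str, int]] = field(default_factory=list)
    individuals_removed: list[str] = field(default_factory=list)
    n_input_sites: int = 0
    n_output_sites: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed"])


def filter_sites(
    g: GenoMatrix,
    min_mean_dp: float = 5.0,
    max_mean_dp: float = 50.0,
    mac: int = 3,
    max_missing_frac: float = 0.5,
    ind_max_missing: float = 0.6,
    strict_missing_frac: float = 0.05,
    hwe_p: float = 0.001,
) -> tuple[GenoMatrix, FilterReport]:
    """Apply the site-filter cascade in its fixed order.

    depth -> minor-allele count -> site missingness -> individual
    missingness -> strict site missingness -> HWE by species (a site is
    dropped if it fails in any species).  The report counts removals per
    step; site-step counts sum to input minus output sites.
    """
    report = FilterReport(n_input_sites=g.n_sites)

    def _apply(name: str, keep: np.ndarray, gm: GenoMatrix) -> GenoMatrix:
        report.steps.append((name, int((~keep).sum())))
        return gm.take_sites(keep)

    keep = (g.mean_depth >= min_mean_dp) & (g.mean_depth <= max_mean_dp)
    g = _apply("mean_depth", keep, g)

    gt = g.genotypes
    alt = np.nansum(gt, axis=0)
    called = 2.0 * np.sum(~np.isnan(gt), axis=0)
    minor = np.minimum(alt, called - alt)
    g = _apply("mac", minor >= mac, g)

    miss = np.isnan(g.genotypes).mean(axis=0)
    g = _apply("max_missing", miss <= max_missing_frac, g)

    ind_miss = np.isnan(g.genotypes).mean(axis=1)
    drop_ind = ind_miss > ind_max_missing
    report.individuals_removed = [
        ind for ind, d in zip(g.individuals, drop_ind) if d
    ]
    g = g.take_individuals(~drop_ind)

    miss = np.isnan(g.genotypes).mean(axis=0)
    g = _apply("strict_missing", miss <= strict_missing_frac, g)

    fail = np.zeros(g.n_sites, dtype=bool)
    for sp in np.unique(g.species):
        sub = g.genotypes[g.species == sp]
        for j in range(g.n_sites):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            if hwe_exact_test(*counts) < hwe_p:
                fail[j] = True
    g = _apply("hwe", ~fail, g)

    report.n_output_sites = g.n_sites
    if g.n_sites == 0:
        warnings.warn("all sites removed by filters")
    return g, report


def impute_major(g: GenoMatrix) -> GenoMatrix:
    """Replace missing calls with the species' modal genotype at the site.

    Ties between equally common genotypes break toward the lower dosage
    code (logged).  An all-missing (species, site) cell is an error.
    """
    gt = g.genotypes.copy()
    bad = []
    for sp in np.unique(g.species):
        rows = g.species == sp
        sub = gt[rows]
        counts = np.stack([(sub == v).sum(axis=0) for v in (0.0, 1.0, 2.0)])
        observed = counts.sum(axis=0)
        mode = counts.argmax(axis=0).astype(float)  # argmax takes lowest on ties
        n_ties = int(((counts == counts.max(axis=0)).sum(axis=0) > 1).sum())
        if n_ties:
            logger.info("impute_major: %d tied modes for %s broken to lower code",
                        n_ties, sp)
        miss = np.isnan(sub)
        empty = np.flatnonzero(observed == 0)
        for j in empty:
            if miss[:, j].any():
                bad.append((sp, g.site_ids[j]))
        sub[miss] = np.broadcast_to(mode, sub.shape)[miss]
        gt[rows] = sub
    if bad:
        raise ValueError(f"all-missing (species, site) cells: {bad}")
    return GenoMatrix(gt, g.mean_depth, g.individuals, g.populations,
                      g.species, g.site_ids)


# ---------------------------------------------------------------------------
# Ordination


def pca_genotypes(g: GenoMatrix | np.ndarray, n_axes: int = 2):
    """PCA of the column-centered genotype matrix via SVD.

    Returns (scores, pct_variance): scores are U * s for the leading
    axes; pct variance is each squared singular value as a percentage of
    their total.
    """
    X = g.genotypes if isinstance(g, GenoMatrix) else np.asarray(g, float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_axes > rank:
        warnings.warn(f"n_axes={n_axes} exceeds rank {rank}; truncating")
        n_axes = rank
    pct = 100.0 * s ** 2 / np.sum(s ** 2)
    return U[:, :n_axes] * s[:n_axes], pct[:n_axes]


def _condition_basis(n: int, Z: np.ndarray | None) -> np.ndarray:
    Z1 = np.column_stack([np.ones(n), Z]) if Z is not None else np.ones((n, 1))
    Q, _ = np.linalg.qr(Z1)
    return Q


def _residualize(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of Y on [1 Z] (intercept always included)."""
    Q = _condition_basis(len(Y), Z)
    return Y - Q @ (Q.T @ Y)


def _ezekiel(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p)


@dataclass
class RdaResult:
    """Conditioned-ordination output plus the state permutation tests need."""

    scores: np.ndarray          # individuals x constrained axes (fitted-site)
    loadings: pd.DataFrame      # climate variables x axes (corr with scores)
    eigenvalues: np.ndarray
    r2_constrained: float       # raw fraction of total inertia
    r2_conditional: float
    r2_residual: float
    adj_r2_constrained: float
    adj_r2_conditional: float
    pseudo_f: float
    n: int
    n_constraints: int
    n_conditions: int
    p_model: float | None = None
    p_axes: np.ndarray | None = None
    # internal state for permutation tests
    _Q_x: np.ndarray | None = None   # orthonormal basis of residualized climate
    _Q_z: np.ndarray | None = None   # orthonormal basis of [1, condition]
    _R_g: np.ndarray | None = None   # reduced residualized genotypes (U*s)
    _ss_res: float = 0.0
    _df_res: int = 0


def vif(clim: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per variable: 1/(1 - R^2_j | others)."""
    X = clim.to_numpy(float)
    X = X - X.mean(axis=0)
    out = {}
    for j, name in enumerate(clim.columns):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        yj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        r2 = 1.0 - resid @ resid / (yj @ yj)
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def correlation_prune(clim: pd.DataFrame, r_max: float = 0.70) -> list[str]:
    """Greedy pruning of |r| >= r_max pairs.

    From the most-correlated pair, the member with the larger mean |r|
    against all remaining variables is dropped; repeats until all
    pairwise |r| < r_max.  Deterministic (ties keep the earlier column).
    """
    cols = list(clim.columns)
    while len(cols) > 1:
        R = clim[cols].corr().abs().to_numpy()
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] < r_max:
            break
        mean_r = R.sum(axis=0) / (len(cols) - 1)
        drop = cols[j] if mean_r[j] >= mean_r[i] else cols[i]
        logger.info("correlation_prune: dropping %s (|r|=%.3f)", drop, R[i, j])
        cols.remove(drop)
    return cols


def partial_rda(
    g: GenoMatrix | np.ndarray,
    clim: pd.DataFrame,
    condition: np.ndarray | None = None,
    n_axes: int | None = None,
    check_vif: bool = True,
    vif_max: float = 5.0,
    scale_genotypes: bool = False,
) -> RdaResult:
    """Partial RDA of genotypes on climate, conditioned on ancestry axes.

    Genotypes are column-centered (variance scaling optional, off by
    default); both matrices are residualized on [1, condition]; the
    constrained axes are the SVD of the fitted values of the multivariate
    regression of residual genotypes on residual climate.  Raw fractions
    are of the total inertia of the centered genotype matrix; adjusted
    fractions use the Ezekiel correction applied semipartially (adjusted
    R^2 of condition+climate minus that of condition alone).
    """
    X = g.genotypes if isinstance(g, GenoMatrix) else np.asarray(g, float)
    if np.isnan(X).any():
        raise ValueError("partial RDA requires a complete (imputed) matrix")
    if check_vif and clim.shape[1] > 1:
        v = vif(clim)
        bad = v[v >= vif_max]
        if len(bad):
            raise ValueError(f"VIF >= {vif_max} for: {list(bad.index)}")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    if scale_genotypes:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    ss_total = float((Xc ** 2).sum())

    q = 0 if condition is None else np.atleast_2d(condition.T).T.shape[1]
    G_r = _residualize(Xc, condition)
    ss_cond = ss_total - float((G_r ** 2).sum())

    C = clim.to_numpy(float)
    C_r = _residualize(C, condition)
    Qx, _ = np.linalg.qr(C_r)
    m = C.shape[1]
    fitted = Qx @ (Qx.T @ G_r)
    ss_fit = float((fitted ** 2).sum())
    ss_res = float(((G_r - fitted) ** 2).sum())

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = min(m, int((s > max(s[0], 1e-300) * 1e-9).sum())) if s.size else 0
    if n_axes is not None:
        k = min(k, n_axes)
    scores = U[:, :k] * s[:k]
    eig = s[:k] ** 2

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.array([
            [np.corrcoef(C_r[:, j], scores[:, a])[0, 1] if scores[:, a].std() > 0 else 0.0
             for a in range(k)]
            for j in range(m)
        ]) if k else np.zeros((m, 0))
    loadings = pd.DataFrame(corr, index=clim.columns,
                            columns=[f"RDA{a + 1}" for a in range(k)])

    r2_cond = ss_cond / ss_total
    r2_con = ss_fit / ss_total
    df_res = n - 1 - q - m
    pseudo_f = (ss_fit / m) / (ss_res / df_res) if df_res > 0 and ss_res > 0 else np.inf
    adj_cond = _ezekiel(r2_cond, n, q) if q else 0.0
    adj_full = _ezekiel(r2_cond + r2_con, n, q + m)
    return RdaResult(
        scores=scores, loadings=loadings, eigenvalues=eig,
        r2_constrained=r2_con, r2_conditional=r2_cond,
        r2_residual=ss_res / ss_total,
        adj_r2_constrained=adj_full - adj_cond, adj_r2_conditional=adj_cond,
        pseudo_f=pseudo_f, n=n, n_constraints=m, n_conditions=q,
        _Q_x=Qx, _Q_z=_condition_basis(n, condition),
        _R_g=_reduce(G_r), _ss_res=ss_res, _df_res=df_res,
    )


def _reduce(G_r: np.ndarray) -> np.ndarray:
    """Rank-reduced stand-in for the residualized genotype matrix.

    U*s from the SVD preserves every inner product Q^T G_r needs, so
    permutation statistics computed on it are exact while each
    permutation costs O(n^2 m) instead of O(n m n_loci).
    """
    Ug, sg, _ = np.linalg.svd(G_r, full_matrices=False)
    keep = sg > (sg[0] * 1e-12 if sg.size else 0)
    return Ug[:, keep] * sg[keep]


def permutation_anova(
    rda: RdaResult,
    n_perm_model: int = 999,
    n_perm_axes: int = 299,
    n_axes_test: int | None = None,
    seed: int | np.random.Generator = 0,
) -> RdaResult:
    """ANOVA-like permutation tests for the RDA model and its axes.

    The model test permutes rows of the residualized climate matrix,
    re-residualizes the permuted predictors on the conditioning basis
    (so permuted predictors compete in the same reduced space as the
    observed ones), and recomputes the pseudo-F; axis k is tested
    marginally by comparing its eigenvalue with the k-th ordered
    eigenvalue under the same scheme.  p-values use the
    (exceedances + 1)/(n + 1) convention.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Qx, Qz, Rg = rda._Q_x, rda._Q_z, rda._R_g
    n, m = Qx.shape

    def _perm_proj(n_perm: int) -> np.ndarray:
        """Projections Q_perm^T R_g for row-permuted, re-residualized climate."""
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        Xp = Qx[perms]                                    # (n_perm, n, m)
        Xp = Xp - Qz @ np.matmul(Qz.T, Xp)                # back into the reduced space
        Qp, _ = np.linalg.qr(Xp)
        return np.matmul(np.swapaxes(Qp, 1, 2), Rg)       # (n_perm, m, r)

    # reduced genotypes make each permutation an (m x n)(n x r) product
    obs_f = rda.pseudo_f
    proj = _perm_proj(n_perm_model)
    ss_fit_p = (proj ** 2).sum(axis=(1, 2))
    ss_tot_r = float((Rg ** 2).sum())
    ss_res_p = ss_tot_r - ss_fit_p
    f_p = (ss_fit_p / m) / (ss_res_p / rda._df_res)
    rda.p_model = float(((f_p >= obs_f - 1e-12).sum() + 1) / (n_perm_model + 1))

    k = len(rda.eigenvalues) if n_axes_test is None else min(n_axes_test, len(rda.eigenvalues))
    if k:
        sv = np.linalg.svd(_perm_proj(n_perm_axes), compute_uv=False) ** 2
        p_axes = np.empty(k)
        for a in range(k):
            null = sv[:, a] if a < sv.shape[1] else np.zeros(n_perm_axes)
            p_axes[a] = ((null >= rda.eigenvalues[a] - 1e-12).sum() + 1) / (n_perm_axes + 1)
        rda.p_axes = p_axes
    return rda


def variance_partition(
    g: GenoMatrix | np.ndarray,
    clim: pd.DataFrame,
    condition: np.ndarray | None,
    mode: str = "marginal",
    check_vif: bool = True,
) -> pd.DataFrame:
    """Per-variable adjusted-R^2 fractions of genetic variance.

    ``marginal`` (default): each variable's fraction is the adjusted R^2
    of a partial RDA constrained on that variable alone (conditioned on
    the ancestry axes); under collinearity these need not sum to the
    constrained total.  ``unique``: leave-one-out differences against
    the full model.  The table ends with constrained-total and
    conditional-total rows.
    """
    full = partial_rda(g, clim, condition, check_vif=check_vif)
    rows = []
    for v in clim.columns:
        if mode == "marginal":
            one = partial_rda(g, clim[[v]], condition, check_vif=False)
            frac = one.adj_r2_constrained
        elif mode == "unique":
            rest = [c for c in clim.columns if c != v]
            sub = partial_rda(g, clim[rest], condition, check_vif=False)
            frac = full.adj_r2_constrained - sub.adj_r2_constrained
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append((v, frac))
    rows.append(("constrained_total", full.adj_r2_constrained))
    rows.append(("conditional_total", full.adj_r2_conditional))
    return pd.DataFrame(rows, columns=["variable", "adj_r2"])


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def weir_fst_components(
    gt: np.ndarray, pops: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c).

    ``gt`` is individuals x sites 0/1/2 with NaN missing; ``pops`` labels
    rows.  Sites monomorphic across the included populations (or with
    fewer than two populations containing data) get a = b = c = 0.
    """
    labels = np.unique(pops)
    r = len(labels)
    if r < 2:
        raise ValueError("Weir-Cockerham theta needs >= 2 populations")
    n_i = np.stack([np.sum(~np.isnan(gt[pops == l]), axis=0) for l in labels]).astype(float)
    with np.errstate(invalid="ignore"):
        p_i = np.stack([np.nansum(gt[pops == l], axis=0) for l in labels]) / (2 * n_i)
        h_i = np.stack([np.nansum(gt[pops == l] == 1, axis=0) for l in labels]) / n_i
    valid = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (sum_n - (n_i ** 2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / sum_n
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / sum_n
        pq = pbar * (1 - pbar)
        a = (nbar / n_c) * (
            s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    mono = (pbar <= 0) | (pbar >= 1)
    drop = mono | ~valid | (nbar <= 1) | (n_c <= 0)
    for arr in (a, b, c):
        arr[drop] = 0.0
        np.nan_to_num(arr, copy=False)
    return a, b, c


def weir_fst(g: GenoMatrix, pops: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise weighted Weir's theta: sum(a) / sum(a+b+c) across sites.

    Returns a symmetric populations x populations DataFrame (diagonal 0).
    A pair with no polymorphic site gets NaN and is flagged.
    """
    pops = g.populations if pops is None else np.asarray(pops)
    labels = list(np.unique(pops))
    if len(labels) < 2:
        warnings.warn("single population: theta undefined")
        return pd.DataFrame(np.full((1, 1), np.nan), index=labels, columns=labels)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, li in enumerate(labels):
        for lj in labels[i + 1:]:
            rows = (pops == li) | (pops == lj)
            a, b, c = weir_fst_components(g.genotypes[rows], pops[rows])
            denom = (a + b + c).sum()
            theta = a.sum() / denom if denom > 0 else np.nan
            if not np.isfinite(theta):
                warnings.warn(f"theta undefined for pair ({li}, {lj})")
            out.loc[li, lj] = out.loc[lj, li] = theta
    return out


# ---------------------------------------------------------------------------
# I/O


def write_vcf(g: GenoMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with per-site mean depth in INFO/MDP."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean depth across individuals">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individuals) + "\n")
        for j in range(g.n_sites):
            gts = "\t".join(
                code.get(g.genotypes[i, j], "./.") for i in range(g.n_individuals)
            )
            fh.write(f"1\t{j + 1}\t{g.site_ids[j]}\tA\tG\t.\tPASS\t"
                     f"MDP={g.mean_depth[j]:.2f}\tGT\t{gts}\n")


def read_vcf(path: str | Path, popmap: pd.DataFrame) -> GenoMatrix:
    """Read a biallelic VCF (via cyvcf2) into a GenoMatrix.

    ``popmap`` needs columns id, population and optionally species.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    rows, depth, ids = [], [], []
    for rec in vcf:
        gt = rec.gt_types.astype(float)   # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        mdp = rec.INFO.get("MDP")
        depth.append(float(mdp) if mdp is not None else np.nan)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    pm = popmap.set_index("id")
    pops = pm.loc[individuals, "population"].to_numpy()
    species = (pm.loc[individuals, "species"].to_numpy()
               if "species" in pm.columns else None)
    return GenoMatrix(np.array(rows).T, np.array(depth), individuals, pops,
                      species, ids)


def write_matrix_csv(g: GenoMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.genotypes, index=g.individuals, columns=g.site_ids)
    df.insert(0, "population", g.populations)
    df.insert(1, "species", g.species)
    df.to_csv(path, index_label="id")


def read_matrix_csv(path: str | Path, mean_depth: np.ndarray | None = None) -> GenoMatrix:
    df = pd.read_csv(path, index_col="id")
    pops = df.pop("population").to_numpy()
    species = df.pop("species").to_numpy() if "species" in df.columns else None
    gt = df.to_numpy(float)
    md = np.full(gt.shape[1], np.nan) if mean_depth is None else mean_depth
    return GenoMatrix(gt, md, list(df.index.astype(str)), pops, species,
                      list(df.columns))
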