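"""Multi-trait mixed-model QTL engine: SIM, CIM, threshold, final model.

The scan jointly analyses the three line-mean responses (RNRG and grain
yield in the two field environments).  At every grid position the model is

    y_t = mu_t + sum_c gamma_ct x_c + alpha_t x + residual_t

with trait-specific QTL allele-substitution effects ``alpha_t`` and an
unstructured residual covariance across traits that absorbs the polygenic
background (with one observation per line per trait, polygenic and error
terms are jointly unidentifiable, so they are combined; optional per-trait
error floors from stage 1 separate the genetic variance again when
computing %GV).  Because the regressor set is identical across traits,
per-trait least squares is fully efficient and the residual covariance is
estimated from the stacked residuals.

Presence of a QTL is tested with the multi-trait Wald statistic
W = alpha' V(alpha)^-1 alpha with df = number of traits.  With the residual
covariance estimated from n lines, W is exactly Hotelling's T-squared, so
default p-values use the finite-sample T2 -> F transform (the asymptotic
chi-square reference is available as an option but is anticonservative in
the far tail at n = 90).

The genome-wide threshold converts a target genome-wide level alpha into a
comparisonwise p cutoff through the effective number of independent tests
(Li-Ji): per chromosome, eigenvalues of the marker correlation matrix give
M_eff = sum over lambda of [1{lambda >= 1} + (lambda - floor(lambda))],
summed over chromosomes, and cutoff = 1 - (1 - alpha)^(1/M_eff).

The mapping protocol is: simple interval mapping -> candidate peaks ->
composite interval mapping with candidates as cofactors (excluding
cofactors within a window of the tested position on the same chromosome),
iterated until the candidate set stabilises -> backward elimination of the
joint model -> final effects, standard errors, high-value parent per trait,
and the percentage of genetic variance explained, estimated from the drop
in polygenic variance when each QTL enters the base (polygenic-only) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genmap import (
    GeneticMap,
    GenotypeMatrix,
    QTLGenotypeScores,
    build_scan_grid,
    genotype_probabilities,
)

logger = logging.getLogger("altqtl")

_COLLINEARITY_R = 0.999  # skip positions whose score is this collinear with cofactors


# ---------------------------------------------------------------------------
# results containers


@dataclass(frozen=True)
class ScanResult:
    """Per-position multi-trait Wald profile.

    ``table`` columns: chromosome, position_cM, wald, p, neglog10p; rows are
    aligned with the scan grid.  ``threshold`` is the -log10(p) cutoff (None
    until set) and ``cofactors`` the grid indices used as CIM cofactors.
    """

    table: pd.DataFrame
    threshold: float | None = None
    cofactors: tuple[int, ...] = ()


@dataclass(frozen=True)
class BaseModelFit:
    """Polygenic-only fit: trait means and unstructured covariance."""

    means: pd.Series
    sigma: pd.DataFrame  # combined polygenic + error covariance of line means
    error_floors: pd.Series
    polygenic_var: pd.Series  # diag(sigma) - floor, floored at 0


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    p: float
    effects: np.ndarray
    ses: np.ndarray


# ---------------------------------------------------------------------------
# p-values


def wald_pvalue(w, k: int, nu: int, method: str = "f"):
    """Tail probability of the multi-trait Wald statistic.

    ``method='f'`` uses the exact Hotelling transform
    T2 * (nu - k + 1) / (nu k) ~ F(k, nu - k + 1) for a residual covariance
    on ``nu`` degrees of freedom; ``method='chi2'`` is the asymptotic
    chi-square(k) reference.
    """
    w = np.asarray(w, dtype=float)
    if method == "chi2":
        p = stats.chi2.sf(w, k)
    elif method == "f":
        if nu - k + 1 < 1:
            raise ValueError("too few lines for the F reference")
        p = stats.f.sf(w * (nu - k + 1) / (nu * k), k, nu - k + 1)
    else:
        raise ValueError(f"unknown pvalue method {method!r}")
    return p if np.ndim(w) else float(p)


# ---------------------------------------------------------------------------
# core least-squares machinery (identical regressors across traits)


def _project_out(Q: np.ndarray, M: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def _basis(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q


def _scan_block(Yr: np.ndarray, Sr: np.ndarray, n: int, p_base: int,
                valid: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Wald statistics for many score columns sharing one cofactor basis.

    ``Yr``/``Sr`` are the traits / scores with the base design (intercept +
    cofactors, ``p_base`` columns) projected out; positions where ``valid``
    is False yield NaN.
    """
    k = Yr.shape[1]
    nu = n - p_base - 1
    ssx = np.einsum("ij,ij->j", Sr, Sr)
    ok = valid & (ssx > 1e-12)
    ssx_safe = np.where(ok, ssx, 1.0)
    alpha = (Yr.T @ Sr) / ssx_safe  # k x m
    C = Yr.T @ Yr
    outer = np.einsum("kj,lj->jkl", alpha, alpha)
    Sig = (C[None, :, :] - ssx_safe[:, None, None] * outer) / nu
    Sig = Sig + (1e-12 * np.trace(C) / max(k, 1) / nu) * np.eye(k)[None, :, :]
    sol = np.linalg.solve(Sig, alpha.T[:, :, None])[:, :, 0]
    w = ssx_safe * np.einsum("jk,jk->j", alpha.T, sol)
    w = np.where(ok, w, np.nan)
    p = np.full(w.shape, np.nan)
    p[ok] = wald_pvalue(w[ok], k, nu, method)
    return w, p


def _joint_fit(Y: np.ndarray, X: np.ndarray):
    """Per-trait OLS with shared design; residual covariance on n-p df."""
    n, p = X.shape
    XtX = X.T @ X
    XtXi = np.linalg.pinv(XtX)
    B = XtXi @ X.T @ Y
    R = Y - X @ B
    nu = n - p
    Sigma = R.T @ R / nu
    return B, Sigma, XtXi, nu


def _joint_wald(Y: np.ndarray, X: np.ndarray, cols, method: str):
    """Wald test, effects and SEs for each design column in ``cols``."""
    B, Sigma, XtXi, nu = _joint_fit(Y, X)
    k = Y.shape[1]
    out = []
    for q in cols:
        a = B[q]
        c = float(XtXi[q, q])
        w = float(a @ np.linalg.solve(Sigma, a) / c)
        out.append(
            WaldTest(
                statistic=w,
                p=wald_pvalue(w, k, nu, method),
                effects=a.copy(),
                ses=np.sqrt(np.diag(Sigma) * c),
            )
        )
    return out, Sigma, nu


# ---------------------------------------------------------------------------
# spec operations


def fit_base_model(traits: pd.DataFrame, error_floors=None) -> BaseModelFit:
    """Polygenic-only model: trait means + unstructured covariance of line means.

    With one observation per line the REML estimate of the unstructured
    covariance is the sample covariance of line deviations.  ``error_floors``
    (per-trait sigma_e^2 / r from stage 1) split the combined variance into
    polygenic and error parts for %GV accounting.
    """
    k = traits.shape[1]
    if len(traits) < k + 2:
        raise ValueError("need at least trait-count + 2 lines")
    Y = traits.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("trait table must be complete (filter upstream)")
    sigma = np.cov(Y, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    if np.linalg.matrix_rank(sigma) < k:
        ridge = 1e-8 * np.trace(sigma)
        logger.info("singular trait covariance; adding ridge %.3g", ridge)
        sigma = sigma + ridge * np.eye(k)
    floors = _as_floor_series(error_floors, traits.columns)
    poly = pd.Series(np.maximum(np.diag(sigma) - floors.to_numpy(), 0.0),
                     index=traits.columns)
    return BaseModelFit(
        means=traits.mean(),
        sigma=pd.DataFrame(sigma, index=traits.columns, columns=traits.columns),
        error_floors=floors,
        polygenic_var=poly,
    )


def _as_floor_series(error_floors, columns) -> pd.Series:
    if error_floors is None:
        return pd.Series(0.0, index=columns)
    if isinstance(error_floors, dict):
        return pd.Series({c: float(error_floors.get(c, 0.0)) for c in columns})
    arr = np.asarray(error_floors, dtype=float)
    return pd.Series(arr, index=columns)


def wald_test_at_position(traits: pd.DataFrame, scores: np.ndarray,
                          cofactor_scores: np.ndarray | None = None,
                          pvalue_method: str = "f") -> WaldTest:
    """Multi-trait Wald test of one QTL-genotype score column.

    Returns the statistic (df = trait count), its p-value, and per-trait
    effects with standard errors.  Raises if the score column is constant or
    collinear (r > 0.999) with the cofactors.
    """
    Y = traits.to_numpy(dtype=float)
    n = len(Y)
    x = np.asarray(scores, dtype=float)
    parts = [np.ones((n, 1))]
    if cofactor_scores is not None and np.size(cofactor_scores):
        cof = np.asarray(cofactor_scores, dtype=float)
        parts.append(cof[:, None] if cof.ndim == 1 else cof)
    X_base = np.column_stack(parts)
    Q = _basis(X_base)
    xr = _project_out(Q, x[:, None])[:, 0]
    ssx_c = float(np.sum((x - x.mean()) ** 2))
    if ssx_c < 1e-12:
        raise ValueError("score column is constant across lines")
    if np.sum(xr**2) < (1 - _COLLINEARITY_R**2) * ssx_c:
        raise ValueError("score column collinear with cofactors")
    X = np.column_stack([X_base, x])
    tests, _, _ = _joint_wald(Y, X, [X.shape[1] - 1], pvalue_method)
    return tests[0]


def sim_scan(traits: pd.DataFrame, scores: QTLGenotypeScores,
             pvalue_method: str = "f") -> ScanResult:
    """Simple-interval-mapping round: Wald test at every grid position."""
    return cim_scan(traits, scores, cofactors=(), window=0.0,
                    pvalue_method=pvalue_method)


def cim_scan(traits: pd.DataFrame, scores: QTLGenotypeScores,
             cofactors: tuple[int, ...] = (), window: float = 30.0,
             pvalue_method: str = "f") -> ScanResult:
    """One composite-interval-mapping round with the given cofactor set.

    Cofactors are grid indices; a cofactor on the tested position's
    chromosome and within ``window`` cM of it is excluded from the base
    design at that position.  With no cofactors this reduces bit-for-bit to
    the SIM scan.
    """
    Y = traits.to_numpy(dtype=float)
    n, k = Y.shape
    S = np.asarray(scores.values, dtype=float)
    grid = scores.grid.table
    m = len(grid)
    chrom = grid["chromosome"].to_numpy()
    pos = grid["position_cM"].to_numpy()
    cof = tuple(int(c) for c in cofactors)

    # active cofactor set per position
    groups: dict[tuple[int, ...], list[int]] = {}
    for j in range(m):
        active = tuple(
            c for c in cof
            if not (chrom[c] == chrom[j] and abs(pos[c] - pos[j]) < window)
        )
        groups.setdefault(active, []).append(j)

    wald = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    Sc = S - S.mean(axis=0)
    ssx_c = np.einsum("ij,ij->j", Sc, Sc)
    for active, idx in groups.items():
        idx = np.asarray(idx)
        X_base = np.column_stack([np.ones(n)] + [S[:, c] for c in active])
        Q = _basis(X_base)
        Yr = _project_out(Q, Y)
        Sr = _project_out(Q, S[:, idx])
        ssx_r = np.einsum("ij,ij->j", Sr, Sr)
        valid = (ssx_c[idx] > 1e-12) & (
            ssx_r >= (1 - _COLLINEARITY_R**2) * np.maximum(ssx_c[idx], 1e-12)
        )
        n_skip = int((~valid).sum())
        if n_skip and active:
            logger.debug("skipped %d positions collinear with cofactors", n_skip)
        w, p = _scan_block(Yr, Sr, n, X_base.shape[1], valid, pvalue_method)
        wald[idx] = w
        pval[idx] = p

    with np.errstate(divide="ignore"):
        neglog = -np.log10(pval)
    table = pd.DataFrame(
        {"chromosome": chrom, "position_cM": pos, "wald": wald, "p": pval,
         "neglog10p": neglog}
    )
    return ScanResult(table=table, cofactors=cof)


def cim_round(traits: pd.DataFrame, scores: QTLGenotypeScores,
              candidates: tuple[int, ...], window: float = 30.0,
              pvalue_method: str = "f") -> ScanResult:
    """Spec-facing alias of :func:`cim_scan` with candidates as cofactors."""
    return cim_scan(traits, scores, cofactors=tuple(candidates), window=window,
                    pvalue_method=pvalue_method)


def effective_number_of_tests(geno: GenotypeMatrix, gmap: GeneticMap) -> float:
    """Li-Ji effective number of independent marker tests, summed by chromosome.

    Eigenvalues of each chromosome's marker correlation matrix contribute
    f(lambda) = 1{lambda >= 1} + (lambda - floor(lambda)); monomorphic
    markers are dropped, a single-marker chromosome contributes 1.
    """
    total = 0.0
    for chrom in gmap.chromosomes:
        G = geno.values_for(gmap, chrom)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
        keep = G.std(axis=0) > 1e-9
        G = G[:, keep]
        if G.shape[1] == 0:
            continue
        if G.shape[1] == 1:
            total += 1.0
            continue
        corr = np.corrcoef(G, rowvar=False)
        lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
        lam = np.round(lam, 8)  # floor() must not see 2 - 1e-15 for duplicates
        total += float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return total


def genomewide_threshold(geno: GenotypeMatrix, gmap: GeneticMap,
                         alpha: float = 0.05) -> float:
    """Comparisonwise p cutoff giving genome-wide level ``alpha`` (Sidak/M_eff)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m_eff = effective_number_of_tests(geno, gmap)
    return 1.0 - (1.0 - alpha) ** (1.0 / m_eff)


def select_candidates(scan: ScanResult, min_separation: float = 30.0,
                      threshold: float | None = None) -> tuple[int, ...]:
    """Supra-threshold local maxima of the profile, greedily separated.

    Per chromosome, local maxima of -log10(p) above the threshold are
    accepted in decreasing significance subject to a pairwise separation of
    at least ``min_separation`` cM; ties break toward the lower cM position.
    Returns grid indices.
    """
    thr = scan.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no threshold set on the scan")
    t = scan.table
    picked: list[int] = []
    for chrom in t["chromosome"].unique():
        sub = t[t["chromosome"] == chrom]
        idx = sub.index.to_numpy()
        v = np.nan_to_num(sub["neglog10p"].to_numpy(), nan=-np.inf)
        pos = sub["position_cM"].to_numpy()
        n = len(v)
        is_max = np.ones(n, dtype=bool)
        if n > 1:
            is_max[1:] &= v[1:] >= v[:-1]
            is_max[:-1] &= v[:-1] >= v[1:]
        cand = [(float(-v[i]), float(pos[i]), int(idx[i])) for i in range(n)
                if is_max[i] and v[i] > thr]
        cand.sort()
        accepted: list[float] = []
        for _, p, gi in cand:
            if all(abs(p - a) >= min_separation for a in accepted):
                accepted.append(p)
                picked.append(gi)
    return tuple(sorted(picked))


def backward_eliminate(traits: pd.DataFrame, scores: QTLGenotypeScores,
                       candidates: tuple[int, ...], p_cutoff: float,
                       pvalue_method: str = "f") -> tuple[int, ...]:
    """Drop the least significant candidate until all pass the cutoff.

    Fits all candidates jointly; repeatedly removes the candidate with the
    largest multi-trait Wald p above the comparisonwise ``p_cutoff`` and
    refits.  May return an empty set.
    """
    Y = traits.to_numpy(dtype=float)
    n = len(Y)
    current = list(candidates)
    while current:
        X = np.column_stack([np.ones(n)] + [scores.values[:, c] for c in current])
        tests, _, _ = _joint_wald(Y, X, range(1, X.shape[1]), pvalue_method)
        pvals = np.array([t.p for t in tests])
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_cutoff:
            break
        dropped = current.pop(worst)
        logger.info("backward elimination dropped grid index %d (p=%.3g)",
                    dropped, pvals[worst])
    return tuple(current)


def estimate_qtl_effects(traits: pd.DataFrame, scores: QTLGenotypeScores,
                         final_set: tuple[int, ...], gmap: GeneticMap | None = None,
                         parent_a: str = "A", parent_b: str = "B",
                         pvalue_method: str = "f") -> pd.DataFrame:
    """Joint-model effects, SEs and high-value parent for the final QTL set.

    Effects are the B-parent-class minus A-parent-class difference per
    trait; the high-value parent is the B parent iff the effect is positive.
    Returns a tidy table with one row per (QTL, trait).
    """
    Y = traits.to_numpy(dtype=float)
    n = len(Y)
    grid = scores.grid.table
    X = np.column_stack([np.ones(n)] + [scores.values[:, c] for c in final_set])
    tests, _, _ = _joint_wald(Y, X, range(1, X.shape[1]), pvalue_method)
    rows = []
    for c, t in zip(final_set, tests):
        chrom = grid["chromosome"].iloc[c]
        pos = float(grid["position_cM"].iloc[c])
        if gmap is not None:
            fl, fr = gmap.flanking_markers(chrom, pos)
            closest = f"{fl} - {fr}"
        else:
            closest = ""
        for ti, trait in enumerate(traits.columns):
            eff = float(t.effects[ti])
            rows.append(
                {
                    "qtl": f"q{chrom}@{pos:g}",
                    "chromosome": chrom,
                    "position_cM": pos,
                    "closest_markers": closest,
                    "trait": trait,
                    "effect": eff,
                    "se": float(t.ses[ti]),
                    "high_value_allele": parent_b if eff > 0 else parent_a,
                    "wald": t.statistic,
                    "p": t.p,
                }
            )
    return pd.DataFrame(rows)


def percent_genetic_variance(traits: pd.DataFrame, scores: QTLGenotypeScores,
                             final_set: tuple[int, ...],
                             base: BaseModelFit) -> pd.DataFrame:
    """%GV per QTL per trait from the drop in polygenic variance.

    For QTL q and trait t, %GV = 100 (V_base - V_+q) / G_base where V is the
    residual (polygenic + error) variance of trait t, and G_base the base
    polygenic variance (residual minus the stage-1 error floor).  The
    ``Total`` row adds all QTL jointly.  Negative drops are floored at 0.
    """
    Y = traits.to_numpy(dtype=float)
    n, k = Y.shape
    grid = scores.grid.table
    v_base = Y.var(axis=0, ddof=1)
    g_base = np.maximum(base.polygenic_var.to_numpy(), 1e-12)

    def resid_var(subset):
        X = np.column_stack([np.ones(n)] + [scores.values[:, c] for c in subset])
        _, Sigma, _, _ = _joint_fit(Y, X)
        return np.diag(Sigma)

    rows = {}
    for c in final_set:
        label = (f"q{grid['chromosome'].iloc[c]}@"
                 f"{float(grid['position_cM'].iloc[c]):g}")
        drop = v_base - resid_var([c])
        if (drop < 0).any():
            logger.info("negative variance drop floored at 0 for %s", label)
        rows[label] = np.clip(100.0 * drop / g_base, 0.0, 100.0)
    if final_set:
        drop = v_base - resid_var(list(final_set))
        rows["Total"] = np.clip(100.0 * drop / g_base, 0.0, 100.0)
    out = pd.DataFrame(rows, index=traits.columns).T
    out.index.name = "qtl"
    return out


# ---------------------------------------------------------------------------
# the full protocol as an estimator


class MultiTraitQTLScan(BaseEstimator):
    """Complete multi-trait QTL mapping protocol as a fit-shaped estimator.

    Parameters
    ----------
    step : grid step in cM (grid always includes every marker position).
    alpha : genome-wide significance level for the Li-Ji-corrected threshold.
    min_separation : minimal cM distance between candidate peaks.
    window : cofactor exclusion window (cM) around the tested position.
    max_rounds : maximal number of CIM rounds before stopping with a warning.
    error_floors : optional per-trait stage-1 error variances (sigma_e^2 / r),
        dict keyed by trait name or sequence in trait order; used to separate
        genetic variance when computing %GV.
    pvalue_method : 'f' (exact Hotelling reference, default) or 'chi2'.
    parent_a, parent_b : labels reported as the high-value parent.

    Attributes (after ``fit``)
    --------------------------
    grid_, scores_, m_eff_, p_cutoff_, threshold_ (the -log10(p) cutoff),
    sim_scan_, scan_ (final CIM profile), candidates_, n_cim_rounds_,
    final_set_, qtl_ (tidy effect table), percent_gv_, base_model_.
    """

    def __init__(self, step: float = 2.0, alpha: float = 0.05,
                 min_separation: float = 30.0, window: float = 30.0,
                 max_rounds: int = 5, error_floors=None,
                 pvalue_method: str = "f", parent_a: str = "A",
                 parent_b: str = "B"):
        self.step = step
        self.alpha = alpha
        self.min_separation = min_separation
        self.window = window
        self.max_rounds = max_rounds
        self.error_floors = error_floors
        self.pvalue_method = pvalue_method
        self.parent_a = parent_a
        self.parent_b = parent_b

    def fit(self, X, y: pd.DataFrame, genetic_map: GeneticMap = None):
        """Run SIM -> CIM -> backward elimination -> final model.

        ``X`` is a :class:`GenotypeMatrix` (or 0/1/NaN line x marker
        DataFrame), ``y`` the complete line x trait BLUE table; line ids are
        aligned by intersection.
        """
        if genetic_map is None:
            raise ValueError("genetic_map is required")
        geno = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(
            pd.DataFrame(X).astype(float))
        common = [l for l in y.index.astype(str) if l in set(geno.data.index)]
        if len(common) < len(y):
            logger.info("dropped %d trait lines without genotypes",
                        len(y) - len(common))
        if len(common) < y.shape[1] + 3:
            raise ValueError("too few lines shared between traits and genotypes")
        traits = y.loc[common].astype(float)
        geno = GenotypeMatrix(geno.data.loc[common])

        self.grid_ = build_scan_grid(genetic_map, self.step)
        self.scores_ = genotype_probabilities(geno, genetic_map, self.grid_)
        self.m_eff_ = effective_number_of_tests(geno, genetic_map)
        self.p_cutoff_ = 1.0 - (1.0 - self.alpha) ** (1.0 / self.m_eff_)
        self.threshold_ = float(-np.log10(self.p_cutoff_))

        sim = sim_scan(traits, self.scores_, self.pvalue_method)
        self.sim_scan_ = ScanResult(table=sim.table, threshold=self.threshold_)
        candidates = select_candidates(self.sim_scan_, self.min_separation)
        scan = self.sim_scan_
        rounds = 0
        while candidates and rounds < self.max_rounds:
            rounds += 1
            scan = cim_scan(traits, self.scores_, candidates, self.window,
                            self.pvalue_method)
            scan = ScanResult(table=scan.table, threshold=self.threshold_,
                              cofactors=scan.cofactors)
            new = select_candidates(scan, self.min_separation)
            if new == candidates:
                break
            candidates = new
        else:
            if candidates:
                logger.warning("candidate set did not stabilise in %d CIM rounds",
                               self.max_rounds)
        self.n_cim_rounds_ = rounds
        self.scan_ = scan
        self.candidates_ = candidates

        self.final_set_ = backward_eliminate(
            traits, self.scores_, candidates, self.p_cutoff_, self.pvalue_method
        )
        self.base_model_ = fit_base_model(traits, self.error_floors)
        self.qtl_ = estimate_qtl_effects(
            traits, self.scores_, self.final_set_, genetic_map,
            self.parent_a, self.parent_b, self.pvalue_method,
        )
        self.percent_gv_ = percent_genetic_variance(
            traits, self.scores_, self.final_set_, self.base_model_
        )
        return self
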