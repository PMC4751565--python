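"""Stage-1 phenotypic analysis: RNRG, design mixed models, BLUEs, heritability.

The two-stage strategy fits each experiment's design model first and carries
only genotype means (BLUEs) into the genome scan:

* Hydroponics: relative net root growth per plant,
  RNRG = 100 * (fl_Al - il_Al) / (fl_c - il_c), averaged over the seven
  plants of each (line, block) cell, log10-transformed, then analysed under
  the randomised-complete-block model ``response = block + genotype + error``.
* Field yield: per environment, the incomplete-block model
  ``response = replicate + incomplete block(replicate) + genotype + error``
  with replicate fixed and incomplete block random; the two environments are
  fitted separately because their variances differ under Al stress.

With genotype random, REML variance components give the line-mean
heritability h2 = sigma2_g / (sigma2_g + sigma2_e / r); with genotype fixed
the same model yields the BLUEs used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger("altqtl")


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components and line-mean heritability for one response."""

    sigma2_g: float
    sigma2_e: float
    r: int
    sigma2_b: float | None = None

    @property
    def h2(self) -> float:
        denom = self.sigma2_g + self.sigma2_e / self.r
        return 0.0 if denom <= 0 else self.sigma2_g / denom


# ---------------------------------------------------------------------------
# RNRG


def compute_rnrg(records: pd.DataFrame, floor_pct: float = 1.0) -> pd.DataFrame:
    """Per-(line, block) RNRG from plant-level root lengths.

    Plants whose control root did not grow (fl_c - il_c <= 0) are excluded
    with a logged count; plant RNRG values are averaged within each
    (line, block) cell, clamped at ``floor_pct`` percent, and log10
    transformed.  Returns columns line, block, rnrg_pct, rnrg_log10.
    """
    rec = records.copy()
    crgr = rec["fl_c"] - rec["il_c"]
    alrgr = rec["fl_Al"] - rec["il_Al"]
    bad = crgr <= 0
    if bad.any():
        logger.info("excluded %d plants with non-growing control roots", int(bad.sum()))
    rec = rec.loc[~bad]
    rec = rec.assign(rnrg=100.0 * alrgr[~bad] / crgr[~bad])
    cell = rec.groupby(["line", "block"], sort=True)["rnrg"].mean().reset_index()
    n_clamped = int((cell["rnrg"] <= floor_pct).sum())
    if n_clamped:
        logger.info("clamped %d non-positive RNRG cell means at %.3g%%", n_clamped,
                    floor_pct)
    cell["rnrg_pct"] = cell["rnrg"]
    cell["rnrg_log10"] = np.log10(cell["rnrg"].clip(lower=floor_pct))
    return cell[["line", "block", "rnrg_pct", "rnrg_log10"]]


# ---------------------------------------------------------------------------
# design models


def _blues_from_fixed_fit(params: pd.Series, factor: str) -> pd.Series:
    prefix = f"C({factor})["
    out = {}
    for name, val in params.items():
        if name.startswith(prefix):
            out[name[len(prefix):-1]] = float(val)
    return pd.Series(out).sort_index()


def _fit_mixedlm(model) -> "statsmodels result":
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(reml=True, method="lbfgs")
        except Exception:
            return model.fit(reml=True, method="powell")


class RCBDModel(BaseEstimator):
    """Randomised-complete-block model ``response = block + genotype + error``.

    With ``genotype_random=True`` the fit yields REML variance components and
    line-mean heritability (r = number of blocks); with ``genotype_random=False``
    it yields genotype BLUEs adjusted for block.

    Attributes (after ``fit``): ``varcomp_``, ``h2_`` (random) or ``blues_``
    (fixed).
    """

    def __init__(self, genotype_random: bool = True, response: str = "rnrg_log10"):
        self.genotype_random = genotype_random
        self.response = response

    def fit(self, X: pd.DataFrame, y=None):
        df = X.rename(columns={self.response: "_y"})[["line", "block", "_y"]].dropna()
        n_blocks = df["block"].nunique()
        if n_blocks < 2:
            raise ValueError("heritability undefined with fewer than 2 blocks")
        if self.genotype_random:
            if np.var(df["_y"].to_numpy()) < 1e-14:
                self.varcomp_ = VarianceComponents(0.0, 0.0, n_blocks)
            else:
                md = MixedLM.from_formula("_y ~ C(block)", groups="line", data=df)
                res = _fit_mixedlm(md)
                self.varcomp_ = VarianceComponents(
                    sigma2_g=max(float(res.cov_re.iloc[0, 0]), 0.0),
                    sigma2_e=max(float(res.scale), 0.0),
                    r=n_blocks,
                )
            self.h2_ = self.varcomp_.h2
        else:
            import statsmodels.formula.api as smf

            res = smf.ols("_y ~ 0 + C(line) + C(block, Sum)", data=df).fit()
            self.blues_ = _blues_from_fixed_fit(res.params, "line")
        return self


class IncompleteBlockModel(BaseEstimator):
    """Per-environment incomplete-block mixed model for field yield.

    ``response = replicate (fixed) + incomplete block within replicate
    (random) + genotype + error``; genotype random gives variance components
    and h2 with r = number of replicates, genotype fixed gives BLUEs.
    Boundary variance estimates (0) are accepted and logged.

    Attributes: ``varcomp_``, ``h2_`` or ``blues_``.
    """

    def __init__(self, genotype_random: bool = True, response: str = "yield_t_ha"):
        self.genotype_random = genotype_random
        self.response = response

    def fit(self, X: pd.DataFrame, y=None):
        df = X.rename(columns={self.response: "_y"}).dropna(subset=["_y"]).copy()
        df["line"] = df["line"].astype(str)
        df["_rb"] = df["replicate"].astype(str) + ":" + df["block"].astype(str)
        n_rep = df["replicate"].nunique()
        ones = np.ones(len(df))
        if self.genotype_random:
            md = MixedLM.from_formula(
                "_y ~ C(replicate)",
                groups=ones,
                vc_formula={"genotype": "0 + C(line)", "iblock": "0 + C(_rb)"},
                data=df,
            )
            res = _fit_mixedlm(md)
            names = list(md.exog_vc.names)
            vc = {nm: max(float(v), 0.0) for nm, v in zip(names, res.vcomp)}
            if min(vc.values()) == 0.0:
                logger.info("variance component at boundary (0): %s", vc)
            self.varcomp_ = VarianceComponents(
                sigma2_g=vc["genotype"],
                sigma2_e=max(float(res.scale), 0.0),
                r=n_rep,
                sigma2_b=vc["iblock"],
            )
            self.h2_ = self.varcomp_.h2
        else:
            md = MixedLM.from_formula(
                "_y ~ 0 + C(line) + C(replicate, Sum)",
                groups=ones,
                vc_formula={"iblock": "0 + C(_rb)"},
                data=df,
            )
            res = _fit_mixedlm(md)
            self.blues_ = _blues_from_fixed_fit(res.fe_params, "line")
        return self


def fit_rcbd(values: pd.DataFrame, genotype_random: bool = True,
             response: str = "rnrg_log10"):
    """Thin wrapper over :class:`RCBDModel`; returns components or BLUEs."""
    m = RCBDModel(genotype_random=genotype_random, response=response).fit(values)
    return m.varcomp_ if genotype_random else m.blues_


def fit_incomplete_block(plots: pd.DataFrame, environment: str,
                         genotype_random: bool = True):
    """Thin wrapper over :class:`IncompleteBlockModel` for one environment."""
    sub = plots[plots["environment"] == environment]
    m = IncompleteBlockModel(genotype_random=genotype_random).fit(sub)
    return m.varcomp_ if genotype_random else m.blues_


# ---------------------------------------------------------------------------
# cross-environment summaries


def genetic_correlation_between_environments(
    blues_control: pd.Series, blues_al: pd.Series
) -> float:
    """Product-moment correlation of the two environments' line BLUEs.

    This is the attenuated proxy for the genotypic correlation: stage-1 error
    in either BLUE vector biases it toward zero by roughly sqrt(h2_1 * h2_2).
    """
    a, b = blues_control.align(blues_al, join="inner")
    if len(a) < 3:
        raise ValueError("need at least 3 shared lines")
    if np.std(a.to_numpy()) < 1e-14 or np.std(b.to_numpy()) < 1e-14:
        raise ValueError("zero variance in one environment's BLUEs")
    logger.info("between-environment correlation is attenuated by stage-1 error")
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])


def assemble_trait_table(
    rnrg_blues: pd.Series,
    gy_control_blues: pd.Series,
    gy_al_blues: pd.Series,
    exclude: tuple[str, ...] = ("BR007", "SC283", "ATF10B", "ATF8B"),
) -> pd.DataFrame:
    """Inner-join the three BLUE vectors into the line x trait table.

    Parental and check entries are dropped by default so the mapping
    population stays clean; lines missing any trait are dropped with their
    ids logged.
    """
    df = pd.concat(
        {"RNRG_log10": rnrg_blues, "Gy_control": gy_control_blues,
         "Gy_Al": gy_al_blues},
        axis=1, join="outer",
    )
    df = df.drop(index=[e for e in exclude if e in df.index])
    dropped = df.index[df.isna().any(axis=1)].tolist()
    if dropped:
        logger.info("dropped %d lines missing a trait: %s", len(dropped), dropped)
    df = df.dropna()
    if df.empty:
        raise ValueError("no line is present in all three trait BLUE vectors")
    df.index.name = "line"
    return df
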