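"""Split-plot analysis of the isogenic-hybrid trial and the allele-dosage test.

Eight hybrids (2 female x 4 male factorial around the chromosome-3 Al
tolerance locus) are grown as subplots within whole plots that carry the Al
vs. control treatment; the whole plots follow a completely randomised
design with four replicates per treatment.  The ANOVA therefore has two
error strata: the treatment effect is tested against the whole-plot error
(variation among whole plots within treatment), every other effect against
the subplot error.  Least significant differences use the error stratum
appropriate to the factor.

The dosage covariate model replaces the female and male factors by the
number of tolerance (T) alleles each hybrid carries (0, 1 or 2).  Under
additive gene action its coefficient equals the average allele-substitution
effect from the factor model; divergence between the two indicates
dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


def _cell_means(df, by):
    return df.groupby(by, sort=True)["_y"].mean()


def _ss(means: pd.Series, grand: float, n_per: int) -> float:
    return float(n_per * ((means - grand) ** 2).sum())


class SplitPlotAnova(BaseEstimator):
    """Two-stratum ANOVA of the balanced hybrid split-plot trial.

    Requires the full balanced layout (every hybrid once in every whole
    plot); unbalanced input raises rather than approximating.

    Attributes: ``anova_`` (source, df, ss, ms, F, p), ``means_`` (dict of
    marginal-mean Series for treatment, female, male, hybrid), ``lsd_``
    (LSD(alpha) per factor), ``ms_wholeplot_error_``, ``ms_subplot_error_``.
    """

    def __init__(self, alpha: float = 0.05, response: str = "yield_t_ha"):
        self.alpha = alpha
        self.response = response

    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df.rename(columns={self.response: "_y"}).copy()
        counts = df.groupby(["whole_plot", "hybrid"], sort=False).size()
        wp_per_treat = df.groupby("treatment")["whole_plot"].nunique()
        hybrids = df["hybrid"].nunique()
        if (counts != 1).any() or df["treatment"].nunique() != 2:
            bad = counts[counts != 1]
            raise ValueError(
                f"unbalanced split-plot design; cell counts != 1: {bad.to_dict()}"
            )
        if wp_per_treat.nunique() != 1:
            raise ValueError("unequal whole-plot replication across treatments")
        n_expected = wp_per_treat.sum() * hybrids
        if len(df) != n_expected:
            raise ValueError("plot count does not match the factorial layout")
        return df

    def fit(self, X: pd.DataFrame, y=None):
        df = self._validate(X)
        yv = df["_y"].to_numpy(dtype=float)
        grand = float(yv.mean())
        n = len(df)
        n_treat = 2
        n_wp = df["whole_plot"].nunique()
        n_hyb = df["hybrid"].nunique()
        n_fem = df["female"].nunique()
        n_male = df["male"].nunique()
        reps = n_wp // n_treat

        m_t = _cell_means(df, "treatment")
        m_wp = _cell_means(df, "whole_plot")
        m_h = _cell_means(df, "hybrid")
        m_f = _cell_means(df, "female")
        m_m = _cell_means(df, "male")
        m_th = _cell_means(df, ["treatment", "hybrid"])
        m_fm = _cell_means(df, ["female", "male"])

        ss_total = float(((yv - grand) ** 2).sum())
        ss_treat = _ss(m_t, grand, n_hyb * reps)
        # whole-plot error: among whole plots within treatment
        wp_treat = df.groupby("whole_plot")["treatment"].first()
        dev_wp = m_wp - wp_treat.map(m_t)
        ss_wp_err = float(n_hyb * (dev_wp**2).sum())
        ss_hyb = _ss(m_h, grand, n_wp)
        ss_fem = _ss(m_f, grand, n // n_fem)
        ss_male = _ss(m_m, grand, n // n_male)
        inter_fm = (
            m_fm.to_numpy()
            - m_fm.index.get_level_values(0).map(m_f).to_numpy()
            - m_fm.index.get_level_values(1).map(m_m).to_numpy()
            + grand
        )
        ss_fm = float((n // (n_fem * n_male)) * (inter_fm**2).sum())
        inter_th = (
            m_th.to_numpy()
            - m_th.index.get_level_values(0).map(m_t).to_numpy()
            - m_th.index.get_level_values(1).map(m_h).to_numpy()
            + grand
        )
        ss_th = float(reps * (inter_th**2).sum())
        ss_sub_err = max(ss_total - ss_treat - ss_wp_err - ss_hyb - ss_th, 0.0)

        df_treat = n_treat - 1
        df_wp_err = n_wp - n_treat
        df_hyb = n_hyb - 1
        df_fem = n_fem - 1
        df_male = n_male - 1
        df_fm = df_fem * df_male
        df_th = df_treat * df_hyb
        df_sub_err = n - 1 - df_treat - df_wp_err - df_hyb - df_th

        ms_wp = ss_wp_err / df_wp_err
        ms_sub = ss_sub_err / df_sub_err
        self.ms_wholeplot_error_ = ms_wp
        self.ms_subplot_error_ = ms_sub

        def row(source, ss_v, df_v, ms_err, df_err):
            ms_v = ss_v / df_v if df_v else np.nan
            if ms_err is None or ms_err <= 0:
                f_v = p_v = np.nan
            else:
                f_v = ms_v / ms_err
                p_v = float(stats.f.sf(f_v, df_v, df_err))
            return {"source": source, "df": df_v, "ss": ss_v, "ms": ms_v,
                    "F": f_v, "p": p_v}

        self.anova_ = pd.DataFrame(
            [
                row("treatment", ss_treat, df_treat, ms_wp, df_wp_err),
                row("whole_plot_error", ss_wp_err, df_wp_err, None, None),
                row("hybrid", ss_hyb, df_hyb, ms_sub, df_sub_err),
                row("female", ss_fem, df_fem, ms_sub, df_sub_err),
                row("male", ss_male, df_male, ms_sub, df_sub_err),
                row("female_x_male", ss_fm, df_fm, ms_sub, df_sub_err),
                row("treatment_x_hybrid", ss_th, df_th, ms_sub, df_sub_err),
                row("subplot_error", ss_sub_err, df_sub_err, None, None),
                row("total", ss_total, n - 1, None, None),
            ]
        )
        self.means_ = {"treatment": m_t, "female": m_f, "male": m_m, "hybrid": m_h}

        def lsd(ms_err, df_err, n_per_mean):
            if df_err <= 0 or ms_err < 0:
                return np.nan
            t = stats.t.ppf(1 - self.alpha / 2, df_err)
            return float(t * np.sqrt(2.0 * ms_err / n_per_mean))

        self.lsd_ = {
            "treatment": lsd(ms_wp, df_wp_err, n // n_treat),
            "female": lsd(ms_sub, df_sub_err, n // n_fem),
            "male": lsd(ms_sub, df_sub_err, n // n_male),
            "hybrid": lsd(ms_sub, df_sub_err, n // n_hyb),
        }
        return self


@dataclass(frozen=True)
class DosageTestResult:
    coefficient: float  # yield change per added tolerance allele
    se: float
    factor_substitution_effect: float  # average single-allele contrast, factor model
    contrasts: pd.Series  # the individual single-allele contrasts
    divergence: float  # covariate coefficient minus factor-model average


class DosageCovariateModel(BaseEstimator):
    """Additivity test: linear allele-dosage covariate within split-plot strata.

    Whole-plot dummies absorb the treatment and whole-plot error, so the
    dosage coefficient and its SE come from the subplot stratum.  For
    comparison the factor model (female + male in place of dosage) yields
    the average single-allele substitution effect; under additivity the two
    coincide.

    Attributes: ``result_`` (:class:`DosageTestResult`).
    """

    def __init__(self, response: str = "yield_t_ha"):
        self.response = response

    def fit(self, X: pd.DataFrame, y=None):
        df = X.rename(columns={self.response: "_y"}).copy()
        if df["dosage"].nunique() < 2:
            raise ValueError("allele dosage is constant; covariate test undefined")
        yv = df["_y"].to_numpy(dtype=float)
        wp = pd.get_dummies(df["whole_plot"], dtype=float).to_numpy()
        dosage = df["dosage"].to_numpy(dtype=float)

        Xc = np.column_stack([wp, dosage])
        beta, _, _, _ = np.linalg.lstsq(Xc, yv, rcond=None)
        resid = yv - Xc @ beta
        dof = len(yv) - np.linalg.matrix_rank(Xc)
        s2 = float(resid @ resid) / dof
        XtXi = np.linalg.pinv(Xc.T @ Xc)
        coef = float(beta[-1])
        se = float(np.sqrt(s2 * XtXi[-1, -1]))

        # factor model: per-parent allele contributions inferred from dosage
        fem = pd.get_dummies(df["female"], dtype=float)
        male = pd.get_dummies(df["male"], dtype=float)
        Xf = np.column_stack([wp, fem.to_numpy()[:, 1:], male.to_numpy()[:, 1:]])
        bf, _, _, _ = np.linalg.lstsq(Xf, yv, rcond=None)
        k_f, k_m = fem.shape[1] - 1, male.shape[1] - 1
        fem_eff = dict(zip(fem.columns, [0.0, *bf[wp.shape[1]: wp.shape[1] + k_f]]))
        male_eff = dict(zip(male.columns, [0.0, *bf[wp.shape[1] + k_f:]]))
        fem_dose = df.groupby("female")["dosage"].mean()
        male_dose = df.groupby("male")["dosage"].mean()
        contrasts = {}
        for eff, dose, ref in ((fem_eff, fem_dose, fem.columns[0]),
                               (male_eff, male_dose, male.columns[0])):
            for level in eff:
                ddiff = dose[level] - dose[ref]
                if level != ref and abs(ddiff) > 1e-12:
                    contrasts[f"{ref}->{level}"] = (eff[level] - eff[ref]) / ddiff
        contrasts = pd.Series(contrasts)
        avg = float(contrasts.mean())
        self.result_ = DosageTestResult(
            coefficient=coef, se=se, factor_substitution_effect=avg,
            contrasts=contrasts, divergence=coef - avg,
        )
        return self


def split_plot_anova(plots: pd.DataFrame, alpha: float = 0.05) -> SplitPlotAnova:
    """Thin wrapper returning a fitted :class:`SplitPlotAnova`."""
    return SplitPlotAnova(alpha=alpha).fit(plots)


def dosage_covariate_test(plots: pd.DataFrame) -> DosageTestResult:
    """Thin wrapper over :class:`DosageCovariateModel`."""
    return DosageCovariateModel().fit(plots).result_
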