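"""Loss-aversion estimation from choice data and group-level behavioral inference.

The central quantity is the loss-aversion parameter lambda: each
subject's accept/reject decisions over mixed gambles are fit with a
logistic value model

    P(accept) = logistic(b0 + beta_gain * G - beta_loss * L),

and lambda = beta_loss / beta_gain, the factor by which prospective
losses outweigh equal gains.  Both weights are kept positive; the loss
magnitude enters with a negative sign.  Perfectly separable or
degenerate choice sets fall back to a Jeffreys-prior (Firth) penalized
fit so lambda stays finite, and the subject is flagged rather than
dropped.

Group-level inference mirrors a standard behavioral battery: two-sample
t-test, ANCOVA with nuisance covariates, 2x2 group-by-sex ANOVA with
Type-III sums of squares, normality/correlation screening, and
Benjamini-Hochberg FDR applied within declared test families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LAEstimate",
    "estimate_lambda",
    "residualize_lambda",
    "two_sample_test",
    "ancova_group_effect",
    "factorial_anova_2x2",
    "screen_assumptions",
    "fdr_adjust",
    "behavioral_report",
]


# ---------------------------------------------------------------------------
# lambda estimation
# ---------------------------------------------------------------------------

@dataclass
class LAEstimate:
    """Fitted choice-model weights and the loss-aversion statistic.

    ``lambda_`` is ``beta_loss / beta_gain`` when the fit converged with
    a positive gain weight, else NaN (never silently zero);
    ``lambda_defined`` records which.
    """

    beta_gain: float
    beta_loss: float
    intercept: float
    se_beta_gain: float
    se_beta_loss: float
    se_intercept: float
    converged: bool
    separation_flag: bool
    n_trials: int
    acceptance_rate: float
    note: str = ""

    @property
    def lambda_defined(self) -> bool:
        return bool(self.converged and self.beta_gain > 0
                    and np.isfinite(self.beta_loss / self.beta_gain))

    @property
    def lambda_(self) -> float:
        if not self.lambda_defined:
            return float("nan")
        return self.beta_loss / self.beta_gain


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                    tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Jeffreys-prior penalized logistic regression (Firth).

    Newton scoring on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    h the hat values of the weighted design.  Estimates exist and are
    finite even under complete separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat values of sqrt(W) X (X'WX)^-1 X' sqrt(W)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        return beta, np.sqrt(np.diag(np.linalg.pinv(info))), False
    se = np.sqrt(np.diag(info_inv))
    return beta, se, True


def estimate_lambda(choices: pd.DataFrame, include_intercept: bool = True,
                    min_trials: int = 10) -> LAEstimate:
    """Fit the logistic value model to one subject's choices.

    Expects columns ``gain``, ``loss`` (positive magnitudes) and
    ``accept`` (0/1).  Maximum likelihood by default; complete/quasi
    separation or an all-accept / all-reject record triggers the Firth
    penalized fallback and sets ``separation_flag``.
    """
    for col in ("gain", "loss", "accept"):
        if col not in choices:
            raise ValueError(f"choice table lacks column '{col}'")
    y = choices["accept"].to_numpy(dtype=float)
    G = choices["gain"].to_numpy(dtype=float)
    L = choices["loss"].to_numpy(dtype=float)
    n = len(y)
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")
    cols = [G, -L]
    if include_intercept:
        X = np.column_stack([np.ones(n)] + cols)
    else:
        X = np.column_stack(cols)

    degenerate = len(np.unique(y)) < 2
    beta = se = None
    separation = False
    converged = False
    note = ""
    if not degenerate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                beta, se = res.params, res.bse
                converged = bool(res.mle_retvals.get("converged", False))
                p_hat = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -700, 700)))
                if np.max(np.abs(y - p_hat)) < 1e-4 or not np.all(np.isfinite(se)):
                    separation = True  # perfectly fitted responses
            except Exception:
                separation = True
    if degenerate or separation or not converged:
        separation = True
        note = ("all responses identical" if degenerate
                else "separation; Firth penalized fit used")
        beta, se, converged = _firth_logistic(X, y)

    if include_intercept:
        b0, bg, bl = beta
        s0, sg, sl = se
    else:
        b0, s0 = 0.0, float("nan")
        bg, bl = beta
        sg, sl = se
    est = LAEstimate(
        beta_gain=float(bg), beta_loss=float(bl), intercept=float(b0),
        se_beta_gain=float(sg), se_beta_loss=float(sl), se_intercept=float(s0),
        converged=bool(converged), separation_flag=bool(separation),
        n_trials=n, acceptance_rate=float(y.mean()), note=note,
    )
    if est.converged and est.beta_gain <= 0:
        est.note = (est.note + "; " if est.note else "") + \
            "beta_gain <= 0: lambda undefined"
    return est


def residualize_lambda(lambdas, risk_scores) -> np.ndarray:
    """Residualize loss aversion against the risk-attitude score.

    A single-predictor least-squares fit pooled over the whole sample;
    the residuals have zero mean and zero sample correlation with the
    risk score.  A constant risk score carries no information, so the
    mean-centered lambdas are returned with a warning.
    """
    lam = np.asarray(lambdas, dtype=float)
    risk = np.asarray(risk_scores, dtype=float)
    if lam.shape != risk.shape:
        raise ValueError("lambdas and risk_scores must have equal length")
    if lam.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(risk) == 0:
        warnings.warn("risk score is constant; returning mean-centered lambda")
        return lam - lam.mean()
    X = np.column_stack([np.ones_like(risk), risk])
    coef, *_ = np.linalg.lstsq(X, lam, rcond=None)
    return lam - X @ coef


# ---------------------------------------------------------------------------
# group-level tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple
    p: float
    effect_sizes: dict = field(default_factory=dict)
    family: str = ""
    extras: dict = field(default_factory=dict)


def two_sample_test(values, groups, welch: bool = False) -> TestResult:
    """Two-sample t-test on a per-subject quantity (Student or Welch)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = st.ttest_ind(a, b, equal_var=not welch)
    sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                 / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
    return TestResult(
        name="two_sample_t", statistic=float(res.statistic),
        df=(float(res.df),), p=float(res.pvalue),
        effect_sizes={"cohen_d": float(d)},
        extras={
            "groups": [str(levels[0]), str(levels[1])],
            "means": [float(a.mean()), float(b.mean())],
            "sds": [float(a.std(ddof=1)), float(b.std(ddof=1))],
            "ns": [int(len(a)), int(len(b))],
        },
    )


def _design_full_rank_or_raise(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the dependency via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ancova_group_effect(values, group, covariates: pd.DataFrame) -> TestResult:
    """ANCOVA: F-test of the group term controlling for covariates.

    Fits ``value ~ group + covariates`` by OLS and compares with the
    covariates-only model; partial eta^2 = SS_group / (SS_group +
    SS_resid) and Cohen's f = sqrt(eta^2 / (1 - eta^2)).
    """
    from .moderation import cohens_f_from_eta2

    y = np.asarray(values, dtype=float)
    g = pd.Categorical(np.asarray(group))
    if len(g.categories) != 2:
        raise ValueError("group must have exactly 2 levels")
    gi = (g.codes == 1).astype(float)
    C = covariates.to_numpy(dtype=float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), gi, C])
    names = ["intercept", "group"] + list(covariates.columns)
    _design_full_rank_or_raise(X_full, names)
    X_red = np.column_stack([np.ones(n), C])

    def ssr(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    ssr_f, ssr_r = ssr(X_full), ssr(X_red)
    df_num = 1
    df_den = n - X_full.shape[1]
    F = ((ssr_r - ssr_f) / df_num) / (ssr_f / df_den)
    p = float(st.f.sf(F, df_num, df_den))
    eta2 = (ssr_r - ssr_f) / ssr_r
    return TestResult(
        name="ancova_group", statistic=float(F), df=(df_num, df_den), p=p,
        effect_sizes={"partial_eta2": float(eta2),
                      "cohen_f": float(cohens_f_from_eta2(eta2))},
    )


def factorial_anova_2x2(values, factor_a, factor_b) -> dict[str, TestResult]:
    """2x2 factorial ANOVA, Type-III sums of squares, sum-to-zero coding.

    Suited to unbalanced cells (as in unequal group-by-sex counts);
    returns main effects and the interaction keyed by term name.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "A": np.asarray(factor_a), "B": np.asarray(factor_b)})
    counts = df.groupby(["A", "B"], observed=True).size()
    if len(counts) < 4 or (counts < 1).any():
        raise ValueError("all four cells of the 2x2 design must be nonempty")
    model = sm.formula.ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    out: dict[str, TestResult] = {}
    keymap = {"C(A, Sum)": "A", "C(B, Sum)": "B",
              "C(A, Sum):C(B, Sum)": "A:B"}
    df_res = float(tab.loc["Residual", "df"])
    for row, key in keymap.items():
        out[key] = TestResult(
            name=f"anova_{key}", statistic=float(tab.loc[row, "F"]),
            df=(float(tab.loc[row, "df"]), df_res),
            p=float(tab.loc[row, "PR(>F)"]),
        )
    return out


def screen_assumptions(table: pd.DataFrame, variables: list[str],
                       lilliefors_correction: bool = True) -> dict:
    """Normality and pairwise-correlation screening of a variable set.

    Normality uses the Kolmogorov-Smirnov statistic against a normal
    with the sample mean/SD — Lilliefors-corrected p by default (the
    parameters are estimated), plain K-S p as an option.  Constant
    variables have undefined normality and are reported as NaN.
    """
    norm = {}
    for v in variables:
        x = table[v].dropna().to_numpy(dtype=float)
        if len(x) < 5:
            raise ValueError(f"variable '{v}' has fewer than 5 observations")
        if np.ptp(x) == 0:
            norm[v] = {"statistic": float("nan"), "p": float("nan"),
                       "note": "constant variable; normality undefined"}
            continue
        if lilliefors_correction:
            stat, p = lilliefors(x, dist="norm")
        else:
            stat, p = st.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        norm[v] = {"statistic": float(stat), "p": float(p), "note": ""}

    k = len(variables)
    r = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], pmat[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = table[[variables[i], variables[j]]].dropna()
            if np.ptp(pair.iloc[:, 0]) == 0 or np.ptp(pair.iloc[:, 1]) == 0:
                continue
            rr = st.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rr.statistic
            pmat[i, j] = pmat[j, i] = rr.pvalue
    return {
        "normality": norm,
        "pearson_r": pd.DataFrame(r, index=variables, columns=variables),
        "pearson_p": pd.DataFrame(pmat, index=variables, columns=variables),
    }


def fdr_adjust(pvalues, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up, applied independently within families."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_labels is None:
        family_labels = np.zeros(len(p))
    fam = np.asarray(family_labels)
    if fam.shape != p.shape:
        raise ValueError("family_labels must match pvalues in length")
    adj = np.empty_like(p)
    for f in pd.unique(fam):
        idx = fam == f
        adj[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return adj


def behavioral_report(tests: list[TestResult]) -> pd.DataFrame:
    """Assemble a tidy report with within-family FDR-adjusted p-values."""
    rows = []
    for t in tests:
        rows.append({
            "test": t.name, "family": t.family, "statistic": t.statistic,
            "df": "x".join(f"{d:g}" for d in t.df), "p": t.p,
            **{k: v for k, v in t.effect_sizes.items()},
        })
    rep = pd.DataFrame(rows)
    rep["p_fdr"] = fdr_adjust(rep["p"].to_numpy(), rep["family"].to_numpy())
    return rep
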