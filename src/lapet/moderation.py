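"""Conditional-process moderation analysis (simple-slopes "model 1").

Regresses an outcome on a focal predictor, a moderator, their product
and covariates by OLS, with heteroscedasticity-consistent (HC0-HC4)
inference, case-resampling bootstrap percentile CIs, conditional
effects of the focal predictor at chosen moderator values, a
Johnson-Neyman region of significance, and the effect-size /
post-hoc-power arithmetic that goes with it.

Conventions follow the common SPSS-macro style output: the focal
predictor is mean-centered before the product is formed; a binary
male/female moderator is coded male=1, female=2 and left uncentered
(this is the coding under which conditional effects equal
``b1 + b3 * w`` at w = 1 and 2); continuous moderators are centered.
The highest-order interaction test and the model F are robust Wald
tests by default, with the classical R-squared-based versions reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "ModerationResult",
    "fit_moderation",
    "johnson_neyman",
    "effect_sizes",
    "posthoc_power",
    "cohens_f_from_eta2",
    "cohens_f2_from_delta_r2",
]

DEFAULT_SEX_CODING = {"male": 1.0, "female": 2.0}


def cohens_f_from_eta2(eta2: float) -> float:
    """f = sqrt(eta^2 / (1 - eta^2))."""
    if not 0 <= eta2 < 1:
        raise ValueError("partial eta^2 must lie in [0, 1)")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def cohens_f2_from_delta_r2(delta_r2: float, r2_full: float) -> float:
    """f^2 = delta R^2 / (1 - R^2_full)."""
    if not 0 <= r2_full < 1:
        raise ValueError("R^2_full must lie in [0, 1)")
    if delta_r2 < 0 or delta_r2 > r2_full:
        raise ValueError("delta R^2 must lie in [0, R^2_full]")
    return float(delta_r2 / (1.0 - r2_full))


def _hc_covariance(X: np.ndarray, resid: np.ndarray, hc_type: str) -> np.ndarray:
    """Heteroscedasticity-consistent coefficient covariance, HC0-HC4."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    e2 = resid ** 2
    t = hc_type.upper()
    if t == "HC0":
        omega = e2
    elif t == "HC1":
        omega = e2 * n / (n - k)
    elif t == "HC2":
        omega = e2 / (1.0 - h)
    elif t == "HC3":
        omega = e2 / (1.0 - h) ** 2
    elif t == "HC4":
        delta = np.minimum(4.0, n * h / k)
        omega = e2 / (1.0 - h) ** delta
    else:
        raise ValueError(f"unknown hc_type {hc_type!r}")
    return xtx_inv @ (X.T * omega) @ X @ xtx_inv


@dataclass
class ModerationResult:
    """Full output of :func:`fit_moderation`.

    ``coefficients`` rows are ordered (intercept, focal, moderator,
    interaction, covariates...).  ``cov`` is the robust coefficient
    covariance used for all analytic CIs and conditional effects.
    """

    coefficients: pd.DataFrame       # coeff, se, t, p, llci, ulci
    cov: np.ndarray
    classical_cov: np.ndarray
    hc_type: str
    r2: float
    mse: float
    f_robust: float
    f_classical: float
    df1: int
    df2: int
    p_model: float
    delta_r2: float
    f_interaction_robust: float
    p_interaction_robust: float
    f_interaction_classical: float
    p_interaction_classical: float
    conditional_effects: pd.DataFrame
    bootstrap: pd.DataFrame | None
    moderator_is_binary: bool
    moderator_values: np.ndarray
    moderator_label: dict
    focal_mean: float
    alpha: float
    n: int
    bootstrap_B: int = 0
    bootstrap_seed: int | None = None
    design: np.ndarray | None = field(default=None, repr=False)
    outcome: np.ndarray | None = field(default=None, repr=False)

    def coefficient(self, name: str) -> float:
        return float(self.coefficients.loc[name, "coeff"])

    def conditional_effect(self, w: float) -> float:
        """Simple slope of the focal predictor at moderator value w."""
        return self.coefficient("focal") + self.coefficient("interaction") * w


def fit_moderation(
    outcome,
    focal,
    moderator,
    covariates: pd.DataFrame | None = None,
    center_focal: bool = True,
    moderator_coding: dict | None = None,
    hc_type: str = "HC3",
    alpha: float = 0.05,
    B: int = 50_000,
    seed: int | None = 0,
    max_redraw_rounds: int = 50,
) -> ModerationResult:
    """OLS moderation fit with robust inference and bootstrap CIs.

    Parameters of note: ``B`` case-resampling bootstrap draws (percentile
    intervals; 0 disables the bootstrap), ``hc_type`` the HC covariance
    flavor, ``moderator_coding`` a mapping for categorical moderators
    (default male=1, female=2).  Point estimates never depend on B or
    the seed.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(focal, dtype=float)
    n = len(y)

    w_raw = np.asarray(moderator)
    if w_raw.dtype.kind in "OUS" or len(np.unique(w_raw)) == 2:
        if w_raw.dtype.kind in "OUS":
            coding = dict(DEFAULT_SEX_CODING if moderator_coding is None
                          else moderator_coding)
            try:
                w = np.array([float(coding[v]) for v in w_raw])
            except KeyError as e:
                raise ValueError(f"moderator level {e} missing from coding map")
        else:
            w = w_raw.astype(float)
            coding = {float(v): float(v) for v in np.unique(w)}
        binary = True
        w_eval = np.unique(w)
    else:
        w = w_raw.astype(float)
        w = w - w.mean()
        coding = {}
        binary = False
        w_eval = np.array([-w.std(ddof=1), w.std(ddof=1)])  # mean -/+ 1 SD

    focal_mean = float(x.mean()) if center_focal else 0.0
    xc = x - focal_mean

    names = ["intercept", "focal", "moderator", "interaction"]
    blocks = [np.ones(n), xc, w, xc * w]
    if covariates is not None and len(covariates.columns):
        for c in covariates.columns:
            names.append(str(c))
            blocks.append(covariates[c].to_numpy(dtype=float))
    X = np.column_stack(blocks)
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k - 1} predictors")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("collinear design: moderation model is not identified")

    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df2 = n - k
    df1 = k - 1
    r2 = 1.0 - ssr / sst
    mse = ssr / df2

    V = _hc_covariance(X, resid, hc_type)
    V_classical = mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(V))
    tval = beta / se
    pval = 2 * st.t.sf(np.abs(tval), df2)
    tcrit = st.t.ppf(1 - alpha / 2, df2)
    coef_tab = pd.DataFrame(
        {"coeff": beta, "se": se, "t": tval, "p": pval,
         "llci": beta - tcrit * se, "ulci": beta + tcrit * se},
        index=names,
    )

    # robust Wald F on all slopes, plus classical R^2-based F
    R = np.eye(k)[1:]
    rb = R @ beta
    f_rob = float(rb @ np.linalg.solve(R @ V @ R.T, rb) / df1)
    f_cls = (r2 / df1) / ((1 - r2) / df2)
    p_model = float(st.f.sf(f_rob, df1, df2))

    # highest-order interaction: robust Wald t^2, and classical dR^2 F
    i_int = names.index("interaction")
    f_int_rob = float(tval[i_int] ** 2)
    p_int_rob = float(st.f.sf(f_int_rob, 1, df2))
    X_red = np.delete(X, i_int, axis=1)
    beta_r = np.linalg.solve(X_red.T @ X_red, X_red.T @ y)
    ssr_r = float(((y - X_red @ beta_r) ** 2).sum())
    r2_red = 1.0 - ssr_r / sst
    delta_r2 = r2 - r2_red
    f_int_cls = float(((ssr_r - ssr) / 1) / (ssr / df2))
    p_int_cls = float(st.f.sf(f_int_cls, 1, df2))

    # conditional effects of the focal predictor at moderator values
    b1, b3 = beta[1], beta[i_int]
    rows = []
    label_of = {v: k_ for k_, v in coding.items()} if binary else {}
    for wv in w_eval:
        eff = b1 + b3 * wv
        var = V[1, 1] + wv ** 2 * V[i_int, i_int] + 2 * wv * V[1, i_int]
        se_eff = float(np.sqrt(var))
        t_eff = eff / se_eff
        rows.append({
            "moderator_value": float(wv),
            "moderator_label": str(label_of.get(float(wv), f"{wv:g}")),
            "effect": float(eff), "se": se_eff, "t": float(t_eff),
            "p": float(2 * st.t.sf(abs(t_eff), df2)),
            "llci": float(eff - tcrit * se_eff),
            "ulci": float(eff + tcrit * se_eff),
        })
    cond = pd.DataFrame(rows)

    boot_tab = None
    if B > 0:
        boot_tab = _bootstrap_coefficients(
            X, y, names, B=B, seed=seed, alpha=alpha,
            max_redraw_rounds=max_redraw_rounds)

    return ModerationResult(
        coefficients=coef_tab, cov=V, classical_cov=V_classical,
        hc_type=hc_type.upper(), r2=r2, mse=mse, f_robust=f_rob,
        f_classical=float(f_cls), df1=df1, df2=df2, p_model=p_model,
        delta_r2=float(delta_r2),
        f_interaction_robust=f_int_rob, p_interaction_robust=p_int_rob,
        f_interaction_classical=f_int_cls, p_interaction_classical=p_int_cls,
        conditional_effects=cond, bootstrap=boot_tab,
        moderator_is_binary=binary, moderator_values=w_eval,
        moderator_label=coding, focal_mean=focal_mean, alpha=alpha, n=n,
        bootstrap_B=B, bootstrap_seed=seed, design=X, outcome=y,
    )


def _bootstrap_coefficients(X, y, names, B, seed, alpha,
                            max_redraw_rounds) -> pd.DataFrame:
    """Case-resampling bootstrap, percentile intervals, batched solves."""
    rng = np.random.default_rng(seed)
    n, k = X.shape
    idx = rng.integers(0, n, size=(B, n))
    betas = np.empty((B, k))
    pending = np.arange(B)
    for _ in range(max_redraw_rounds):
        Xb = X[idx[pending]]                      # (b, n, k)
        yb = y[idx[pending]]
        XtX = np.einsum("bni,bnj->bij", Xb, Xb)
        Xty = np.einsum("bni,bn->bi", Xb, yb)
        ok = np.abs(np.linalg.det(XtX)) > 1e-10
        if ok.any():
            betas[pending[ok]] = np.linalg.solve(
                XtX[ok], Xty[ok][..., None])[..., 0]
        pending = pending[~ok]
        if len(pending) == 0:
            break
        idx[pending] = rng.integers(0, n, size=(len(pending), n))
    n_failed = len(pending)
    if n_failed:
        betas = np.delete(betas, pending, axis=0)
    lo, hi = np.percentile(betas, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                           axis=0)
    tab = pd.DataFrame(
        {"boot_mean": betas.mean(axis=0), "boot_se": betas.std(ddof=1, axis=0),
         "boot_llci": lo, "boot_ulci": hi},
        index=names,
    )
    tab.attrs["n_failed_resamples"] = int(n_failed)
    return tab


@dataclass
class JNResult:
    boundaries: list
    region: str        # "entire range" | "nowhere" | interval description
    significant_between: bool | None
    code: str


def johnson_neyman(result: ModerationResult,
                   w_range: tuple[float, float] | None = None) -> JNResult:
    """Johnson-Neyman region of significance for the conditional effect.

    Solves (b1 + b3 w)^2 = t_crit^2 Var(b1 + b3 w) for the moderator
    value(s) w at which the focal effect's t crosses the critical value,
    using the robust covariance.  For a binary moderator the per-level
    conditional-effect tests already answer the question, so the levels'
    significance is reported instead of boundaries.
    """
    i1 = list(result.coefficients.index).index("focal")
    i3 = list(result.coefficients.index).index("interaction")
    b1 = result.coefficients.iloc[i1]["coeff"]
    b3 = result.coefficients.iloc[i3]["coeff"]
    V = result.cov
    tc2 = st.t.ppf(1 - result.alpha / 2, result.df2) ** 2

    if result.moderator_is_binary:
        sig = result.conditional_effects["p"] < result.alpha
        desc = ", ".join(
            f"{r.moderator_label}: {'significant' if s else 'n.s.'}"
            for r, s in zip(result.conditional_effects.itertuples(), sig))
        return JNResult([], desc, None, "binary_moderator")

    a = b3 ** 2 - tc2 * V[i3, i3]
    b = 2 * (b1 * b3 - tc2 * V[i1, i3])
    c = b1 ** 2 - tc2 * V[i1, i1]

    def is_sig(w):
        eff = b1 + b3 * w
        var = V[i1, i1] + w ** 2 * V[i3, i3] + 2 * w * V[i1, i3]
        return eff * eff > tc2 * var

    if abs(a) < 1e-14:
        # degenerate quadratic: fall back to a dense grid
        if w_range is None:
            s = result.moderator_values.max() or 1.0
            w_range = (-5 * abs(s), 5 * abs(s))
        grid = np.linspace(*w_range, 100_001)
        sig = np.array([is_sig(w) for w in grid])
        if sig.all():
            return JNResult([], "entire range", None, "degenerate_all")
        if not sig.any():
            return JNResult([], "nowhere", None, "degenerate_none")
        edges = grid[:-1][np.diff(sig.astype(int)) != 0]
        return JNResult([float(e) for e in edges], "from grid search", None,
                        "degenerate_grid")

    disc = b * b - 4 * a * c
    if disc < 0:
        everywhere = is_sig(0.0)
        return JNResult([], "entire range" if everywhere else "nowhere",
                        None, "no_real_roots")
    r1, r2 = sorted(((-b - np.sqrt(disc)) / (2 * a),
                     (-b + np.sqrt(disc)) / (2 * a)))
    between = is_sig((r1 + r2) / 2.0)
    region = (f"significant for moderator in ({r1:.6g}, {r2:.6g})" if between
              else f"significant outside [{r1:.6g}, {r2:.6g}]")
    return JNResult([float(r1), float(r2)], region, bool(between), "two_roots")


def effect_sizes(partial_eta2: float | None = None,
                 delta_r2: float | None = None,
                 r2_full: float | None = None) -> dict:
    """Closed-form effect-size conversions.

    Supply ``partial_eta2`` for Cohen's f, and/or (``delta_r2``,
    ``r2_full``) for Cohen's f^2.
    """
    out = {}
    if partial_eta2 is not None:
        out["partial_eta2"] = float(partial_eta2)
        out["cohen_f"] = cohens_f_from_eta2(partial_eta2)
    if delta_r2 is not None:
        if r2_full is None:
            raise ValueError("r2_full required with delta_r2")
        out["delta_r2"] = float(delta_r2)
        out["r2_full"] = float(r2_full)
        out["cohen_f2"] = cohens_f2_from_delta_r2(delta_r2, r2_full)
    if not out:
        raise ValueError("nothing to convert")
    return out


def posthoc_power(f2: float, df1: int, df2: int, n: int | None = None,
                  alpha: float = 0.05, ncp_convention: str = "n"
                  ) -> dict:
    """Achieved power of an F test at effect size f^2.

    Power = P(noncentral F(df1, df2, ncp) > F_crit(alpha)).  Two
    noncentrality conventions are in circulation: ``"n"`` uses
    ncp = f^2 * N (requires ``n``); ``"df"`` uses
    ncp = f^2 * (df1 + df2 + 1).  The convention is recorded in the
    output; both can be requested via ``ncp_convention="both"``.
    """
    if f2 < 0:
        raise ValueError("f^2 must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    fcrit = st.f.ppf(1 - alpha, df1, df2)

    def power(ncp):
        if ncp == 0:
            return float(alpha)
        return float(st.ncf.sf(fcrit, df1, df2, ncp))

    out = {"alpha": alpha, "df1": df1, "df2": df2, "f2": f2}
    if ncp_convention in ("n", "both"):
        if n is None:
            raise ValueError("n required for the ncp = f^2*N convention")
        out["power_ncp_n"] = power(f2 * n)
    if ncp_convention in ("df", "both"):
        out["power_ncp_df"] = power(f2 * (df1 + df2 + 1))
    if ncp_convention not in ("n", "df", "both"):
        raise ValueError("ncp_convention must be 'n', 'df', or 'both'")
    return out
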