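"""Genotype–phenotype association in inbred-line panels.

Tests whether the indel genotype is associated with log2-scale expression
(Student's t test, fold change as 2^Δmean) and with survival under
oxidative stress (Cox proportional hazards with sex, genotype and line as
factors; Spearman rank correlation between expression and survival).

The Cox model is fit here by Newton–Raphson maximization of the partial
likelihood with Efron (default) or Breslow handling of tied event times;
per-covariate Wald tests are reported. Line effects enter either as
treatment-coded indicators (default) or as strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import DELETION, NON_DELETION
from .qpcr import variance_explained


def expression_ttest(
    expr_del, expr_non, welch: bool = False
) -> dict[str, float]:
    """Two-sample t test on log2 expression plus the implied fold change.

    Pooled-variance Student's t by default (Welch optional). The fold
    change is 2^(mean_del − mean_non) since expression is log2-scale.
    """
    a = np.asarray(expr_del, dtype=float)
    b = np.asarray(expr_non, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 lines per genotype group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return dict(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        fold=float(2.0 ** (a.mean() - b.mean())),
        mean_del=float(a.mean()),
        mean_non=float(b.mean()),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def prepare_line_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Drop lines with a single expression replicate in either sex."""
    required = {"line_id", "sex", "expression_rep1", "expression_rep2"}
    if not required <= set(panel.columns):
        return panel
    bad = panel["expression_rep1"].isna() | panel["expression_rep2"].isna()
    bad_lines = set(panel.loc[bad, "line_id"])
    if bad_lines:
        warnings.warn(
            f"excluding {len(bad_lines)} line(s) with a single expression replicate",
            stacklevel=2,
        )
    return panel[~panel["line_id"].isin(bad_lines)].copy()


# ---------------------------------------------------------------- Cox PH ---


@dataclass
class CoxFit:
    summary: pd.DataFrame  # coef, se, hazard_ratio, p per covariate column
    loglik: float
    converged: bool
    ties_method: str
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hazard_ratio"])

    def p(self, name: str) -> float:
        return float(self.summary.loc[name, "p"])


def _design_matrix(
    df: pd.DataFrame,
    covariates,
    line_col: str | None,
    line_mode: str,
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for c in covariates:
        s = df[c]
        values = set(s.dropna().unique())
        if values <= {DELETION, NON_DELETION}:
            cols[f"{c}_{DELETION}"] = (s == DELETION).astype(float).to_numpy()
        elif s.dtype.kind in "ifu":
            cols[c] = s.astype(float).to_numpy()
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=c, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].astype(float).to_numpy()
    if line_col is not None and line_mode == "factor":
        dummies = pd.get_dummies(df[line_col].astype(str), prefix="line", drop_first=True)
        for name in dummies.columns:
            cols[name] = dummies[name].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=df.index)
    if X.shape[1] == 0:
        raise ValueError("no covariates")
    return X


def _drop_aliased(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Sequentially drop columns linearly dependent on earlier ones.

    The partial likelihood is invariant to a constant shift of the linear
    predictor, so dependence is assessed on centered columns; covariates
    precede line indicators, so aliased line dummies are the ones dropped
    (mirrors how R marks aliased factor levels NA).
    """
    keep: list[int] = []
    dropped: list[str] = []
    basis: list[np.ndarray] = []
    for k in range(X.shape[1]):
        col = X[:, k].astype(float)
        norm0 = np.linalg.norm(col)
        v = col.copy()
        for b in basis:
            v -= (b @ col) * b
        if norm0 > tol and np.linalg.norm(v) > tol * max(norm0, 1.0):
            basis.append(v / np.linalg.norm(v))
            keep.append(k)
        else:
            dropped.append(names[k])
    return keep, dropped


def _partial_loglik(beta, X, time, event, ties):
    """Log partial likelihood, gradient and observed information (one stratum).

    Times are processed in decreasing order with running risk-set sums
    S0 = Σ w, S1 = Σ w·x, S2 = Σ w·xxᵀ, so memory is O(p²) regardless of n.
    """
    order = np.argsort(-time, kind="stable")
    Xs, ts, ds = X[order], time[order], event[order]
    n, p = Xs.shape
    eta = np.clip(Xs @ beta, -200, 200)
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        block = Xs[i:j]
        wb = w[i:j]
        S0 += float(wb.sum())
        S1 += wb @ block
        S2 += (block * wb[:, None]).T @ block
        deaths = [k for k in range(i, j) if ds[k]]
        d = len(deaths)
        if d:
            wD = w[deaths]
            xD = Xs[deaths]
            ll += float(eta[deaths].sum())
            grad += xD.sum(axis=0)
            if ties == "efron" and d > 1:
                S0D = wD.sum()
                S1D = (wD[:, None] * xD).sum(axis=0)
                S2D = (wD[:, None, None] * (xD[:, :, None] * xD[:, None, :])).sum(axis=0)
            else:
                S0D = 0.0
                S1D = np.zeros(p)
                S2D = np.zeros((p, p))
            for l in range(d):
                f = l / d if (ties == "efron" and d > 1) else 0.0
                phi0 = S0 - f * S0D
                phi1 = S1 - f * S1D
                phi2 = S2 - f * S2D
                ll -= float(np.log(phi0))
                grad -= phi1 / phi0
                info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
        i = j
    return ll, grad, info


def cox_ph(
    df: pd.DataFrame,
    duration_col: str = "survival_time",
    event_col: str = "event",
    covariates=("sex", "genotype"),
    line_col: str | None = None,
    line_mode: str = "factor",
    strata_col: str | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton–Raphson on the partial likelihood.

    ``ties`` is ``"efron"`` (default) or ``"breslow"``. ``line_col`` adds
    treatment-coded line indicators (``line_mode="factor"``) or, with
    ``line_mode="strata"``, stratifies the baseline hazard by line;
    ``strata_col`` stratifies by an arbitrary column. Wald tests per
    covariate. Raises on non-convergence; a monotone partial likelihood
    (complete separation) is flagged.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=float).astype(bool)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if len(np.unique(time[event])) < 2:
        raise ValueError("need >= 2 distinct event times")
    strata_key = None
    if line_col is not None and line_mode == "strata":
        strata_key = df[line_col].astype(str)
        line_col = None
    elif strata_col is not None:
        strata_key = df[strata_col].astype(str)
    Xf = _design_matrix(df, covariates, line_col, line_mode)
    names = list(Xf.columns)
    X = Xf.to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # centering: pure conditioning, no effect on beta
    keep, aliased = _drop_aliased(X, names)
    flags_init: list[str] = []
    if aliased:
        warnings.warn(
            f"dropping aliased design column(s): {aliased}", stacklevel=2
        )
        flags_init = [f"aliased:{nm}" for nm in aliased]
        X = X[:, keep]
        names = [names[k] for k in keep]
    if not names:
        raise ValueError("design matrix has no identifiable columns")
    groups = (
        [np.ones(len(df), dtype=bool)]
        if strata_key is None
        else [(strata_key == s).to_numpy() for s in strata_key.unique()]
    )

    def evaluate(beta):
        ll = 0.0
        g = np.zeros(len(names))
        I = np.zeros((len(names), len(names)))
        for sel in groups:
            if not np.any(event[sel]):
                continue
            a, b, c = _partial_loglik(beta, X[sel], time[sel], event[sel], ties)
            ll += a
            g += b
            I += c
        return ll, g, I

    beta = np.zeros(len(names))
    ll, g, I = evaluate(beta)
    converged = False
    flags: list[str] = list(flags_init)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(I + 1e-12 * np.eye(len(names)), g)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_g, new_I = evaluate(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 25:
            step /= 2
            new_beta = beta + step
            new_ll, new_g, new_I = evaluate(new_beta)
            halvings += 1
        delta_ll = new_ll - ll
        beta, ll, g, I = new_beta, new_ll, new_g, new_I
        if np.max(np.abs(beta)) > 25:
            flags.append("monotone_likelihood")
            break
        if np.max(np.abs(g)) < 1e-7 or abs(delta_ll) < tol:
            converged = True
            break
    if not converged and "monotone_likelihood" not in flags:
        raise ValueError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|grad|max={np.max(np.abs(g)):.3g})"
        )
    cov = np.linalg.inv(I + 1e-12 * np.eye(len(names)))
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        dict(
            coef=beta,
            se=se,
            hazard_ratio=np.exp(beta),
            p=pvals,
        ),
        index=names,
    )
    return CoxFit(
        summary=summary,
        loglik=float(ll),
        converged=converged,
        ties_method=ties,
        n=int(len(df)),
        n_events=int(event.sum()),
        flags=flags,
    )


def agent_contrast(
    panel: pd.DataFrame,
    ties: str = "efron",
    line_col: str | None = "line_id",
    line_mode: str = "factor",
) -> pd.DataFrame:
    """Per-agent association summary: expression–survival Spearman and the
    genotype hazard ratio from the Cox model (no new statistics).

    A missing agent yields a partial report with a warning.
    """
    agents = list(panel["agent"].unique())
    for expected in ("MSB", "paraquat"):
        if expected not in agents:
            warnings.warn(f"no records for agent {expected!r}", stacklevel=2)
    rows = []
    gcol = f"genotype_{DELETION}"
    for agent in agents:
        sub = panel[panel["agent"] == agent]
        rho, rho_p = spearman(sub["expression"], sub["survival_time"])
        fit = cox_ph(
            sub,
            covariates=("sex", "genotype"),
            line_col=line_col if line_col in sub.columns else None,
            line_mode=line_mode,
            ties=ties,
        )
        rows.append(
            dict(
                agent=agent,
                n=len(sub),
                spearman_rho=rho,
                spearman_p=rho_p,
                genotype_hazard_ratio=fit.hazard_ratio(gcol),
                genotype_coef=fit.coef(gcol),
                genotype_p=fit.p(gcol),
                converged=fit.converged,
            )
        )
    return pd.DataFrame(rows)


__all__ = [
    "CoxFit",
    "expression_ttest",
    "spearman",
    "prepare_line_panel",
    "cox_ph",
    "agent_contrast",
]
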