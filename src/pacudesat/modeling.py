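"""Multivariable logistic modeling of early postoperative respiratory
complications.

The centerpiece is change-in-estimate backward selection anchored on the
primary exposure: starting from the fully specified model, the removable
covariate with the largest Wald p-value is dropped; if removing it moves
the exposure's log odds ratio by more than 10% — |ln(AOR_full / AOR_-1)| >
0.10 — the covariate is restored and, by default, the whole procedure
stops at that first retained covariate.  Every step is recorded in a
ledger so the final model can be replayed.

Diagnostics cover discrimination (c-statistic with Hanley-McNeil SE),
calibration (Hosmer-Lemeshow over deciles of risk), collinearity (VIF and
condition indices of the scaled design), and the omnibus likelihood-ratio
test against the intercept-only model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """What to fit: outcome, primary exposure term(s) (never removable),
    and the removable covariate candidates, all named by data columns."""

    outcome: str
    exposure_terms: List[str]
    candidates: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.exposure_terms) & set(self.candidates)
        if overlap:
            raise ValueError(f"exposure terms cannot be candidates: {sorted(overlap)}")


@dataclass
class Diagnostics:
    c_statistic: float
    c_se: float
    hosmer_lemeshow: float
    hl_df: int
    hl_p: float
    hl_groups: int
    vif: Dict[str, float]
    condition_indices: List[float]
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float


@dataclass
class FittedModel:
    terms: List[str]
    params: Dict[str, float]
    bse: Dict[str, float]
    wald_p: Dict[str, float]
    aor: Dict[str, float]
    ci_low: Dict[str, float]
    ci_high: Dict[str, float]
    llf: float
    llnull: float
    n: int
    diagnostics: Optional[Diagnostics] = None
    dropped_terms: List[Dict[str, object]] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "estimate": self.params[t],
                "se": self.bse[t],
                "aor": self.aor[t],
                "ci_low": self.ci_low[t],
                "ci_high": self.ci_high[t],
                "p_value": self.wald_p[t],
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


def _design(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = data[list(terms)].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_logistic(
    spec: ModelSpec,
    data: pd.DataFrame,
    extra_terms: Sequence[str] = (),
    with_diagnostics: bool = False,
) -> FittedModel:
    """Maximum-likelihood logistic fit (Newton/IRLS, tol 1e-8, <=100 iter).

    Raises :class:`SeparationError` when any estimate exceeds 15 in
    magnitude (quasi-separation) and :class:`ConvergenceError` on
    non-convergence, naming the last deviance.
    """
    terms = list(spec.exposure_terms) + list(spec.candidates) + list(extra_terms)
    sub = data[[spec.outcome] + terms].dropna()
    y = sub[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must have both classes present")
    if len(sub) <= len(terms) + 1:
        raise ValueError("need n > number of terms")
    X = _design(sub, terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        except np.linalg.LinAlgError:
            # singular Hessian: usually a separating covariate; refit with a
            # gradient method so the offender can be named
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
    bad = [t for t in X.columns if t != "const" and abs(res.params[t]) > SEPARATION_BOUND]
    if bad:
        raise SeparationError(f"quasi-separation suspected for term(s) {bad}")
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge; last deviance {-2 * res.llf:.3f}")

    cols = [c for c in X.columns]
    model = FittedModel(
        terms=[c for c in cols if c != "const"],
        params={c: float(res.params[c]) for c in cols},
        bse={c: float(res.bse[c]) for c in cols},
        wald_p={c: float(res.pvalues[c]) for c in cols},
        aor={c: float(np.exp(res.params[c])) for c in cols},
        ci_low={c: float(np.exp(res.params[c] - 1.96 * res.bse[c])) for c in cols},
        ci_high={c: float(np.exp(res.params[c] + 1.96 * res.bse[c])) for c in cols},
        llf=float(res.llf),
        llnull=float(res.llnull),
        n=int(len(sub)),
    )
    if with_diagnostics:
        model.diagnostics = diagnostics(
            np.asarray(res.predict(X)), y.to_numpy(), X, float(res.llf), float(res.llnull)
        )
    return model


def c_statistic(scores: np.ndarray, outcome: np.ndarray) -> Tuple[float, float]:
    """Concordance of fitted risks over case/control pairs (ties count 1/2),
    with the Hanley-McNeil standard error."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    cases = scores[outcome == 1]
    controls = scores[outcome == 0]
    n1, n0 = len(cases), len(controls)
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    ranks = stats.rankdata(scores)
    auc = (ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(auc), float(np.sqrt(max(var, 0.0)))


def hosmer_lemeshow(
    probs: np.ndarray, outcome: np.ndarray, groups: int = 10
) -> Tuple[float, int, float, int]:
    """Hosmer-Lemeshow statistic over deciles of fitted risk.

    Returns (statistic, df, p, groups_used); duplicate decile edges
    collapse groups with a warning, and df = groups_used - 2.
    """
    probs = np.asarray(probs, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    try:
        bins = pd.qcut(probs, groups, duplicates="drop")
    except ValueError:
        bins = pd.qcut(probs, 2, duplicates="drop")
    df_groups = pd.DataFrame({"p": probs, "y": outcome, "g": bins})
    agg = df_groups.groupby("g", observed=True).agg(n=("y", "size"), o=("y", "sum"), pbar=("p", "mean"))
    used = len(agg)
    if used < groups:
        warnings.warn(f"Hosmer-Lemeshow groups collapsed to {used}", stacklevel=2)
    e = agg["n"] * agg["pbar"]
    denom = agg["n"] * agg["pbar"] * (1 - agg["pbar"])
    stat = float((((agg["o"] - e) ** 2) / denom.replace(0, np.nan)).dropna().sum())
    dof = max(used - 2, 1)
    return stat, dof, float(stats.chi2.sf(stat, dof)), used


def condition_indices(X: pd.DataFrame) -> List[float]:
    """Condition indices of the column-equilibrated design (intercept in)."""
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    s = np.linalg.svd(A / norms, compute_uv=False)
    s = s[s > 1e-12]
    return list((s.max() / s).astype(float))


def design_vif(X: pd.DataFrame) -> Dict[str, float]:
    """Per-term VIF from auxiliary regressions on the design matrix."""
    cols = [c for c in X.columns if c != "const"]
    A = X.to_numpy(dtype=float)
    out = {}
    for c in cols:
        out[c] = float(variance_inflation_factor(A, list(X.columns).index(c)))
    return out


def diagnostics(
    probs: np.ndarray, outcome: np.ndarray, X: pd.DataFrame, llf: float, llnull: float
) -> Diagnostics:
    auc, auc_se = c_statistic(probs, outcome)
    hl, hl_df, hl_p, used = hosmer_lemeshow(probs, outcome)
    k = len([c for c in X.columns if c != "const"])
    omni = 2.0 * (llf - llnull)
    return Diagnostics(
        c_statistic=auc,
        c_se=auc_se,
        hosmer_lemeshow=hl,
        hl_df=hl_df,
        hl_p=hl_p,
        hl_groups=used,
        vif=design_vif(X),
        condition_indices=condition_indices(X),
        omnibus_chi2=float(omni),
        omnibus_df=k,
        omnibus_p=float(stats.chi2.sf(omni, k)) if k else 1.0,
    )


def viable_candidates(
    data: pd.DataFrame, outcome: str, candidates: Sequence[str], min_cell: int = 1
) -> List[str]:
    """Candidates whose level-by-outcome cross-tab has no empty cell.

    Covariates with zero events in a level cannot be estimated by plain ML
    (their coefficients diverge); screening them out up front keeps the
    selection loop on estimable terms.
    """
    keep = []
    for c in candidates:
        sub = data[[c, outcome]].dropna()
        tab = pd.crosstab(sub[c], sub[outcome])
        if tab.shape[1] == 2 and (tab.to_numpy() >= min_cell).all():
            keep.append(c)
    return keep


def linearity_of_logits(
    data: pd.DataFrame,
    variable: str,
    outcome: str,
    tolerance: float = 0.15,
) -> Dict[str, object]:
    """Ordinal-vs-indicator coding decision for an ordinal covariate.

    Per-level empirical logits are computed (0.5 continuity correction on
    zero-event levels, flagged); the variable keeps ordinal coding when the
    incremental logit steps are monotone and each step is within
    ``tolerance`` of the mean step, else it is recoded as indicators.
    Binary variables pass through (the distinction is vacuous).
    """
    sub = data[[variable, outcome]].dropna()
    levels = sorted(sub[variable].unique())
    if len(levels) <= 2:
        return {"decision": "ordinal", "logits": {}, "corrected_levels": [], "vacuous": True}
    logits, corrected = {}, []
    for lev in levels:
        grp = sub[sub[variable] == lev][outcome]
        events, n = float(grp.sum()), float(len(grp))
        if events == 0 or events == n:
            events += 0.5
            n += 1.0
            corrected.append(lev)
        logits[lev] = float(np.log(events / (n - events)))
    steps = np.diff([logits[lev] for lev in levels])
    monotone = bool(np.all(steps >= 0) or np.all(steps <= 0))
    within = bool(np.max(np.abs(steps - steps.mean())) <= tolerance)
    decision = "ordinal" if (monotone and within) else "indicator"
    return {
        "decision": decision,
        "logits": logits,
        "steps": list(steps.astype(float)),
        "corrected_levels": corrected,
        "vacuous": False,
    }


def _exposure_delta(current: FittedModel, reduced: FittedModel, exposure_terms: Sequence[str]) -> float:
    return max(
        abs(np.log(current.aor[t]) - np.log(reduced.aor[t])) for t in exposure_terms
    )


def change_in_estimate_selection(
    spec: ModelSpec,
    data: pd.DataFrame,
    threshold: float = 0.10,
    stop_at_first_retained: bool = True,
    from_full_model: bool = False,
    with_diagnostics: bool = True,
) -> FittedModel:
    """Backward covariate selection by the change-in-estimate criterion.

    At each step the removable covariate with the largest Wald p-value
    (ties broken by candidate list order) is tentatively removed and the
    exposure AOR compared between the two fits: Delta =
    |ln(AOR_current / AOR_reduced)|.  Delta > ``threshold`` restores the
    covariate — and by default stops the whole procedure there; pass
    ``stop_at_first_retained=False`` to keep screening the remaining
    candidates.  ``from_full_model=True`` compares each reduced model to
    the original full model instead of the current one.  The ledger on the
    returned model records every step.

    A failing intermediate fit aborts selection with the partial ledger
    attached to the raised error.
    """
    ledger: List[Dict[str, object]] = []
    in_model = list(spec.candidates)       # candidates currently in the model
    removable = list(spec.candidates)      # subset still eligible for removal
    full = fit_logistic(ModelSpec(spec.outcome, spec.exposure_terms, in_model), data)
    current = full
    order = {t: i for i, t in enumerate(spec.candidates)}
    step = 0
    try:
        while removable:
            target = max(removable, key=lambda t: (current.wald_p[t], -order[t]))
            reduced_terms = [t for t in in_model if t != target]
            reduced = fit_logistic(ModelSpec(spec.outcome, spec.exposure_terms, reduced_terms), data)
            baseline = full if from_full_model else current
            delta = _exposure_delta(baseline, reduced, spec.exposure_terms)
            step += 1
            retained = delta > threshold
            ledger.append(
                {
                    "step": step,
                    "term": target,
                    "wald_p": current.wald_p[target],
                    "delta": float(delta),
                    "action": "retained" if retained else "dropped",
                }
            )
            removable.remove(target)
            if retained:
                if stop_at_first_retained:
                    break
                continue  # covariate kept in the model, no longer screened
            in_model.remove(target)
            current = reduced
    except (SeparationError, ConvergenceError, ValueError) as err:
        err.args = (f"{err.args[0]} (selection aborted; partial ledger: {ledger})",)
        raise

    kept = in_model
    final = fit_logistic(
        ModelSpec(spec.outcome, spec.exposure_terms, kept), data, with_diagnostics=with_diagnostics
    )
    final.dropped_terms = ledger
    return final


@dataclass
class InteractionResult:
    """2x2 matrix of stratum AORs (exposure level x stratifier level) from a
    product-term model, the product-term Wald p, and the stratify flag."""

    cell_aor: Dict[Tuple[int, int], float]
    cell_p: Dict[Tuple[int, int], float]
    product_p: float
    stratify: bool
    degenerate: bool = False


def interaction_analysis(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    stratifier: str,
    covariates: Sequence[str] = (),
    alpha: float = 0.05,
) -> InteractionResult:
    """Exposure-by-stratifier interaction via a product-term model.

    Cell AORs are contrasts against the joint (0, 0) reference:
    exp(b_e*e + b_s*s + b_es*e*s), with Wald p-values from the linear
    combination.  ``stratify`` is product-term p < alpha.  An empty
    exposure-by-stratum cell flags the result degenerate with no decision.
    """
    sub = data[[outcome, exposure, stratifier, *covariates]].dropna()
    counts = sub.groupby([exposure, stratifier]).size()
    if len(counts) < 4:
        return InteractionResult({}, {}, np.nan, False, degenerate=True)
    work = sub.copy()
    work["_product"] = work[exposure] * work[stratifier]
    spec = ModelSpec(outcome, [exposure, stratifier, "_product"], list(covariates))
    terms = spec.exposure_terms + spec.candidates
    X = _design(work, terms)
    y = work[outcome].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    idx = {c: i for i, c in enumerate(X.columns)}
    cell_aor, cell_p = {(0, 0): 1.0}, {(0, 0): np.nan}
    for e, s in [(1, 0), (0, 1), (1, 1)]:
        L = np.zeros(len(X.columns))
        L[idx[exposure]] = e
        L[idx[stratifier]] = s
        L[idx["_product"]] = e * s
        tt = res.t_test(L)
        cell_aor[(e, s)] = float(np.exp(tt.effect[0]))
        cell_p[(e, s)] = float(tt.pvalue)
    product_p = float(res.pvalues["_product"])
    return InteractionResult(cell_aor, cell_p, product_p, bool(product_p < alpha))


def stratified_models(
    spec: ModelSpec, data: pd.DataFrame, stratifier: str, **selection_kwargs
) -> Dict[object, object]:
    """Full change-in-estimate pipeline run independently per stratum.

    Per-stratum failures are isolated: the failing stratum maps to its
    exception, the other is still reported.
    """
    out: Dict[object, object] = {}
    for level, grp in data.groupby(stratifier):
        try:
            out[level] = change_in_estimate_selection(spec, grp, **selection_kwargs)
        except Exception as err:  # noqa: BLE001 - isolation is the contract
            out[level] = err
    return out
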