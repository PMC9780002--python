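"""Prognostic risk scoring and survival evaluation machinery.

The risk score is a fixed linear combination of gene expression values,

    RiskScore = sum_g coefficient_g * expression_g            (no intercept)

with the published 10-gene gastric-cancer model shipped as package data
(``RiskModel.load_published``). Around it sit the evaluation tools the
signature workflow needs: the Kaplan-Meier product-limit estimator, the
two-group log-rank test with an O/E hazard-ratio approximation, a
maximally-selected log-rank cutoff search, univariate Cox regression via
Newton-Raphson on the Breslow partial likelihood, IPCW time-dependent
(cumulative-case / dynamic-control) ROC AUC, and a resampling
stability-selection wrapper around cross-validated lasso-Cox that counts
how often each gene (and each exact gene combination) is selected across B
repetitions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "KMCurve",
    "SelectionFrequency",
    "risk_score",
    "zscore",
    "km_estimate",
    "logrank_test",
    "maxstat_cutoff",
    "cox_univariate",
    "breslow_loglik",
    "td_auc",
    "stability_select",
    "assign_risk_groups",
]


# ---------------------------------------------------------------------------
# risk model


@dataclass
class RiskModel:
    """Ordered gene list with one real coefficient per gene."""

    genes: list[str]
    coefficients: dict[str, float]
    name: str = "risk-model"
    center: dict[str, float] | None = None  # optional per-gene z-scaling
    scale: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in model")
        missing = [g for g in self.genes if g not in self.coefficients]
        if missing:
            raise ValueError(f"genes without coefficients: {missing}")
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("coefficients must be finite")

    @classmethod
    def load_published(cls) -> "RiskModel":
        """The published 10-gene PD-1-negative gastric-cancer model."""
        payload = json.loads(
            resources.files("dmegnet").joinpath("data/risk_model.json").read_text()
        )
        return cls(genes=payload["genes"], coefficients=payload["coefficients"], name=payload["name"])

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=payload["genes"],
            coefficients=payload["coefficients"],
            name=payload.get("name", "risk-model"),
            center=payload.get("center"),
            scale=payload.get("scale"),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {"name": self.name, "genes": self.genes, "coefficients": self.coefficients}
        if self.center is not None:
            payload["center"] = self.center
        if self.scale is not None:
            payload["scale"] = self.scale
        Path(path).write_text(json.dumps(payload, indent=1))


def risk_score(expr: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Linear risk score per sample from a gene x sample log2 matrix.

    Raises on missing model genes, naming them (the published model's
    RP11-44K6.2, for instance, is absent from some array platforms).
    """
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"model genes absent from expression matrix: {missing}")
    scores = pd.Series(0.0, index=expr.columns, name="risk_score")
    for gene in model.genes:
        x = expr.loc[gene].astype(float)
        if model.center is not None:
            x = x - model.center.get(gene, 0.0)
        if model.scale is not None:
            x = x / model.scale.get(gene, 1.0)
        scores = scores + model.coefficients[gene] * x
    return scores


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, SD 1 (denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate at the ordered event times."""

    times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t) -> np.ndarray:
        """S(t), right-continuous step function with S(0) = 1."""
        if self.times.size == 0:
            return np.ones_like(np.atleast_1d(t), dtype=float)
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)

    def before(self, t) -> np.ndarray:
        """Left limit S(t-)."""
        if self.times.size == 0:
            return np.ones_like(np.atleast_1d(t), dtype=float)
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="left") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)


def _as_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("time and event must be equal-length 1-d arrays")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event must be 0/1")
    return t, e


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Ties are processed together per time point; samples censored exactly at
    an event time count as at risk for that time.
    """
    t, e = _as_time_event(time, event)
    if t.size == 0:
        raise ValueError("empty survival data")
    event_times = np.unique(t[e == 1])
    surv, at_risk, d_events = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        d_events.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        events=np.asarray(d_events),
    )


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hr: float  # O/E approximation exp((O1-E1)/V) for group1
    observed1: float
    expected1: float
    variance: float


def _logrank_oev(t, e, in1) -> tuple[float, float, float]:
    """O1, E1 and hypergeometric variance summed over distinct event times."""
    o1 = e1 = v = 0.0
    for et in np.unique(t[e == 1]):
        risk = t >= et
        n = int(risk.sum())
        n1 = int((risk & in1).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & in1).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o1, e1, v


def logrank_test(time, event, groups, group1: str | None = None) -> LogrankResult:
    """Two-group log-rank test.

    ``groups`` is a length-n label array (or boolean, True = group 1).
    chi2 = (O1-E1)^2 / V with 1 df; the hazard ratio reported is the O/E
    approximation exp((O1-E1)/V) for group 1 versus the other group.
    """
    t, e = _as_time_event(time, event)
    g = np.asarray(groups)
    if g.dtype == bool:
        in1 = g
    else:
        levels = sorted(pd.unique(g).tolist())
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        if group1 is None:
            group1 = "high" if "high" in levels else levels[1]
        in1 = g == group1
    if in1.all() or not in1.any():
        raise ValueError("one group is empty")
    if e.sum() == 0:
        raise ValueError("no events")
    o1, e1, v = _logrank_oev(t, e, in1)
    if v == 0:
        raise ValueError("log-rank variance is zero (a group never at risk with the other)")
    chi2 = (o1 - e1) ** 2 / v
    return LogrankResult(
        chi2=chi2,
        p=float(stats.chi2.sf(chi2, df=1)),
        hr=float(np.exp((o1 - e1) / v)),
        observed1=o1,
        expected1=e1,
        variance=v,
    )


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """Label samples 'high' when score > cutoff (strict), else 'low'."""
    return pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)


def maxstat_cutoff(
    scores, time, event, min_group_frac: float = 0.1
) -> tuple[float, float]:
    """Maximally selected log-rank cutoff on a continuous score.

    Scans every midpoint between consecutive sorted distinct score values
    whose split leaves both groups with at least ``min_group_frac`` of the
    samples, and returns (cutoff, chi2) for the split maximising the
    log-rank statistic. Samples with score > cutoff form the high group.
    """
    s = np.asarray(scores, dtype=float)
    t, e = _as_time_event(time, event)
    if s.size != t.size:
        raise ValueError("scores and survival data differ in length")
    if s.size < 10:
        raise ValueError("need at least 10 samples")
    if e.sum() == 0:
        raise ValueError("no events")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("scores are constant")
    n = s.size
    min_n = min_group_frac * n
    best: tuple[float, float] | None = None
    for cut in (uniq[:-1] + uniq[1:]) / 2.0:
        high = s > cut
        n_high = int(high.sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        try:
            chi2 = logrank_test(t, e, high).chi2
        except ValueError:
            continue
        if best is None or chi2 > best[1]:
            best = (float(cut), float(chi2))
    if best is None:
        raise ValueError("no admissible split under min_group_frac")
    return best


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)


def breslow_loglik(lp, time, event) -> np.ndarray:
    """Breslow log partial likelihood of linear predictors.

    ``lp`` may be (n,) or (n, k) for k candidate models; returns a scalar
    array of shape () or (k,).
    """
    t, e = _as_time_event(time, event)
    lp = np.asarray(lp, dtype=float)
    squeeze = lp.ndim == 1
    if squeeze:
        lp = lp[:, None]
    total = np.zeros(lp.shape[1])
    for et in np.unique(t[e == 1]):
        dead = (t == et) & (e == 1)
        risk = t >= et
        total += lp[dead].sum(axis=0) - dead.sum() * logsumexp(lp[risk], axis=0)
    return total[0] if squeeze else total


@dataclass
class CoxResult:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    separation: bool = False


def cox_univariate(covariate, time, event, max_iter: int = 50, tol: float = 1e-10) -> CoxResult:
    """Single-covariate Cox regression, Newton-Raphson on the Breslow likelihood.

    HR = exp(beta); 95% Wald CI = exp(beta +/- 1.96 se); p from the Wald
    statistic. A monotone likelihood (perfect separation) is flagged and
    yields an effectively unbounded CI.
    """
    x = np.asarray(covariate, dtype=float)
    t, e = _as_time_event(time, event)
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant")

    event_times = np.unique(t[e == 1])
    dead_masks = [(t == et) & (e == 1) for et in event_times]
    risk_masks = [t >= et for et in event_times]

    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        score = 0.0
        info = 0.0
        w_all = np.exp(beta * x)
        for dead, risk in zip(dead_masks, risk_masks):
            w = w_all[risk]
            xr = x[risk]
            s0 = w.sum()
            s1 = (w * xr).sum()
            s2 = (w * xr * xr).sum()
            d = dead.sum()
            score += x[dead].sum() - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(step) < tol:
            converged = True
            break

    separation = not converged and abs(beta) > 10
    if separation:
        logger.warning("monotone partial likelihood: perfect separation suspected")
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    wald = beta / se if np.isfinite(se) and se > 0 else float("inf")
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=float(2 * stats.norm.sf(abs(wald))),
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# time-dependent AUC


def td_auc(scores, time, event, horizons) -> dict[float, float]:
    """Cumulative-case / dynamic-control AUC at each horizon, IPCW-weighted.

    Cases at horizon tau are samples with an event by tau (weight
    1/G(T_i-)); controls are samples still event-free past tau (weight
    1/G(tau)), with G the Kaplan-Meier estimate of the censoring survival.
    A horizon with no cases or no controls maps to NaN (flagged in the log).
    """
    s = np.asarray(scores, dtype=float)
    t, e = _as_time_event(time, event)
    cens_km = km_estimate(t, 1 - e) if (1 - e).sum() > 0 else None
    out: dict[float, float] = {}
    for tau in np.atleast_1d(horizons):
        tau = float(tau)
        if tau <= 0 or tau > t.max():
            raise ValueError(f"horizon {tau} outside the observed time range")
        case = (t <= tau) & (e == 1)
        ctrl = t > tau
        if not case.any() or not ctrl.any():
            logger.warning("horizon %s has no cases or no controls; AUC undefined", tau)
            out[tau] = float("nan")
            continue
        if cens_km is None:
            w_case = np.ones(case.sum())
            w_ctrl_scalar = 1.0
        else:
            g_case = cens_km.before(t[case])
            g_tau = float(cens_km.at(tau)[0])
            keep = g_case > 0
            case_idx = np.flatnonzero(case)[keep]
            case = np.zeros_like(case)
            case[case_idx] = True
            w_case = 1.0 / g_case[keep]
            if g_tau <= 0 or not case.any():
                out[tau] = float("nan")
                continue
            w_ctrl_scalar = 1.0 / g_tau
        sc, st = s[case], s[ctrl]
        w_ctrl = np.full(st.size, w_ctrl_scalar)
        comp = (sc[:, None] > st[None, :]) + 0.5 * (sc[:, None] == st[None, :])
        num = float(w_case @ comp @ w_ctrl)
        den = float(w_case.sum() * w_ctrl.sum())
        out[tau] = num / den
    return out


# ---------------------------------------------------------------------------
# stability selection


@dataclass
class SelectionFrequency:
    """Gene and gene-combination selection counts over B lasso repetitions."""

    B: int
    gene_counts: dict[str, int]
    combination_counts: dict[tuple[str, ...], int] = field(repr=False)

    @property
    def modal_combination(self) -> tuple[str, ...]:
        return max(self.combination_counts, key=lambda c: (self.combination_counts[c], c))

    def to_frame(self) -> pd.DataFrame:
        return (
            pd.DataFrame(
                sorted(self.gene_counts.items(), key=lambda kv: (-kv[1], kv[0])),
                columns=["gene", "count"],
            ).set_index("gene")
        )


def _cv_lasso_selected(
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
    n_alphas: int,
) -> np.ndarray | None:
    """One repetition: CV-tuned lasso-Cox, returns the nonzero-coef mask."""
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(e.astype(bool), t)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.05)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    cv_ll = np.zeros(alphas.size)
    folds = KFold(n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    for train, test in folds.split(X):
        if e[train].sum() == 0 or e[test].sum() == 0:
            return None
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        try:
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="all coefficients are zero")
                fold_fit.fit(X[train], Surv.from_arrays(e[train].astype(bool), t[train]))
        except (ValueError, ArithmeticError):
            return None
        coefs = np.asarray(fold_fit.coef_)  # (p, n_fit_alphas)
        fit_alphas = np.asarray(fold_fit.alphas_)
        lp = X[test] @ coefs
        ll = breslow_loglik(lp, t[test], e[test])
        # map back onto the requested alpha grid (coxnet may truncate it)
        idx = np.searchsorted(-alphas, -fit_alphas)
        cv_ll[idx] += ll
    best = int(np.argmax(cv_ll))
    return np.asarray(path.coef_)[:, best] != 0


def stability_select(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    B: int = 1000,
    k_folds: int = 10,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_alphas: int = 30,
    max_redraws: int = 50,
) -> SelectionFrequency:
    """Selection frequencies from B repetitions of cross-validated lasso-Cox.

    Each repetition subsamples ``subsample_frac`` of the samples without
    replacement, fits an L1-penalised Cox path with the penalty chosen by
    ``k_folds``-fold cross-validated Breslow partial likelihood, and records
    the nonzero-coefficient gene set. A repetition whose subsample or folds
    lack events is redrawn (logged). ``expr`` is gene x sample; ``surv`` has
    (time, event) indexed by sample.
    """
    genes = list(expr.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 candidate genes")
    samples = [s for s in expr.columns if s in surv.index]
    X_full = expr[samples].to_numpy(dtype=float).T
    t_full = surv.loc[samples, "time"].to_numpy(dtype=float)
    e_full = surv.loc[samples, "event"].to_numpy(dtype=int)
    if e_full.sum() < k_folds:
        raise ValueError("fewer events than folds")
    n = len(samples)
    m = max(k_folds, int(round(subsample_frac * n)))

    gene_counts = {g: 0 for g in genes}
    combo_counts: dict[tuple[str, ...], int] = {}
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        mask = None
        for attempt in range(max_redraws):
            idx = rng.choice(n, size=m, replace=False)
            if e_full[idx].sum() < k_folds:
                logger.info("repetition %d redrawn (too few events)", b)
                continue
            mask = _cv_lasso_selected(
                X_full[idx], t_full[idx], e_full[idx], k_folds, rng, n_alphas
            )
            if mask is not None:
                break
        if mask is None:
            logger.warning("repetition %d abandoned after %d redraws", b, max_redraws)
            mask = np.zeros(len(genes), dtype=bool)
        combo = tuple(g for g, keep in zip(genes, mask) if keep)
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
        for g in combo:
            gene_counts[g] += 1
    return SelectionFrequency(B=B, gene_counts=gene_counts, combination_counts=combo_counts)
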