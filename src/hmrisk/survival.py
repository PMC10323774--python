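"""Prognostic risk-score modelling over candidate driver genes.

The funnel: intersect differential-mark genes with DEGs and keep those
expressed in most tumor samples; screen each survivor with a univariate Cox
proportional-hazards fit; shrink the screened set with an L1-penalised Cox
path (penalty chosen by cross-validated partial likelihood); fit a joint
multivariate Cox model; and score each patient with the linear predictor
``RS = sum_j coef_j * x_j``. Patients are stratified at the median risk
score (ties to low) for Kaplan-Meier curves and a log-rank test, and the
score is evaluated with cumulative-case/dynamic-control time-dependent AUCs.

Ties in the Cox partial likelihood are handled with Efron's method
(lifelines' default). Expression enters the models untransformed by default;
z-scoring is available via ``standardize=True`` on the fitting helpers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoxResult:
    """One covariate's proportional-hazards estimate."""

    gene: str
    coef: float
    se_coef: float
    p: float

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))

    @property
    def z(self) -> float:
        return self.coef / self.se_coef


@dataclass
class RiskModel:
    """Ordered driver genes with multivariate Cox coefficients."""

    genes: list[str]
    coefs: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if not np.all(np.isfinite(self.coefs)) or np.any(self.coefs == 0):
            raise ValueError("risk-model coefficients must be finite and nonzero")

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Linear predictor per sample; ``expr`` is genes x samples."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise KeyError(f"model genes missing from expression: {missing}")
        return pd.Series(
            self.coefs @ expr.loc[self.genes].to_numpy(),
            index=expr.columns, name="risk_score",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "coef": self.coefs})


# ---------------------------------------------------------------------------
# Candidate funnel
# ---------------------------------------------------------------------------

def build_candidates(
    diff_genes: Sequence[str],
    degs: pd.DataFrame,
    cohort_expr: pd.DataFrame,
    tumor_samples: Sequence[str],
    expressed_frac: float = 0.9,
) -> list[str]:
    """Differential-mark DEGs expressed in more than ``expressed_frac`` of
    tumor samples (expressed = value > 0)."""
    from .diffexpr import deg_genes

    tumor_samples = [s for s in tumor_samples if s in cohort_expr.columns]
    if not tumor_samples:
        raise ValueError("cohort has no tumor samples")
    both = sorted(set(diff_genes) & set(deg_genes(degs)))
    if not both:
        raise ValueError("differential-mark genes and DEGs do not intersect")
    both = [g for g in both if g in cohort_expr.index]
    if not both:
        raise ValueError("no intersection gene is present in the cohort matrix")
    frac = (cohort_expr.loc[both, tumor_samples] > 0).mean(axis=1)
    return frac.index[frac > expressed_frac].tolist()


def _design(
    genes: Sequence[str],
    cohort_expr: pd.DataFrame,
    survival: pd.DataFrame,
    standardize: bool = False,
) -> pd.DataFrame:
    """samples x (genes + time + event) frame for Cox fitting."""
    samples = [s for s in survival.index if s in cohort_expr.columns]
    if not samples:
        raise ValueError("no overlap between survival table and expression columns")
    X = cohort_expr.loc[list(genes), samples].T.astype(float)
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0).replace(0, 1.0)
    df = X.copy()
    df["time"] = survival.loc[samples, "time"].to_numpy()
    df["event"] = survival.loc[samples, "event"].to_numpy()
    return df


def univariate_screen(
    candidates: Sequence[str],
    cohort_expr: pd.DataFrame,
    survival: pd.DataFrame,
    p_cut: float = 0.05,
    standardize: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fit per gene; keep genes with p < ``p_cut``.

    Returns (seed genes, results table for every converging gene). Genes
    whose fit fails to converge are dropped with a warning.
    """
    n_events = int(survival["event"].sum())
    if n_events < 10:
        logger.warning("only %d events in cohort; screening is underpowered", n_events)
    rows = []
    for gene in candidates:
        df = _design([gene], cohort_expr, survival, standardize)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("univariate Cox failed for %s: %s", gene, exc)
            continue
        s = cph.summary.loc[gene]
        rows.append({"gene": gene, "coef": s["coef"], "se_coef": s["se(coef)"],
                     "z": s["z"], "p": s["p"]})
    results = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["coef", "se_coef", "z", "p"])
    seeds = results.index[results["p"] < p_cut].tolist()
    return seeds, results


# ---------------------------------------------------------------------------
# LASSO (L1-penalised Cox path)
# ---------------------------------------------------------------------------

def _cox_log_partial_likelihood(lp: np.ndarray, time: np.ndarray,
                                event: np.ndarray) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp, time, event = lp[order], time[order], event[order]
    exp_lp = np.exp(lp - lp.max())
    cum = np.cumsum(exp_lp)
    # risk set for subject i: all with time >= time_i; with decreasing sort,
    # that is the prefix up to the last tied index
    ll = 0.0
    log_shift = lp.max()
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        risk = np.log(cum[j]) + log_shift
        for k in range(i, j + 1):
            if event[k]:
                ll += lp[k] - risk
        i = j + 1
    return ll


def lasso_select(
    seeds: Sequence[str],
    cohort_expr: pd.DataFrame,
    survival: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    standardize: bool = False,
) -> tuple[list[str], dict]:
    """Genes with nonzero coefficients on the L1 Cox path at the CV-chosen
    penalty.

    The penalty grid comes from the path fit on the full data; the chosen
    ``alpha`` minimises the cross-validated partial-likelihood deviance
    (fold deviance measured as the full-minus-train log partial likelihood
    of the fold-trained coefficients). Pass ``alpha`` to bypass CV: ``0``
    means no shrinkage (all seeds enter an unpenalised joint fit and any
    gene with a nonzero coefficient is kept), larger values force sparser
    sets; a penalty at which every coefficient vanishes raises an error.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need >= 2 seed genes for selection")
    df = _design(seeds, cohort_expr, survival, standardize)
    X = df[seeds].to_numpy()
    y = Surv.from_arrays(event=df["event"].astype(bool), time=df["time"])
    time = df["time"].to_numpy()
    event = df["event"].to_numpy().astype(bool)

    if alpha == 0:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        kept = [g for g in seeds if cph.params_[g] != 0]
        return kept, {"alpha": 0.0, "cv": None}

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    if alpha is None:
        rng = np.random.default_rng(seed)
        # stratified fold assignment on event status
        fold = np.empty(len(time), dtype=int)
        for grp in (np.where(event)[0], np.where(~event)[0]):
            perm = rng.permutation(grp)
            fold[perm] = np.arange(len(perm)) % n_folds
        deviance = np.zeros(len(alphas))
        for k in range(n_folds):
            train = fold != k
            if event[train].sum() == 0:
                continue
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                       fit_baseline_model=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X[train], y[train])
            for ai, a in enumerate(m.alphas_):
                lp_all = m.predict(X, alpha=a)
                pl_full = _cox_log_partial_likelihood(lp_all, time, event)
                pl_train = _cox_log_partial_likelihood(
                    lp_all[train], time[train], event[train])
                deviance[ai] += -2.0 * (pl_full - pl_train)
        best = int(np.argmin(deviance))
        alpha = float(alphas[best])
        cv_info = {"alphas": alphas.tolist(), "deviance": deviance.tolist()}
    else:
        cv_info = None

    coefs = path.coef_[:, np.argmin(np.abs(alphas - alpha))] if alpha in alphas else None
    if coefs is None:
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha],
                                   fit_baseline_model=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X, y)
            coefs = m.coef_[:, 0]
        except Exception:
            coefs = np.zeros(len(seeds))
    kept = [g for g, c in zip(seeds, coefs) if c != 0]
    if not kept:
        raise ValueError(
            f"all coefficients are zero at alpha={alpha:g}; review the penalty grid"
        )
    return kept, {"alpha": float(alpha), "cv": cv_info}


# ---------------------------------------------------------------------------
# Multivariate fit and risk scoring
# ---------------------------------------------------------------------------

def multivariate_fit(
    selected: Sequence[str],
    cohort_expr: pd.DataFrame,
    survival: pd.DataFrame,
    standardize: bool = False,
    drop_insignificant: float | None = None,
) -> tuple[RiskModel, pd.DataFrame]:
    """Joint Cox fit over the selected genes.

    Returns the :class:`RiskModel` plus a per-gene results table (coef,
    hazard_ratio, se_coef, z, p). ``drop_insignificant`` optionally refits
    after removing genes with p above the cutoff, mimicking a backward
    reduction from the LASSO set to a compact final model. A rank-deficient
    design raises an error naming the collinear genes.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("no genes selected for the multivariate fit")
    df = _design(selected, cohort_expr, survival, standardize)
    X = df[selected].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) <= len(selected):
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (selected[i], selected[j])
            for i in range(len(selected)) for j in range(i + 1, len(selected))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"singular design; collinear genes: {pairs or selected}")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")

    if drop_insignificant is not None:
        keep = cph.summary.index[cph.summary["p"] < drop_insignificant].tolist()
        if keep and len(keep) < len(selected):
            return multivariate_fit(keep, cohort_expr, survival, standardize, None)

    summary = cph.summary
    results = pd.DataFrame({
        "coef": summary["coef"],
        "hazard_ratio": np.exp(summary["coef"]),
        "se_coef": summary["se(coef)"],
        "z": summary["z"],
        "p": summary["p"],
    }).loc[selected]
    nonzero = results.index[results["coef"] != 0].tolist()
    model = RiskModel(
        genes=nonzero,
        coefs=results.loc[nonzero, "coef"].to_numpy(),
        provenance={"n_samples": len(df), "n_events": int(df["event"].sum())},
    )
    return model, results


def risk_score(model: RiskModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Risk score per sample with a median-split group label.

    Samples with RS strictly above the median are "high"; ties go to "low"
    so the split is deterministic.
    """
    rs = model.score(expr)
    median = rs.median()
    return pd.DataFrame({
        "risk_score": rs,
        "group": np.where(rs > median, "high", "low"),
    })


def km_curves(
    scores: pd.DataFrame,
    survival: pd.DataFrame,
) -> dict:
    """Kaplan-Meier curves per risk group and the two-sided log-rank test.

    Returns ``{"curves": {group: DataFrame}, "logrank_p": float,
    "reliable": bool}``; ``reliable`` is False when a group has no events.
    """
    samples = [s for s in scores.index if s in survival.index]
    merged = scores.loc[samples].join(survival.loc[samples])
    groups = merged["group"].unique()
    if len(groups) < 2:
        raise ValueError("both risk groups must be non-empty")
    curves = {}
    zero_event = False
    for grp, sub in merged.groupby("group"):
        if sub["event"].sum() == 0:
            zero_event = True
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(grp))
        curves[str(grp)] = kmf.survival_function_.rename(
            columns={str(grp): "survival"})
    hi = merged[merged["group"] == "high"]
    lo = merged[merged["group"] == "low"]
    res = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])
    if zero_event:
        logger.warning("a risk group has zero events; log-rank p is unreliable")
    return {"curves": curves, "logrank_p": float(res.p_value),
            "reliable": not zero_event}


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

def _censoring_survival(time: np.ndarray, event: np.ndarray):
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    return kmf


def _ipcw_auc(score: np.ndarray, time: np.ndarray, event: np.ndarray,
              horizon: float) -> float:
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() == 0:
        raise ValueError(f"no events by horizon {horizon}")
    if controls.sum() == 0:
        raise ValueError(f"no subjects at risk past horizon {horizon}")
    G = _censoring_survival(time, event)
    g_case = G.survival_function_at_times(time[cases] - 1e-9).to_numpy()
    w = 1.0 / np.clip(g_case, 1e-12, None)
    s_case, s_ctrl = score[cases], score[controls]
    # weighted fraction of (case, control) pairs ranked concordantly
    order = np.argsort(s_ctrl, kind="stable")
    s_ctrl_sorted = s_ctrl[order]
    n_less = np.searchsorted(s_ctrl_sorted, s_case, side="left")
    n_leq = np.searchsorted(s_ctrl_sorted, s_case, side="right")
    conc = n_less + 0.5 * (n_leq - n_less)
    return float((w * conc).sum() / (w.sum() * len(s_ctrl)))


def _nn_auc(score: np.ndarray, time: np.ndarray, event: np.ndarray,
            horizon: float, span: float | None = None) -> float:
    """Nearest-neighbour smoothed estimator (survivalROC-style NNE)."""
    n = len(score)
    if span is None:
        span = 0.25 * n ** (-0.20)
    half = max(int(np.ceil(span * n / 2)), 1)
    rank = np.argsort(np.argsort(score, kind="stable"), kind="stable")
    S_i = np.empty(n)
    for i in range(n):
        nb = np.abs(rank - rank[i]) <= half
        t_nb, e_nb = time[nb], event[nb]
        ev_times = np.unique(t_nb[(e_nb == 1) & (t_nb <= horizon)])
        s = 1.0
        for u in ev_times:
            at_risk = (t_nb >= u).sum()
            d = ((t_nb == u) & (e_nb == 1)).sum()
            if at_risk > 0:
                s *= 1.0 - d / at_risk
        S_i[i] = s
    F_i = 1.0 - S_i
    if F_i.sum() <= 0:
        raise ValueError(f"no events by horizon {horizon}")
    thresholds = np.unique(score)
    sens = [(F_i[score > c].sum()) / F_i.sum() for c in thresholds]
    spec = [(S_i[score <= c].sum()) / S_i.sum() for c in thresholds]
    x = np.concatenate([[1.0], 1.0 - np.asarray(spec), [0.0]])
    y = np.concatenate([[1.0], np.asarray(sens), [0.0]])
    order = np.argsort(x)
    return float(np.trapezoid(y[order], x[order]))


def time_dependent_roc(
    scores: pd.DataFrame | pd.Series,
    survival: pd.DataFrame,
    horizons: Sequence[float] = (3.0, 5.0),
    method: str = "ipcw",
) -> dict[float, float]:
    """Cumulative-case / dynamic-control AUC at each horizon (years).

    ``ipcw`` (default) weights cases by the inverse Kaplan-Meier censoring
    survival; ``nn`` is a nearest-neighbour smoothed alternative. Cases are
    subjects with an event by the horizon, controls those still at risk
    beyond it.
    """
    s = scores["risk_score"] if isinstance(scores, pd.DataFrame) else scores
    samples = [x for x in s.index if x in survival.index]
    score = s.loc[samples].to_numpy(dtype=float)
    time = survival.loc[samples, "time"].to_numpy(dtype=float)
    event = survival.loc[samples, "event"].to_numpy(dtype=int)
    out = {}
    for t in horizons:
        if t >= time.max():
            raise ValueError(f"horizon {t} is beyond observed follow-up")
        if method == "ipcw":
            out[float(t)] = _ipcw_auc(score, time, event, float(t))
        elif method == "nn":
            out[float(t)] = _nn_auc(score, time, event, float(t))
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
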