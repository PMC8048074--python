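"""Diagnostic evaluation of stool-based markers and marker panels.

Single continuous markers (qMSP copies/ul) are summarized by empirical ROC
curves, AUC with a DeLong 95% confidence interval, and a positivity cutoff
chosen to maximize the positive likelihood ratio LR+ = sens / (1 - spec).
Binary marker calls combine into OR-panels (positive if any member, or
optionally the FIT, is positive); every panel subset is enumerated and
ranked. A cutoff-free panel score is obtained from a maximum-likelihood
logistic combination of the continuous marker values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import StoolStudy

__all__ = [
    "RocResult",
    "CutoffResult",
    "PanelDefinition",
    "roc_auc",
    "max_lr_cutoff",
    "binomial_ci",
    "evaluate_binary_marker",
    "panel_status",
    "enumerate_panels",
    "continuous_panel_score",
    "FIT_POSITIVE_THRESHOLD",
]

#: quantitative FIT threshold for a positive test, ng Hb/ml
FIT_POSITIVE_THRESHOLD = 50.0


@dataclass
class RocResult:
    points: pd.DataFrame  # columns: fpr, tpr
    auc: float
    auc_ci: tuple[float, float]


@dataclass
class CutoffResult:
    marker: str
    cutoff: float
    sensitivity: float
    specificity: float
    lr_positive: float


@dataclass
class PanelDefinition:
    """An OR-rule panel: positive iff any member marker (or the FIT, when
    ``include_fit``) is positive."""

    members: frozenset[str]
    include_fit: bool = False

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members and not self.include_fit:
            raise ValueError("a panel without FIT must have >= 1 member")

    @property
    def name(self) -> str:
        parts = sorted(self.members)
        if self.include_fit:
            parts.append("FIT")
        return "/".join(parts)


def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    cases = s[y == 1]
    controls = s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return controls, cases


def _delong_variance(controls: np.ndarray, cases: np.ndarray) -> float:
    # placement values: V10[i] = P(case_i beats a random control), V01 analog
    m, n = cases.size, controls.size
    order = np.concatenate([cases, controls])
    v10 = np.empty(m)
    for i, x in enumerate(cases):
        v10[i] = ((x > controls).sum() + 0.5 * (x == controls).sum()) / n
    v01 = np.empty(n)
    for j, x in enumerate(controls):
        v01[j] = ((cases > x).sum() + 0.5 * (cases == x).sum()) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Empirical ROC curve and AUC with a nonparametric 95% CI.

    AUC is the concordance probability (ties count 1/2), identical to
    U / (n1 * n2) of the rank-sum statistic. The default CI is the DeLong
    normal-approximation interval, truncated to [0, 1]; a seeded bootstrap
    percentile interval is available via ``ci_method='bootstrap'``.
    """
    controls, cases = _split_scores(scores, labels)
    greater = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    auc = (greater + 0.5 * ties) / (cases.size * controls.size)

    thresholds = np.unique(np.concatenate([controls, cases]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        fpr = (controls >= t).mean()
        tpr = (cases >= t).mean()
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    points = pd.DataFrame(sorted(set(pts)), columns=["fpr", "tpr"])

    if ci_method == "delong":
        se = math.sqrt(_delong_variance(controls, cases))
        z = stats.norm.ppf(0.975)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            cs = rng.choice(cases, cases.size, replace=True)
            ct = rng.choice(controls, controls.size, replace=True)
            g = (cs[:, None] > ct[None, :]).sum()
            t = (cs[:, None] == ct[None, :]).sum()
            reps[b] = (g + 0.5 * t) / (cs.size * ct.size)
        ci = tuple(np.quantile(reps, [0.025, 0.975]))
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return RocResult(points=points, auc=float(auc), auc_ci=(float(ci[0]), float(ci[1])))


def max_lr_cutoff(scores, labels, marker: str = "") -> CutoffResult:
    """Choose the positivity cutoff maximizing the positive likelihood ratio.

    Candidate cutoffs are the unique observed values; a subject is positive
    when its value is strictly greater than the cutoff. LR+ is infinite when
    specificity is 1 and sensitivity > 0 (such cutoffs win outright). Ties
    are broken by higher sensitivity, then by lower cutoff.
    """
    controls, cases = _split_scores(scores, labels)
    best = None
    for cutoff in np.unique(np.concatenate([controls, cases])):
        sens = float((cases > cutoff).mean())
        spec = float((controls <= cutoff).mean())
        if spec == 1.0:
            lr = math.inf if sens > 0 else 0.0
        else:
            lr = sens / (1.0 - spec)
        key = (lr, sens, -cutoff)
        if best is None or key > best[0]:
            best = (key, CutoffResult(marker, float(cutoff), sens, spec, lr))
    return best[1]


def binomial_ci(
    successes: int, trials: int, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """Two-sided 95% binomial confidence interval.

    ``clopper_pearson``: exact interval from beta-distribution quantiles.
    ``wald``: normal approximation p +- z * sqrt(p(1-p)/n), truncated to
    [0, 1].
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    if method == "clopper_pearson":
        lo = 0.0 if successes == 0 else float(stats.beta.ppf(0.025, successes, trials - successes + 1))
        hi = 1.0 if successes == trials else float(stats.beta.ppf(0.975, successes + 1, trials - successes))
        return lo, hi
    if method == "wald":
        p = successes / trials
        z = stats.norm.ppf(0.975)
        half = z * math.sqrt(p * (1 - p) / trials)
        return max(0.0, p - half), min(1.0, p + half)
    raise ValueError("method must be 'clopper_pearson' or 'wald'")


def evaluate_binary_marker(
    statuses, labels, ci_method: str = "clopper_pearson"
) -> dict:
    """Sensitivity and specificity (with 95% CIs) of binary marker calls."""
    s = np.asarray(statuses, dtype=int)
    y = np.asarray(labels, dtype=int)
    cases = s[y == 1]
    controls = s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    tp = int(cases.sum())
    tn = int((controls == 0).sum())
    return {
        "sensitivity": tp / cases.size,
        "sensitivity_ci": binomial_ci(tp, cases.size, ci_method),
        "specificity": tn / controls.size,
        "specificity_ci": binomial_ci(tn, controls.size, ci_method),
        "n_cases": int(cases.size),
        "n_controls": int(controls.size),
        "ci_method": ci_method,
    }


def panel_status(
    statuses: dict[str, int | float],
    panel: PanelDefinition,
    fit_positive: bool | None = None,
) -> int:
    """OR-rule panel call for one subject; raises if a member call is
    missing (the subject is then excluded from that panel's evaluation)."""
    for m in panel.members:
        v = statuses.get(m)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise KeyError(f"missing status for panel member {m!r}")
        if v:
            return 1
    if panel.include_fit:
        if fit_positive is None:
            raise KeyError("panel includes FIT but no FIT status was given")
        if fit_positive:
            return 1
    return 0


def _binary_calls(study: StoolStudy, cutoffs: dict[str, CutoffResult]) -> pd.DataFrame:
    calls = {}
    for m, c in cutoffs.items():
        vals = study.marker_values(m)
        call = np.where(np.isnan(vals), np.nan, (vals > c.cutoff).astype(float))
        calls[m] = call
    return pd.DataFrame(calls, index=study.subjects.index)


def enumerate_panels(
    study: StoolStudy,
    cutoffs: dict[str, CutoffResult],
    fit_threshold: float = FIT_POSITIVE_THRESHOLD,
    ci_method: str = "clopper_pearson",
) -> pd.DataFrame:
    """Evaluate every non-empty marker subset with and without FIT, plus the
    FIT-only panel: (2^m - 1) * 2 + 1 panels in total.

    Panels are ranked by specificity (highest tier first), then sensitivity,
    then fewer markers, then name. Subjects missing any member value are
    excluded from that panel's evaluation.
    """
    if not cutoffs:
        raise ValueError("at least one marker cutoff is required")
    markers = sorted(cutoffs)
    calls = _binary_calls(study, cutoffs)
    fit_vals = study.subjects.get("fit_value")
    fit_pos = None
    if fit_vals is not None:
        fv = fit_vals.to_numpy(dtype=float)
        fit_pos = np.where(np.isnan(fv), np.nan, (fv >= fit_threshold).astype(float))
    labels = study.labels

    panels: list[PanelDefinition] = []
    for r in range(1, len(markers) + 1):
        for combo in itertools.combinations(markers, r):
            panels.append(PanelDefinition(frozenset(combo), include_fit=False))
            panels.append(PanelDefinition(frozenset(combo), include_fit=True))
    panels.append(PanelDefinition(frozenset(), include_fit=True))

    rows = []
    for panel in panels:
        cols = [calls[m].to_numpy() for m in sorted(panel.members)]
        parts = cols + ([fit_pos] if panel.include_fit else [])
        mat = np.column_stack(parts)
        ok = ~np.isnan(mat).any(axis=1)
        status = (mat[ok] > 0).any(axis=1).astype(int)
        y = labels[ok]
        if (y == 1).sum() == 0 or (y == 0).sum() == 0:
            continue
        res = evaluate_binary_marker(status, y, ci_method=ci_method)
        auc = roc_auc(status.astype(float), y).auc
        rows.append(
            {
                "panel": panel.name,
                "n_markers": len(panel.members),
                "includes_fit": panel.include_fit,
                "sensitivity": res["sensitivity"],
                "sensitivity_ci_low": res["sensitivity_ci"][0],
                "sensitivity_ci_high": res["sensitivity_ci"][1],
                "specificity": res["specificity"],
                "specificity_ci_low": res["specificity_ci"][0],
                "specificity_ci_high": res["specificity_ci"][1],
                "auc": auc,
                "n_evaluated": int(ok.sum()),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["specificity", "sensitivity", "n_markers", "panel"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)


class ConvergenceError(RuntimeError):
    """Raised when the logistic panel-score fit does not converge."""


def continuous_panel_score(values: pd.DataFrame, labels) -> tuple[np.ndarray, RocResult]:
    """Cutoff-free panel: maximum-likelihood logistic combination of
    continuous marker values, scored by its linear predictor, then ROC/AUC.

    Exactly duplicated marker columns are collapsed before fitting (they
    carry no extra information and make the likelihood unidentifiable).
    """
    import statsmodels.api as sm

    X = pd.DataFrame(values).astype(float)
    if X.shape[1] < 2:
        raise ValueError("a continuous panel needs >= 2 markers")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = X.T.drop_duplicates().T  # collapse identical marker columns
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation, singular Hessian, ...
        raise ConvergenceError(f"logistic panel score failed to converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic panel score failed to converge")
    score = design @ fit.params
    return score, roc_auc(score, y)
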