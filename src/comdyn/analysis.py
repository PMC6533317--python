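"""Behavioural read-outs: psychometric/chronometric fits, uncertainty
measures, change-of-mind statistics and the RT-uncertainty regression.

All functions consume either a :class:`~comdyn.simulate.TrialSet` or the
per-trial summary ``DataFrame`` it produces.  Indecision trials are excluded
from every behavioural quantity (they are retained in the raw tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.stats import linregress, pearsonr

from .simulate import TrialRecord, TrialSet

__all__ = [
    "PsychometricFit",
    "ComCurve",
    "weibull",
    "fit_weibull",
    "classify_change_of_mind",
    "uncertainty_measures",
    "normalize_feature",
    "chronometric_summary",
    "uncertainty_summary",
    "com_probability_curve",
    "rt_uncertainty_regression",
    "accuracy_by_uncertainty",
    "coupled_rt_summary",
]


def _frame(trials) -> pd.DataFrame:
    if isinstance(trials, TrialSet):
        return trials.to_frame()
    return trials


def _valid(df: pd.DataFrame) -> pd.DataFrame:
    return df[~df["indecision"]]


# ----------------------------------------------------------------------
# psychometric function
# ----------------------------------------------------------------------

def weibull(epsilon, alpha, beta):
    """p(correct) = 1 - 0.5 exp(-(eps/alpha)^beta)."""
    epsilon = np.asarray(epsilon, float)
    with np.errstate(divide="ignore"):
        z = np.where(epsilon > 0, (epsilon / alpha) ** beta, 0.0)
    return 1.0 - 0.5 * np.exp(-z)


@dataclass
class PsychometricFit:
    alpha: float  # threshold, % evidence quality
    beta: float  # slope
    epsilon: np.ndarray
    accuracy: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    method: str

    def predict(self, epsilon):
        return weibull(epsilon, self.alpha, self.beta)


def fit_weibull(trials, method: str = "mle") -> PsychometricFit:
    """Fit the Weibull psychometric function to per-condition accuracy.

    ``method='mle'`` maximises the binomial likelihood (robust when
    accuracies saturate); ``method='ls'`` performs least squares on the
    accuracy points.  The fitting method is recorded on the result.
    """
    df = _valid(_frame(trials))
    grp = df.groupby("epsilon")
    eps = np.array(sorted(grp.groups))
    if len(eps) < 3:
        raise ValueError("need at least 3 evidence-quality levels to fit")
    k = grp.apply(lambda g: int((g.final_choice == g.correct_side).sum()),
                  include_groups=False).reindex(eps).to_numpy()
    n = grp.size().reindex(eps).to_numpy()
    return fit_weibull_points(eps, k / n, n, method=method)


def fit_weibull_points(epsilon, accuracy, n, method: str = "mle") -> PsychometricFit:
    """Fit the Weibull to per-condition accuracy points directly.

    ``n`` gives the trial count behind each point (binomial weights for the
    ML fit and the SEM estimates).
    """
    eps = np.asarray(epsilon, float)
    acc = np.asarray(accuracy, float)
    n = np.asarray(n)
    if len(eps) < 3:
        raise ValueError("need at least 3 evidence-quality levels to fit")
    k = acc * n
    sem = np.sqrt(acc * (1 - acc) / n)

    if method == "ls":
        try:
            popt, _ = curve_fit(weibull, eps, acc, p0=[8.0, 1.3], maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(f"Weibull least-squares fit failed: {err}") from err
        alpha, beta = popt
    elif method == "mle":
        def nll(theta):
            a, b = np.exp(theta)
            p = np.clip(weibull(eps, a, b), 1e-9, 1 - 1e-9)
            return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

        res = minimize(nll, np.log([8.0, 1.3]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if not res.success:
            raise RuntimeError(f"Weibull ML fit did not converge: {res.message}")
        alpha, beta = np.exp(res.x)
    else:
        raise ValueError(f"unknown fitting method {method!r}")
    if alpha <= 0:
        raise RuntimeError("degenerate Weibull threshold")
    return PsychometricFit(float(alpha), float(beta), eps, acc, sem, n, method)


# ----------------------------------------------------------------------
# per-trial measures
# ----------------------------------------------------------------------

def classify_change_of_mind(record: TrialRecord,
                            deadband_frac: float = 0.05) -> tuple[bool, str]:
    """(com, direction) for one trial.

    A change-of-mind requires a sign reversal of the motor position x(t)
    after movement initiation and a choice target reached before timeout;
    direction is labelled by the final outcome.  Indecision trials are never
    changes-of-mind.  When a trace is present the reversal is re-derived from
    x(t) (movement onset = first nonzero motor activity; positions within
    ``deadband_frac`` of the target distance carry no sign); otherwise the
    simulator's online flags are used.
    """
    if record.rt != record.rt:  # nan: never decided
        return False, "none"
    if record.traces is not None:
        x = np.asarray(record.traces["x"])
        motor = np.asarray(record.traces["y_L"]) + np.asarray(record.traces["y_R"])
        on = np.nonzero(motor > 0)[0]
        if len(on) == 0:
            return False, "none"
        xm = x[on[0]:]
        deadband = deadband_frac * np.max(np.abs(x)) if np.any(x) else 0.0
        signs = np.sign(xm[np.abs(xm) >= max(deadband, 1e-12)])
        changed = bool(np.any(np.diff(signs) != 0))
        com = changed and record.final_choice != 0
    else:
        com = record.com
    if not com or record.final_choice == 0:
        return False, "none"
    if record.final_choice == record.correct_side:
        return True, "error-to-correct"
    return True, "correct-to-error"


def uncertainty_measures(record: TrialRecord) -> tuple[float, float]:
    """(peak, area) of the uncertainty-encoding activity for one trial.

    Peak is the maximum of y_U over the recorded window; area is its
    trapezoidal integral (nA*ms).  Uses the trace when present, else the
    online accumulators.
    """
    if record.traces is not None:
        y = record.traces["y_U"]
        t = record.traces["time"]
        return float(np.max(y)), float(np.trapezoid(y, t))
    return record.uncertainty_peak, record.uncertainty_area


def normalize_feature(values) -> np.ndarray:
    """Feature scaling X' = (X - min) / (max - min) onto [0, 1]."""
    values = np.asarray(values, float)
    vmin, vmax = np.min(values), np.max(values)
    if vmax == vmin:
        raise ValueError("cannot feature-scale values with zero range")
    return (values - vmin) / (vmax - vmin)


# ----------------------------------------------------------------------
# summaries over a trial set
# ----------------------------------------------------------------------

def chronometric_summary(trials) -> pd.DataFrame:
    """Mean RT +/- SEM keyed by (epsilon, outcome); indecisions excluded."""
    df = _valid(_frame(trials))
    df = df.assign(outcome=np.where(df.final_choice == df.correct_side, "correct", "error"))
    out = (
        df.groupby(["epsilon", "outcome"])["rt"]
        .agg(mean_rt="mean", sem_rt=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
             n="size")
        .reset_index()
    )
    return out


def uncertainty_summary(trials) -> pd.DataFrame:
    """Normalized uncertainty (peak and area) by condition and outcome.

    Feature scaling is applied across the whole trial set per measure, then
    averaged per (epsilon, outcome) cell; this is the '<' pattern table.
    """
    df = _valid(_frame(trials)).copy()
    df["norm_peak"] = normalize_feature(df["uncertainty_peak"].to_numpy())
    df["norm_area"] = normalize_feature(df["uncertainty_area"].to_numpy())
    df["outcome"] = np.where(df.final_choice == df.correct_side, "correct", "error")
    out = (
        df.groupby(["epsilon", "outcome"])[["norm_peak", "norm_area"]]
        .agg(["mean", "sem", "size"])
    )
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index().rename(columns={"norm_peak_size": "n"}).drop(columns=["norm_area_size"])


@dataclass
class ComCurve:
    epsilon: np.ndarray
    p_any: np.ndarray
    p_to_correct: np.ndarray
    p_to_error: np.ndarray
    se_any: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epsilon": self.epsilon,
            "p_com": self.p_any,
            "p_com_to_correct": self.p_to_correct,
            "p_com_to_error": self.p_to_error,
            "se_com": self.se_any,
            "n": self.n,
        })


def com_probability_curve(trials) -> ComCurve:
    """Per-condition change-of-mind probabilities (of all simulated trials).

    The denominator is all trials of the condition, matching the definition
    of dividing change-of-mind counts by the total simulated trials; the two
    directional curves partition the total exactly.
    """
    df = _frame(trials)
    grp = df.groupby("epsilon")
    eps = np.array(sorted(grp.groups))
    n = grp.size().reindex(eps).to_numpy()
    k_any = grp["com"].sum().reindex(eps).to_numpy()
    k_corr = grp.apply(lambda g: int((g.com & (g.final_choice == g.correct_side)).sum()),
                       include_groups=False).reindex(eps).to_numpy()
    k_err = k_any - k_corr
    p = k_any / n
    return ComCurve(eps, p, k_corr / n, k_err / n, np.sqrt(p * (1 - p) / n), n)


def rt_uncertainty_regression(trials, measure: str = "uncertainty_peak",
                              level: str = "trial") -> dict[str, float]:
    """OLS regression of response time on decision uncertainty.

    ``level='trial'`` pairs every non-indecision trial's RT with its
    uncertainty read-out (the trial-level Pearson correlation);
    ``level='condition'`` regresses per-condition mean RT on per-condition
    mean uncertainty (six points on the default grid, the conventional
    high-R^2 summary).  Returns slope, intercept, pearson_r and r_squared.
    """
    df = _valid(_frame(trials))
    if level == "condition":
        cell = df.groupby("epsilon").agg(rt=("rt", "mean"), u=(measure, "mean"))
        x, y = cell["u"].to_numpy(), cell["rt"].to_numpy()
    elif level == "trial":
        x, y = df[measure].to_numpy(), df["rt"].to_numpy()
    else:
        raise ValueError(f"unknown pairing level {level!r}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points for regression")
    fit = linregress(x, y)
    r = pearsonr(x, y)[0]
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r": float(r),
        "r_squared": float(fit.rvalue ** 2),
        "n": int(len(x)),
    }


def accuracy_by_uncertainty(trials, n_bins: int = 10,
                            measure: str = "uncertainty_peak") -> pd.DataFrame:
    """Accuracy in quantile bins of normalized decision uncertainty."""
    df = _valid(_frame(trials)).copy()
    df["u"] = normalize_feature(df[measure].to_numpy())
    df["correct"] = df.final_choice == df.correct_side
    df["bin"] = pd.qcut(df["u"].rank(method="first"), n_bins, labels=False)
    out = df.groupby("bin").agg(
        uncertainty=("u", "mean"), accuracy=("correct", "mean"), n=("correct", "size")
    ).reset_index(drop=True)
    return out


def coupled_rt_summary(paired_trials) -> pd.DataFrame:
    """Second-trial normalized mean RT by second-trial epsilon and
    first-trial outcome, for coupled-pair sets.

    Normalization is feature scaling over the table's condition means.
    """
    df = _frame(paired_trials)
    if "stage" not in df.columns:
        raise ValueError("expected a coupled-pair trial set with a 'stage' column")
    second = df[(df.stage == 2) & (~df.indecision) & df.rt.notna()]
    cell = (
        second.groupby(["epsilon", "first_correct"])["rt"]
        .agg(mean_rt="mean", sem_rt=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size")
        .reset_index()
    )
    cell["norm_rt"] = normalize_feature(cell["mean_rt"].to_numpy())
    return cell
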