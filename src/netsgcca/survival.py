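"""Survival utilities: null deviance residuals and concordance.

To make the canonical components survival-aware, the (right-censored)
outcome enters the model as a one-column pseudo-block of *null deviance
residuals* — deviance-transformed martingale residuals of a covariate-free
Cox model — during training only.  Prediction quality is measured with
Harrell's concordance index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import Block

__all__ = [
    "SurvivalData",
    "null_deviance_residuals",
    "residual_block",
    "concordance_index",
    "survival_evaluation",
    "read_survival",
]


@dataclass
class SurvivalData:
    """Right-censored survival outcome, aligned with block sample order.

    time : positive event/censoring times.  event : 1 = event observed,
    0 = censored.
    """

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if np.any(self.time <= 0):
            raise ValueError("times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.time)

    def subset(self, indices) -> "SurvivalData":
        idx = np.asarray(indices)
        sids = [self.sample_ids[i] for i in idx] if self.sample_ids else None
        return SurvivalData(self.time[idx], self.event[idx], sids)


def _nelson_aalen_at(surv: SurvivalData) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's own time.

    Tied events share the at-risk set at their common time (Breslow-style):
    Lambda(t) = sum_{t_i <= t} d_i / n_i.
    """
    times = surv.time
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    uniq = np.unique(t_sorted)
    n = surv.n
    cumhaz_at_uniq = np.empty(len(uniq))
    running = 0.0
    for i, t in enumerate(uniq):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (surv.event == 1)))
        running += d / at_risk
        cumhaz_at_uniq[i] = running
    idx = np.searchsorted(uniq, times)
    return cumhaz_at_uniq[idx]


def null_deviance_residuals(surv: SurvivalData) -> np.ndarray:
    """Deviance residuals of the null (covariate-free) Cox model.

    With Lambda the Nelson-Aalen cumulative hazard, the martingale residual
    is M_i = delta_i - Lambda(t_i) and the deviance residual

        d_i = sign(M_i) * sqrt(-2 [M_i + delta_i log(delta_i - M_i)]),

    with delta * log(.) = 0 for censored subjects.  Requires at least one
    event (otherwise the residual block would be identically zero).
    """
    if surv.event.sum() == 0:
        raise ValueError(
            "no events: the null cumulative hazard is zero and the residual "
            "block would be constant"
        )
    cumhaz = _nelson_aalen_at(surv)
    delta = surv.event.astype(float)
    m = delta - cumhaz
    inner = np.where(delta > 0, delta * np.log(np.maximum(delta - m, 1e-300)), 0.0)
    arg = np.maximum(-2.0 * (m + inner), 0.0)
    return np.sign(m) * np.sqrt(arg)


def residual_block(surv: SurvivalData, sample_ids: list[str],
                   name: str = "deviance_residuals") -> Block:
    """One-column training block carrying the null deviance residuals."""
    d = null_deviance_residuals(surv)
    return Block(name=name, matrix=d.reshape(-1, 1),
                 feature_names=["null_deviance_residual"],
                 sample_ids=list(sample_ids))


def concordance_index(risk: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's c-index of a risk score against right-censored survival.

    A pair (i, j) is comparable iff t_i < t_j and subject i had the event;
    it is concordant when the earlier failure carries the higher risk; tied
    risks count 1/2.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    if len(risk) != surv.n:
        raise ValueError("risk and survival lengths differ")
    t, e = surv.time, surv.event
    conc = 0.0
    n_comp = 0
    for i in np.flatnonzero(e == 1):
        later = t > t[i]
        n_comp += int(later.sum())
        conc += np.sum(risk[i] > risk[later]) + 0.5 * np.sum(risk[i] == risk[later])
    if n_comp == 0:
        raise ValueError("no comparable pairs (need an event before another time)")
    return float(conc / n_comp)


def survival_evaluation(train_components: np.ndarray,
                        test_components: np.ndarray,
                        surv_train: SurvivalData,
                        surv_test: SurvivalData,
                        penalizer: float = 0.0) -> dict:
    """Cox model on training components; c-index on train and test.

    Fitting is delegated to lifelines' proportional-hazards implementation;
    the risk score is the linear predictor.  Rank-deficient component
    matrices (e.g. duplicated columns) are surfaced as an error carrying the
    condition number — add a small ``penalizer`` to proceed regardless.
    """
    from lifelines import CoxPHFitter

    Xtr = np.atleast_2d(np.asarray(train_components, dtype=float))
    Xte = np.atleast_2d(np.asarray(test_components, dtype=float))
    if Xtr.ndim == 2 and Xtr.shape[0] == 1 and surv_train.n > 1:
        Xtr = Xtr.T
    if Xte.ndim == 2 and Xte.shape[0] == 1 and surv_test.n > 1:
        Xte = Xte.T
    cols = [f"c{k}" for k in range(Xtr.shape[1])]
    df = pd.DataFrame(Xtr, columns=cols)
    df["time"] = surv_train.time
    df["event"] = surv_train.event
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        cond = np.linalg.cond(Xtr)
        raise RuntimeError(
            f"Cox fit failed (component matrix condition number {cond:.3g}); "
            "consider a penalizer or dropping collinear components"
        ) from exc
    beta = cph.params_.to_numpy()
    risk_train = Xtr @ beta
    risk_test = Xte @ beta
    return {
        "c_index_train": concordance_index(risk_train, surv_train),
        "c_index_test": concordance_index(risk_test, surv_test),
        "coefficients": dict(zip(cols, beta.tolist())),
    }


def read_survival(path, delimiter: str | None = None) -> SurvivalData:
    """Read survival TSV/CSV with columns sample_id, time, event."""
    path = str(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return SurvivalData(
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        sample_ids=[str(s) for s in df["sample_id"]],
    )
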