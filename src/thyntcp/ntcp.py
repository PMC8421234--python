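"""The logistic NTCP model of radiotherapy-induced hypothyroidism.

The complication probability one year after intensity-modulated
radiotherapy is modelled as a logistic ("mixture model") function of the
mean thyroid EQD2 dose and the thyroid volume:

    S    = b0 + b_dmean * Dmean + b_volume * V
    NTCP = 1 / (1 + exp(-S))

with published coefficients b0 = -1.385, b_dmean = 0.093 per Gy (odds
ratio 1.098/Gy) and b_volume = -0.188 per cc (odds ratio 0.829/cc): risk
rises with mean dose and falls with gland volume. Tolerance doses TDx/1
(the mean dose giving x% complication probability at one year, for a given
volume) follow in closed form by inverting the logistic:

    TDx/1 = (logit(x) - b0 - b_volume * V) / b_dmean

Model calibration is assessed with the Hosmer-Lemeshow deciles-of-risk
chi-square test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .logistic import LogisticResults

__all__ = [
    "NTCPModel",
    "CalibrationResult",
    "odds_ratio",
    "hosmer_lemeshow",
    "plot_ntcp_curves",
]

#: Cohort ranges the published model was fitted on (Gy, cc); evaluation
#: outside them is extrapolation and emits a warning.
FITTED_DMEAN_RANGE = (10.31, 51.46)
FITTED_VOLUME_RANGE = (8.19, 42.00)


def _validate(dmean, volume):
    dmean = np.asarray(dmean, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if np.any(~np.isfinite(dmean)) or np.any(dmean < 0):
        raise ValueError("dmean must be finite and >= 0")
    if np.any(~np.isfinite(volume)) or np.any(volume < 0):
        raise ValueError("volume must be finite and >= 0")
    if np.any(dmean < FITTED_DMEAN_RANGE[0]) or np.any(dmean > FITTED_DMEAN_RANGE[1]) \
            or np.any(volume < FITTED_VOLUME_RANGE[0]) or np.any(volume > FITTED_VOLUME_RANGE[1]):
        warnings.warn(
            "evaluating NTCP model outside the fitted dose/volume range "
            "(extrapolation)", stacklevel=3)
    return dmean, volume


@dataclass(frozen=True)
class NTCPModel:
    """Two-covariate logistic NTCP model (intercept, per-Gy, per-cc log-odds)."""

    b0: float = -1.385
    b_dmean: float = 0.093
    b_volume: float = -0.188
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name in ("b0", "b_dmean", "b_volume"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def published(cls) -> "NTCPModel":
        """The published hypothyroidism model (Dmean in Gy EQD2, volume in cc)."""
        return cls(metadata={"alpha_beta": 3.0, "endpoint": "hypothyroidism_12m",
                             "units": {"dmean": "Gy (EQD2)", "volume": "cc"}})

    @classmethod
    def from_results(cls, results: LogisticResults,
                     dmean_name: str = "dmean_gy",
                     volume_name: str = "volume_cc") -> "NTCPModel":
        """Extract the NTCP equation from a fitted logistic results object."""
        names = results.exog_names
        for n in ("intercept", dmean_name, volume_name):
            if n not in names:
                raise ValueError(f"fitted model lacks term '{n}' (has {names})")
        p = dict(zip(names, results.params))
        return cls(b0=p["intercept"], b_dmean=p[dmean_name], b_volume=p[volume_name])

    # -- evaluation ---------------------------------------------------------

    def linear_predictor(self, dmean, volume):
        """Log-odds S = b0 + b_dmean*Dmean + b_volume*volume."""
        dmean, volume = _validate(dmean, volume)
        out = self.b0 + self.b_dmean * dmean + self.b_volume * volume
        return float(out) if np.ndim(out) == 0 else out

    def ntcp(self, dmean, volume):
        """Complication probability 1/(1 + exp(-S))."""
        out = expit(self.linear_predictor(dmean, volume))
        return float(out) if np.ndim(out) == 0 else out

    predict = ntcp

    def tolerance_dose(self, volume: float, p: float) -> float:
        """Mean dose (Gy) at which the complication probability equals ``p``.

        Closed-form inversion of the logistic; a negative result means the
        model extrapolates below zero dose for that volume (warned, returned).
        """
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")
        if self.b_dmean == 0:
            raise ZeroDivisionError("tolerance dose undefined: zero dose coefficient")
        td = (logit(p) - self.b0 - self.b_volume * volume) / self.b_dmean
        if td < 0:
            warnings.warn(f"tolerance dose {td:.2f} Gy < 0: model extrapolation")
        return float(td)

    def curve(self, volume: float, dose_range: tuple[float, float] = (0.0, 70.0),
              step: float = 0.5) -> pd.DataFrame:
        """NTCP as a function of mean dose at fixed volume (columns dose_gy, ntcp)."""
        lo, hi = dose_range
        if not (lo < hi) or step <= 0:
            raise ValueError("need dose_range lo < hi and step > 0")
        doses = np.arange(lo, hi + step / 2.0, step)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # curves deliberately span wide ranges
            probs = self.ntcp(doses, np.full_like(doses, volume))
        return pd.DataFrame({"dose_gy": doses, "ntcp": probs})

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"b0": self.b0, "b_dmean": self.b_dmean, "b_volume": self.b_volume,
             "metadata": self.metadata}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NTCPModel":
        d = json.loads(Path(path).read_text())
        return cls(b0=d["b0"], b_dmean=d["b_dmean"], b_volume=d["b_volume"],
                   metadata=d.get("metadata", {}))


def odds_ratio(coefficient: float, standard_error: float | None = None):
    """Per-unit odds ratio exp(b); with an SE, also the 95% Wald CI.

    Returns ``OR`` or ``(OR, (ci_low, ci_high))``.
    """
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    or_ = float(np.exp(coefficient))
    if standard_error is None:
        return or_
    if not np.isfinite(standard_error) or standard_error <= 0:
        raise ValueError("standard_error must be finite and > 0")
    z = stats.norm.ppf(0.975)
    return or_, (float(np.exp(coefficient - z * standard_error)),
                 float(np.exp(coefficient + z * standard_error)))


@dataclass
class CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit summary."""

    chi_square: float
    df: int
    p_value: float
    table: pd.DataFrame
    n_groups: int

    def __str__(self) -> str:
        return (f"Hosmer-Lemeshow: chi2 = {self.chi_square:.3f}, "
                f"df = {self.df}, p = {self.p_value:.3f}")


def hosmer_lemeshow(predicted, observed, n_groups: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow deciles-of-risk calibration test.

    Observations are split into ``n_groups`` equal-count groups by predicted
    probability (ties kept together; fewer distinct values reduce the group
    count with a warning). Per group, with O observed events, n members and
    mean predicted risk pbar (E = n*pbar):

        chi2 = sum (O - E)^2 / (E * (1 - E/n)),   df = n_groups - 2.

    The df correction assumes the predictions come from a model fitted to
    the same data.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predictions must lie strictly in (0, 1)")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("observed must be binary 0/1")
    if n_groups < 3:
        raise ValueError("need at least 3 groups")

    groups = pd.qcut(p, n_groups, labels=False, duplicates="drop")
    groups = np.unique(groups, return_inverse=True)[1]  # consecutive non-empty codes
    g_used = int(groups.max()) + 1
    if g_used < n_groups:
        warnings.warn(
            f"only {g_used} distinct risk groups available; reduced from {n_groups}")
    if g_used < 3:
        raise ValueError("fewer than 3 distinct risk groups: test undefined")

    df_tab = pd.DataFrame({"group": groups, "p": p, "y": y}).groupby("group").agg(
        n=("y", "size"), observed=("y", "sum"), mean_risk=("p", "mean"))
    df_tab["expected"] = df_tab["n"] * df_tab["mean_risk"]
    num = (df_tab["observed"] - df_tab["expected"]) ** 2
    den = df_tab["expected"] * (1.0 - df_tab["expected"] / df_tab["n"])
    chi2 = float((num / den).sum())
    dof = g_used - 2
    return CalibrationResult(
        chi_square=chi2,
        df=dof,
        p_value=float(stats.chi2.sf(chi2, dof)),
        table=df_tab.reset_index(),
        n_groups=g_used,
    )


def plot_ntcp_curves(model: NTCPModel, volumes=(10.0, 15.0, 20.0, 25.0),
                     dose_range=(0.0, 70.0), step: float = 0.5, ax=None):
    """Plot NTCP-vs-mean-dose curves for several thyroid volumes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for v in volumes:
        c = model.curve(v, dose_range, step)
        ax.plot(c["dose_gy"], c["ntcp"], label=f"{v:g} cc")
    ax.set_xlabel("Mean thyroid dose, EQD2 (Gy)")
    ax.set_ylabel("NTCP (12-month hypothyroidism)")
    ax.set_ylim(0, 1)
    ax.legend(title="Thyroid volume")
    return ax
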