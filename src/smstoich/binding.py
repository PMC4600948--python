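"""Equilibrium DNA-binding fits and the activity-dependent elution statistic.

DNA binding of surface-immobilized complexes is measured as labeled-DNA spot
counts across a concentration titration and fit with a one-site hyperbolic
isotherm, count = A * c / (Kd + c), by weighted least squares (weights from
per-field SEM).  The activity-dependent elution statistic is the excess
fraction of complexes released by dNTP-supported synthesis over buffer-only
release at matched timepoints:

    specific(t) = f_buffer(t) - f_dNTP(t)

where f is the remaining-spot fraction normalized to t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stoichiometry import bootstrap_interval

__all__ = ["BindingFit", "fit_kd", "saturation_check", "specific_elution"]


@dataclass(frozen=True)
class BindingFit:
    """One-site isotherm fit result."""

    kd_nM: float
    amplitude: float
    kd_se: float
    amplitude_se: float
    n_concentrations: int
    saturating: bool  # False when the titration does not constrain Kd

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("Kd must be > 0")


def _one_site(c: np.ndarray, amplitude: float, kd: float) -> np.ndarray:
    return amplitude * c / (kd + c)


def fit_kd(
    titration: pd.DataFrame,
    normalize_to_nM: float | None = None,
) -> BindingFit:
    """Fit Kd from a spot-count titration table.

    ``titration`` has columns concentration_nM, field_id, spot_count.  Means
    per concentration are fit to A * c / (Kd + c); per-field SEMs weight the
    fit where replicate fields exist.  ``normalize_to_nM`` divides counts by
    the mean at that anchor concentration first (the relative-units
    reporting convention); the fit itself is invariant to this overall
    scale.  Non-saturating data — fitted Kd far above the top concentration
    or with SE exceeding the estimate — are flagged.
    """
    g = titration.groupby("concentration_nM")["spot_count"]
    mean = g.mean()
    sem = g.sem().fillna(0.0)
    conc = mean.index.to_numpy(dtype=float)
    if conc.size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    y = mean.to_numpy(dtype=float)
    yerr = sem.to_numpy(dtype=float)
    if normalize_to_nM is not None:
        if normalize_to_nM not in mean.index:
            raise ValueError(f"anchor concentration {normalize_to_nM} nM not measured")
        scale = mean.loc[normalize_to_nM]
        if scale <= 0:
            raise ValueError("zero count at the normalization anchor")
        y = y / scale
        yerr = yerr / scale

    # flat data: Kd unidentifiable
    if y.max() > 0 and (y.max() - y.min()) < 0.05 * y.max():
        return BindingFit(
            kd_nM=float(conc.max()),
            amplitude=float(y.max()),
            kd_se=float("inf"),
            amplitude_se=float("inf"),
            n_concentrations=conc.size,
            saturating=False,
        )

    sigma = np.where(yerr > 0, yerr, max(1e-6, 1e-3 * max(y.max(), 1.0)))
    half = y.max() / 2.0
    kd0 = float(conc[np.argmin(np.abs(y - half))])
    popt, pcov = curve_fit(
        _one_site,
        conc,
        y,
        p0=(float(y.max()), max(kd0, conc.min())),
        sigma=sigma,
        absolute_sigma=False,
        bounds=((0.0, 1e-6), (np.inf, np.inf)),
        maxfev=10_000,
    )
    amp, kd = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    saturating = bool(kd < 3.0 * conc.max() and np.isfinite(perr[1]) and perr[1] < kd)
    return BindingFit(
        kd_nM=kd,
        amplitude=amp,
        kd_se=float(perr[1]),
        amplitude_se=float(perr[0]),
        n_concentrations=conc.size,
        saturating=saturating,
    )


def saturation_check(
    count_30nM: float,
    count_100nM: float,
    kd_nM: float | None = None,
    excess_factor: float = 2.0,
) -> dict:
    """Compare observed vs one-site-predicted fold increase from 30 to 100 nM.

    A fold increase more than ``excess_factor`` times the one-site
    prediction (computed at ``kd_nM`` when given, else at the prediction's
    upper limit Kd -> infinity, fold 10/3) flags a low-affinity secondary
    binding population.
    """
    if count_30nM <= 0:
        raise ValueError("zero count at 30 nM")
    observed = count_100nM / count_30nM
    if kd_nM is not None:
        predicted = (100.0 / (kd_nM + 100.0)) / (30.0 / (kd_nM + 30.0))
    else:
        predicted = 10.0 / 3.0  # weak-binding limit of the one-site ratio
    return {
        "fold_observed": observed,
        "fold_predicted": predicted,
        "secondary_population": observed > excess_factor * predicted,
    }


def specific_elution(
    dntp: pd.DataFrame,
    buffer: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-timepoint specific (dNTP-dependent) elution fraction.

    Inputs are (time_min, field_id, spot_count) tables for the two
    conditions sharing identical timepoints.  Counts are normalized within
    each condition to the t = 0 total; specific elution at each later
    timepoint is f_buffer(t) - f_dNTP(t) with a field-resampling bootstrap
    interval.  The statistic is scale-invariant: multiplying all counts in a
    condition by a constant leaves it unchanged.
    """
    t_d = sorted(dntp["time_min"].unique())
    t_b = sorted(buffer["time_min"].unique())
    if t_d != t_b:
        raise ValueError(f"mismatched timepoints: {t_d} vs {t_b}")
    if 0.0 not in t_d:
        raise ValueError("time courses must include t = 0 for normalization")

    def remaining(df: pd.DataFrame, t: float) -> float:
        total0 = df.loc[df["time_min"] == 0.0, "spot_count"].sum()
        if total0 == 0:
            raise ValueError("zero spot count at t = 0")
        return df.loc[df["time_min"] == t, "spot_count"].sum() / total0

    rows = []
    for t in t_d:
        f_d = remaining(dntp, t)
        f_b = remaining(buffer, t)
        spec = f_b - f_d
        lo = hi = float("nan")
        if t > 0:
            fields = sorted(
                set(dntp["field_id"]).intersection(buffer["field_id"])
            )
            if len(fields) >= 2:
                def per_field_tuple(fid):
                    d = dntp[dntp["field_id"] == fid]
                    b = buffer[buffer["field_id"] == fid]
                    return (
                        d.loc[d["time_min"] == 0.0, "spot_count"].sum(),
                        d.loc[d["time_min"] == t, "spot_count"].sum(),
                        b.loc[b["time_min"] == 0.0, "spot_count"].sum(),
                        b.loc[b["time_min"] == t, "spot_count"].sum(),
                    )

                tuples = [per_field_tuple(f) for f in fields]

                def estimator(sample: list[tuple]) -> float:
                    d0 = sum(s[0] for s in sample)
                    dt = sum(s[1] for s in sample)
                    b0 = sum(s[2] for s in sample)
                    bt = sum(s[3] for s in sample)
                    if d0 == 0 or b0 == 0:
                        raise ValueError("empty resample")
                    return bt / b0 - dt / d0

                lo, hi = bootstrap_interval(tuples, estimator, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "time_min": t,
                "f_dNTP": f_d,
                "f_buffer": f_b,
                "specific_elution": spec,
                "interval_low": lo,
                "interval_high": hi,
            }
        )
    return pd.DataFrame(rows)
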