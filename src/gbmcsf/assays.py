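"""Plate-based cytotoxicity analysis and qPCR quantitation.

* :func:`viability` — per-well survival as a percentage of the mean nuclei
  count of the paired vehicle-control wells of the same line/condition.
* :func:`stratify` — responsiveness groups from configured survival
  cutpoints.  Presets follow the two published conventions:
  (50, 90) for drug assays (responsive <50%, moderate 50-90%,
  unresponsive >90%) and (50, 75) for irradiation and combination
  treatment.  Boundary values fall in the lower-resistance class
  ("<50" strict, the middle interval closed at both ends).
* :func:`resistance_fold_change` — per-line CSF/GM survival ratio after
  normalizing both conditions to the mean population survival in GM.
* :func:`fit_4pl` — least-squares fit of the four-parameter logistic
  viability curve with an honest convergence/reliability flag.
* :func:`ddct` — comparative-CT relative quantitation (fold = 2^-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import four_pl

__all__ = [
    "viability",
    "stratify",
    "resistance_fold_change",
    "DoseResponseFit",
    "fit_4pl",
    "ddct",
]

GROUP_LABELS = ("responsive", "moderate", "unresponsive")

#: default cutpoints per treatment family (percent survival)
DEFAULT_CUTPOINTS = {
    "TMZ": (50.0, 90.0),
    "TFP": (50.0, 90.0),
    "irradiation": (50.0, 75.0),
    "combination": (50.0, 75.0),
}


def viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well viability: ``100 * count / mean(paired control counts)``.

    Control wells are rows with ``treatment == "vehicle"``; by construction
    their per-group viability averages exactly 100%.  A zero control mean
    is an error naming the group.
    """
    out = plate.copy()
    ctrl_means = (
        plate[plate["treatment"] == "vehicle"]
        .groupby("control_group", observed=True)["nuclei_count"]
        .mean()
    )
    missing = set(plate["control_group"]) - set(ctrl_means.index)
    if missing:
        raise ValueError(f"control groups without any control well: {sorted(missing)}")
    zero = ctrl_means[ctrl_means == 0]
    if len(zero):
        raise ValueError(f"zero control mean for groups: {zero.index.tolist()}")
    out["viability"] = 100.0 * out["nuclei_count"] / out["control_group"].map(ctrl_means)
    return out


def mean_viability(vr: pd.DataFrame, treated_only: bool = True) -> pd.DataFrame:
    """Mean viability and SEM per line x condition (treated wells)."""
    sub = vr[vr["treatment"] != "vehicle"] if treated_only else vr
    g = sub.groupby(["line", "condition"], observed=True)["viability"]
    return g.agg(mean_viability="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))).reset_index()


def stratify(
    means: pd.DataFrame, cutpoints: tuple[float, float] = (50.0, 90.0)
) -> pd.DataFrame:
    """Assign responsiveness groups from mean survival percentages.

    ``responsive``: survival < low cut; ``moderate``: low <= survival <=
    high (interval closed at both ends); ``unresponsive``: survival > high.
    Every line gets exactly one label.
    """
    low, high = cutpoints
    if not low < high:
        raise ValueError("cutpoints must be strictly increasing")
    out = means.copy()
    v = out["mean_viability"].to_numpy(float)
    label = np.where(v < low, "responsive", np.where(v <= high, "moderate", "unresponsive"))
    out["group"] = label
    return out


def resistance_fold_change(vr_gm: pd.DataFrame, vr_csf: pd.DataFrame) -> pd.DataFrame:
    """Per-line fold change of CSF over GM survival.

    Both conditions are first normalized to the mean population survival in
    GM (the published display convention); the fold change per line is the
    ratio of the two normalized survivals, identical to viability(CSF) /
    viability(GM) per line.
    """
    gm = mean_viability(vr_gm).set_index("line")["mean_viability"]
    csf = mean_viability(vr_csf).set_index("line")["mean_viability"]
    lines = gm.index.intersection(csf.index)
    if len(lines) == 0:
        raise ValueError("no common lines between conditions")
    pop_gm = float(gm.loc[lines].mean())
    if pop_gm == 0 or (gm.loc[lines] == 0).any():
        raise ValueError("zero GM survival")
    norm_gm = gm.loc[lines] / pop_gm
    norm_csf = csf.loc[lines] / pop_gm
    return pd.DataFrame(
        {
            "norm_gm": norm_gm,
            "norm_csf": norm_csf,
            "fold_change": norm_csf / norm_gm,
        }
    )


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    reliable: bool
    message: str = ""


def fit_4pl(doses, viabilities) -> DoseResponseFit:
    """Least-squares fit of ``v(d) = bottom + (top-bottom)/(1+(d/IC50)^hill)``.

    Initialization: top/bottom from the extreme-dose means, IC50 from the
    log-dose midpoint crossing, hill = 1; the only hard bound is IC50 > 0.
    Non-convergence or a fit implying viability that rises with dose
    (hill <= 0 or top < bottom) is returned flagged, never raised.
    """
    d = np.asarray(doses, float)
    v = np.asarray(viabilities, float)
    if len(np.unique(d)) < 4:
        raise ValueError("need at least 4 distinct doses")
    order = np.argsort(d)
    d, v = d[order], v[order]
    top0 = float(v[d == d.min()].mean())
    bot0 = float(v[d == d.max()].mean())
    pos = np.unique(d[d > 0])
    mid = (v.max() + v.min()) / 2.0
    # first dose whose mean response crosses the midpoint
    ic0 = float(np.sqrt(pos[0] * pos[-1]))
    for dd in pos:
        if v[d == dd].mean() <= mid:
            ic0 = float(dd)
            break
    p0 = [max(top0, bot0 + 1e-6), min(bot0, top0), max(ic0, 1e-6), 1.0]
    try:
        popt, _ = curve_fit(
            lambda dd, top, bottom, ic50, hill: four_pl(dd, top, bottom, ic50, hill),
            d,
            v,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
        top, bottom, ic50, hill = (float(x) for x in popt)
        converged = True
        message = "ok"
    except RuntimeError as err:  # no convergence
        top, bottom, ic50, hill = p0
        converged = False
        message = str(err)
    resid = v - four_pl(d, top, bottom, ic50, hill)
    rss = float((resid**2).sum())
    reliable = bool(
        converged
        and hill > 0
        and top > bottom
        and pos[0] / 10.0 <= ic50 <= pos[-1] * 10.0
    )
    if converged and not reliable:
        message = "fit implies non-decreasing or out-of-range dose response"
    return DoseResponseFit(
        top=top, bottom=bottom, ic50=ic50, hill=hill,
        rss=rss, converged=converged, reliable=reliable, message=message,
    )


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    group: str,
    control_group: str,
) -> float:
    """Comparative-CT fold change of ``target`` (normalized to the
    ``reference`` gene) in ``group`` relative to ``control_group``.

    ``ct`` is a long table with columns ``sample``, ``group``, ``gene``,
    ``ct``.  Per sample, dCt = Ct_target - Ct_reference; ddCt is the
    difference of group means; fold = 2^-ddCt.
    """
    for gene in (target, reference):
        if gene not in set(ct["gene"]):
            raise ValueError(f"gene {gene!r} missing from CT table")
    wide = ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    if wide[[target, reference]].isna().any().any():
        raise ValueError("missing CT values for target or reference gene")
    if not np.isfinite(wide[[target, reference]].to_numpy()).all():
        raise ValueError("CT values must be finite")
    dct = wide[target] - wide[reference]
    means = dct.groupby(level="group", observed=True).mean()
    for g in (group, control_group):
        if g not in means.index:
            raise ValueError(f"group {g!r} missing from CT table")
    ddct_val = float(means.loc[group] - means.loc[control_group])
    return float(2.0 ** (-ddct_val))
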