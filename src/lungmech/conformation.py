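"""Acinar conformation analysis: the S = kV^n power law.

The way peripheral-airspace surface area S scales with volume V over a
breath discriminates between modes of acinar expansion:

* n = 2/3 — isotropic, balloon-like inflation (surface grows as the square,
  volume as the cube of a linear dimension);
* n < 2/3 — predominantly ductal (axial) expansion;
* 2/3 < n < 1 — predominantly alveolar expansion / septal unpleating;
* n ≈ 1 — sequential recruitment–derecruitment of identical units.

The exponent is obtained by ordinary least squares of log S on log V over
all phases of the breath (inflation and deflation limbs pooled; a flag
allows limb-separate fits for hysteresis exploration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: reference exponents of the limiting conformational regimes
N_ISOTROPIC = 2.0 / 3.0
N_RECRUITMENT = 1.0


@dataclass
class ConformationFit:
    """Power-law fit S = k V^n and its regime label."""

    n: float
    k: float
    r_squared: float
    n_points: int
    regime: str = ""


def fit_svn(
    V_series: np.ndarray,
    S_series: np.ndarray,
    split_limbs: bool = False,
) -> ConformationFit | tuple[ConformationFit, ConformationFit]:
    """Fit S = kV^n by log–log linear regression.

    With ``split_limbs`` the series is cut at the volume peak and the
    inflation and deflation limbs are fitted separately (non-default;
    the standard fit pools both limbs of the breath).
    """
    V = np.asarray(V_series, dtype=float)
    S = np.asarray(S_series, dtype=float)
    if V.shape != S.shape or V.ndim != 1:
        raise ValueError("V and S must be 1-D series of equal length")
    if V.size < 3:
        raise ValueError("need at least 3 points to fit S = kV^n")
    if np.any(V <= 0) or np.any(S <= 0):
        raise ValueError("V and S must be strictly positive")
    if split_limbs:
        peak = int(np.argmax(V))
        return (fit_svn(V[: peak + 1], S[: peak + 1]),
                fit_svn(V[peak:], S[peak:]))
    lv, ls = np.log(V), np.log(S)
    if np.ptp(lv) == 0:
        raise ValueError("zero variance in log V: exponent undefined")
    slope, intercept = np.polyfit(lv, ls, 1)
    pred = slope * lv + intercept
    ss_res = float(np.sum((ls - pred) ** 2))
    ss_tot = float(np.sum((ls - ls.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = ConformationFit(float(slope), float(np.exp(intercept)), r2, V.size)
    fit.regime = classify_regime(fit)
    return fit


def classify_regime(fit: ConformationFit | float, tol: float = 0.03) -> str:
    """Label the conformational regime of an exponent.

    ``tol`` is the half-width of the bands around the reference exponents
    2/3 (isotropic) and 1 (recruitment-like); the default matches the
    inter-ROI spread reported for healthy rats.
    """
    n = fit.n if isinstance(fit, ConformationFit) else float(fit)
    if n >= N_RECRUITMENT - tol:
        return "recruitment_like"
    if abs(n - N_ISOTROPIC) <= tol:
        return "isotropic"
    if n < N_ISOTROPIC:
        return "ductal_dominant"
    return "alveolar_dominant"


def summarize_rois(fits: dict[str, ConformationFit] | list[ConformationFit]) -> pd.DataFrame:
    """Per-ROI exponent table with a mean ± SD summary row.

    Mirrors the customary presentation: one row per ROI with its fitted n,
    then ``m ± SD`` over ROIs (sample SD).
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f"ROI{i + 1}", f) for i, f in enumerate(fits)]
    if not items:
        raise ValueError("need at least one fit")
    rows = [
        {"roi": name, "n": f.n, "k": f.k, "r_squared": f.r_squared, "regime": f.regime}
        for name, f in items
    ]
    ns = np.array([r["n"] for r in rows])
    mean = float(ns.mean())
    sd = float(ns.std(ddof=1)) if ns.size > 1 else 0.0
    rows.append({"roi": "m +/- SD", "n": mean, "k": np.nan,
                 "r_squared": np.nan, "regime": f"{mean:.2f} +/- {sd:.2f}"})
    df = pd.DataFrame(rows)
    df.attrs["n_mean"] = mean
    df.attrs["n_sd"] = sd
    return df
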