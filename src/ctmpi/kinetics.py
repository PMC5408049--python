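"""First-pass contrast kinetics shared by the phantom and the estimator.

The arterial input function (AIF) is modelled as a gamma-variate bolus on a
constant baseline, parameterised so that ``amplitude`` is the peak enhancement
above baseline and the peak occurs at ``onset_s + shape_alpha * scale_beta``::

    A(t) = baseline + amplitude * (u / (alpha*beta))**alpha
                      * exp(alpha - u/beta),        u = t - onset  (u > 0)

Tissue enhancement follows a flow-scaled plug-flow (box) impulse-residue
model: an instantaneous bolus entering the tissue stays for ``transit_time_s``
seconds and then leaves, so the residue function is R(t) = 1 for
0 <= t < transit_time and 0 afterwards.  The tissue curve is

    C(t) = baseline_t + F * integral_{t - delay - T}^{t - delay} Abar(s) ds

with ``Abar`` the AIF above its baseline and ``F`` the perfusion per unit
tissue volume in 1/s.  Because the box convolution has the closed form
I(t) - I(t - T) where I is the running integral of Abar, the maximal upslope
of the model curve equals F * max_t [Abar(t) - Abar(t - T)], which reduces to
F * max(Abar) whenever the transit time exceeds the bolus rise time.  That is
the relation the maximal-slope readout exploits: MBF = max slope of the model
curve divided by the AIF maximum.

Units bridge
------------
Myocardial blood flow is reported in ml of blood per 100 ml of tissue per
minute.  A flow of F (1/s) = F ml blood / ml tissue / s corresponds to
F * 60 * 100 = F * 6000 ml/100 ml/min (``MBF_UNITS_PER_S``).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.special import gammainc, gammaln

__all__ = [
    "MBF_UNITS_PER_S",
    "AifParams",
    "gamma_variate",
    "gamma_variate_integral",
    "box_response",
    "tissue_curve",
]

#: (ml/100 ml/min) per (ml blood / ml tissue / s)
MBF_UNITS_PER_S = 6000.0


class AifParams(BaseModel):
    """Gamma-variate arterial input function parameters.

    amplitude : HU, peak enhancement above baseline (0 gives a flat curve)
    onset_s : s, bolus arrival time
    shape_alpha : dimensionless shape of the gamma variate (> 0)
    scale_beta : s, time scale of the gamma variate (> 0)
    baseline_hu : HU, pre-contrast blood attenuation
    """

    amplitude: float
    onset_s: float
    shape_alpha: float
    scale_beta: float
    baseline_hu: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "AifParams":
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape_alpha <= 0 or self.scale_beta <= 0:
            raise ValueError("shape_alpha and scale_beta must be positive")
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        return self

    @property
    def peak_time_s(self) -> float:
        """Time of the AIF maximum: onset + alpha * beta."""
        return self.onset_s + self.shape_alpha * self.scale_beta

    def curve(self, t: np.ndarray | float) -> np.ndarray:
        return gamma_variate(
            t,
            self.amplitude,
            self.onset_s,
            self.shape_alpha,
            self.scale_beta,
            self.baseline_hu,
        )

    def above_baseline(self, t: np.ndarray | float) -> np.ndarray:
        return self.curve(t) - self.baseline_hu

    def integral_above_baseline(self, t: np.ndarray | float) -> np.ndarray:
        return gamma_variate_integral(
            t, self.amplitude, self.onset_s, self.shape_alpha, self.scale_beta
        )


def gamma_variate(
    t: np.ndarray | float,
    amplitude: float,
    onset_s: float,
    shape_alpha: float,
    scale_beta: float,
    baseline_hu: float = 0.0,
) -> np.ndarray:
    """Gamma-variate bolus curve in HU; baseline before onset, peak
    ``baseline + amplitude`` at ``onset + alpha * beta``."""
    if shape_alpha <= 0 or scale_beta <= 0:
        raise ValueError("shape_alpha and scale_beta must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t, dtype=float)
    u = t - onset_s
    peak_u = shape_alpha * scale_beta
    with np.errstate(divide="ignore", invalid="ignore"):
        logval = shape_alpha * np.log(u / peak_u) + (shape_alpha - u / scale_beta)
    out = np.where(u > 0, amplitude * np.exp(np.where(u > 0, logval, 0.0)), 0.0)
    return baseline_hu + out


def gamma_variate_integral(
    t: np.ndarray | float,
    amplitude: float,
    onset_s: float,
    shape_alpha: float,
    scale_beta: float,
) -> np.ndarray:
    """Closed-form running integral of the gamma variate above baseline,
    int_0^t (A(s) - baseline) ds in HU*s.

    Uses the regularised lower incomplete gamma function:
    int_0^u s^a exp(-s/b) ds = b**(a+1) * Gamma(a+1) * P(a+1, u/b).
    """
    if shape_alpha <= 0 or scale_beta <= 0:
        raise ValueError("shape_alpha and scale_beta must be positive")
    t = np.asarray(t, dtype=float)
    u = np.maximum(t - onset_s, 0.0)
    a, b = shape_alpha, scale_beta
    log_coef = (
        a
        + gammaln(a + 1.0)
        + (a + 1.0) * np.log(b)
        - a * np.log(a * b)
    )
    return amplitude * np.exp(log_coef) * gammainc(a + 1.0, u / b)


def box_response(
    t: np.ndarray | float,
    aif: AifParams,
    transit_time_s: float,
    delay_s: float = 0.0,
) -> np.ndarray:
    """Convolution of the AIF above baseline with a unit box residue of
    length ``transit_time_s``, delayed by ``delay_s``; units HU*s.

    Multiplying by a flow scale F (1/s) yields tissue enhancement in HU.
    """
    if transit_time_s <= 0:
        raise ValueError("transit_time_s must be positive")
    if delay_s < 0:
        raise ValueError("delay_s must be non-negative")
    t = np.asarray(t, dtype=float)
    upper = aif.integral_above_baseline(t - delay_s)
    lower = aif.integral_above_baseline(t - delay_s - transit_time_s)
    return upper - lower


def tissue_curve(
    t: np.ndarray | float,
    true_mbf: float,
    aif: AifParams,
    transit_time_s: float = 8.0,
    delay_s: float = 0.0,
    tissue_baseline_hu: float = 0.0,
) -> np.ndarray:
    """Noiseless tissue time-attenuation curve for a voxel perfused at
    ``true_mbf`` ml/100 ml/min, by flow-scaled box-residue convolution."""
    if true_mbf < 0:
        raise ValueError("true_mbf must be non-negative")
    flow_per_s = true_mbf / MBF_UNITS_PER_S
    return tissue_baseline_hu + flow_per_s * box_response(
        t, aif, transit_time_s, delay_s
    )
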