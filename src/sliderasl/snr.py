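"""Analytic SNR-efficiency model for shifted thick-slice ASL.

For a single acquired perfusion image the noise variance is

    var = g^2 * var_thermal + var_physio                           (per image)

and after averaging ``N`` measurements

    var_N = g^2 * var_thermal / N + var_physio / N'

where ``N'`` (between 1 and ``N``) is the effective number of measurements
of the temporally correlated physiological noise.  The SNR efficiency of a
super-resolution acquisition with ``N_set`` shifted thick-slice stacks,
relative to a thin-slice reference with ``N_full`` measurements, is

    gain = sqrt(N_set) * sqrt( (var_physio/N'_full + g_ref^2  var_th/N_full)
                             / (var_physio/N'_meas + g_sr^2 var_th/N_meas) )

which reduces to sqrt(N_set) when physiological noise vanishes and the
g-factors and measurement counts match.  The sqrt(N_set) factor is the
idealised sampling argument (every thin slice is covered by every
measurement); the boxcar deblurring penalty it neglects is quantified
empirically by the simulator (see docs/methods.md).

``N'`` is left abstract in the model; :func:`ar1_effective_n` provides the
AR(1)-based value the simulator realises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseBudget", "averaged_noise_variance", "snr_efficiency_ratio",
           "ar1_effective_n"]


@dataclass(frozen=True)
class NoiseBudget:
    """Noise and repetition bookkeeping of one SR-vs-reference comparison."""

    n_set: int
    n_meas: int               # measurements per shifted set
    n_full: int               # measurements of the reference scan
    var_thermal: float
    var_physio: float
    n_meas_eff: float | None = None  # N'_meas; defaults to n_meas (white)
    n_full_eff: float | None = None
    g_slider: float = 1.0
    g_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.n_set < 1 or self.n_meas < 1 or self.n_full < 1:
            raise ValueError("set and measurement counts must be >= 1")
        if self.var_thermal < 0 or self.var_physio < 0:
            raise ValueError("variances must be >= 0")
        if self.g_slider < 1 or self.g_ref < 1:
            raise ValueError("g-factors must be >= 1")
        for eff, n, name in ((self.n_meas_eff, self.n_meas, "n_meas_eff"),
                             (self.n_full_eff, self.n_full, "n_full_eff")):
            if eff is not None and not 1 <= eff <= n + 1e-9:
                raise ValueError(f"{name} must lie in [1, {n}], got {eff}")

    @property
    def meas_eff(self) -> float:
        return self.n_meas if self.n_meas_eff is None else self.n_meas_eff

    @property
    def full_eff(self) -> float:
        return self.n_full if self.n_full_eff is None else self.n_full_eff


def averaged_noise_variance(budget: NoiseBudget, condition: str) -> float:
    """Noise variance of the N-measurement average for one condition.

    ``condition`` is ``'slider'`` (the shifted thick-slice scan, ``N_meas``
    measurements, g_slider) or ``'reference'`` (``N_full``, g_ref).
    """
    if condition == "slider":
        n, n_eff, g = budget.n_meas, budget.meas_eff, budget.g_slider
    elif condition == "reference":
        n, n_eff, g = budget.n_full, budget.full_eff, budget.g_ref
    else:
        raise ValueError(f"condition must be 'slider' or 'reference', "
                         f"got {condition!r}")
    return g**2 * budget.var_thermal / n + budget.var_physio / n_eff


def snr_efficiency_ratio(budget: NoiseBudget) -> float:
    """SNR-efficiency gain of the SR acquisition over the reference."""
    num = averaged_noise_variance(budget, "reference")
    den = averaged_noise_variance(budget, "slider")
    if den == 0 or num == 0:
        raise ValueError("zero total noise; the SNR ratio is undefined")
    return float(np.sqrt(budget.n_set) * np.sqrt(num / den))


def ar1_effective_n(n_meas: int, rho: float, exact: bool = True) -> float:
    """Effective number of measurements for AR(1) noise with lag-1 ``rho``.

    The variance of the mean of ``n`` AR(1) samples with marginal variance
    ``v`` is ``v / n_eff`` with

        n_eff = n / (1 + 2 * sum_{k=1}^{n-1} (1 - k/n) rho^k)

    The asymptotic form (``exact=False``) is ``n (1 - rho) / (1 + rho)``,
    clipped to [1, n].
    """
    if n_meas < 1:
        raise ValueError("n_meas must be >= 1")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if not exact:
        return float(np.clip(n_meas * (1 - rho) / (1 + rho), 1.0, n_meas))
    k = np.arange(1, n_meas)
    factor = 1.0 + 2.0 * np.sum((1.0 - k / n_meas) * rho**k)
    return float(np.clip(n_meas / factor, 1.0, n_meas))
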