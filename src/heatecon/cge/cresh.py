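"""CRESH import-sourcing aggregator.

CRESH (Constant Ratios of Elasticity of Substitution, Homothetic) generalises
CES by giving every input its own substitution parameter, which is what lets
import demand respond with a pair-specific elasticity σ_IMP per
(destination, source) — including the border effect (within-country σ_IMP
raised by 20%). The aggregator is only implicitly defined:

    Σ_o B_o (x_o / Z)^{h_o} = 1,      h_o = (σ_o − 1)/σ_o ∈ (0, 1),

so cost-minimising source shares y_o = x_o/Z solve

    p_o = ν B_o h_o y_o^{h_o − 1}     (ν > 0 a scalar multiplier)

together with the constraint; ν is found by a bracketed scalar root solve.
When all σ_o are equal the system collapses to ordinary CES sourcing, which
serves as the oracle in tests. Only σ_o > 1 is supported (keeps B_o > 0 and
the share system monotone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..errors import ConfigError


@dataclass
class CreshNest:
    """Calibrated CRESH nest for one (destination, good): import sourcing across origins."""

    origins: np.ndarray  # indices of source regions
    h: np.ndarray  # (n,) parameters h_o in (0,1)
    B: np.ndarray  # (n,) calibrated weights
    base_shares: np.ndarray  # benchmark y_o = x̄_o / Z̄

    @classmethod
    def calibrate(cls, origins, x_bar: np.ndarray, sigma: np.ndarray) -> "CreshNest":
        """Calibrate from benchmark import values at unit prices."""
        x_bar = np.asarray(x_bar, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 1.0):
            raise ConfigError("CRESH sourcing requires sigma_imp > 1")
        if np.any(x_bar <= 0):
            raise ConfigError("benchmark import flows must be positive in a CRESH nest")
        h = (sigma - 1.0) / sigma
        z_bar = x_bar.sum()
        y_bar = x_bar / z_bar
        mu = (x_bar / h).sum()
        # FOC at unit prices: 1 = (mu/z_bar) * B_o h_o y_bar^(h_o-1)
        B = z_bar / (mu * h * y_bar ** (h - 1.0))
        nest = cls(origins=np.asarray(origins), h=h, B=B, base_shares=y_bar)
        return nest

    def shares(self, prices: np.ndarray) -> np.ndarray:
        """Cost-minimising quantity shares y_o (per unit of aggregate) at source *prices*."""
        p = np.asarray(prices, dtype=float)
        if np.any(p <= 0):
            raise ConfigError("source prices must be positive")
        h, B = self.h, self.B

        def g(log_nu: float) -> float:
            y = (np.exp(log_nu) * B * h / p) ** (1.0 / (1.0 - h))
            return B @ y**h - 1.0

        lo, hi = -5.0, 5.0
        while g(lo) > 0:
            lo -= 5.0
        while g(hi) < 0:
            hi += 5.0
        log_nu = brentq(g, lo, hi, xtol=1e-14)
        y = (np.exp(log_nu) * B * h / p) ** (1.0 / (1.0 - h))
        return y

    def unit_cost(self, prices: np.ndarray, shares: np.ndarray | None = None) -> float:
        y = self.shares(prices) if shares is None else shares
        return float(np.asarray(prices, dtype=float) @ y)
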