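"""Elastic scattering of low-energy electrons in water.

Angular model: screened Rutherford,

    d(sigma)/d(Omega)  ∝  (1 - cos(theta) + 2 eta)^-2,

with an energy-dependent screening parameter eta(T) of Moliere form.  The
normalised distribution over solid angle integrates to
pi / (eta (1 + eta)) times the constant prefactor, which makes both the
normalisation and the inverse-CDF sampling analytic.

The elastic inverse mean free path is tabulated in a plain-text fixture
(log-log interpolated) rather than derived from the angular model, so a
partial-wave table can replace it without touching the transport code.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np

from .constants import ELECTRON_REST_EV

__all__ = ["screening_parameter", "elastic_dcs", "sample_cos_theta", "ElasticModel"]

#: Moliere screening constant and effective Z for water.
_SCREENING_CONST = 1.7e-5
_Z_EFF_WATER = 7.42


def screening_parameter(t_ev: float) -> float:
    """Screening parameter eta(T); decreases with energy (more forward-peaked)."""
    if t_ev <= 0:
        raise ValueError("energy must be positive")
    tau = t_ev / ELECTRON_REST_EV
    return _SCREENING_CONST * _Z_EFF_WATER ** (2.0 / 3.0) / (tau * (tau + 2.0))


def elastic_dcs(t_ev: float, theta_rad) -> np.ndarray | float:
    """Normalised angular density over solid angle (sr^-1) at angle theta.

    Integrates to one over 4 pi; maximal in the forward direction.
    """
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(theta < 0) or np.any(theta > math.pi + 1e-12):
        raise ValueError("theta must lie in [0, pi]")
    eta = screening_parameter(t_ev)
    norm = eta * (1.0 + eta) / math.pi
    val = norm / (1.0 - np.cos(theta) + 2.0 * eta) ** 2
    if val.ndim == 0:
        return float(val)
    return val


def sample_cos_theta(t_ev: float, u: float) -> float:
    """Inverse-CDF draw of the polar scattering cosine, u ~ U(0,1)."""
    eta = screening_parameter(t_ev)
    return 1.0 - 2.0 * eta * u / (1.0 + eta - u)


class ElasticModel:
    """Elastic inverse mean free path table plus the angular sampler."""

    def __init__(self, t_ev: np.ndarray | None = None,
                 imfp_per_nm: np.ndarray | None = None) -> None:
        if t_ev is None:
            text = resources.files("nanodos.data").joinpath("elastic_imfp.tsv").read_text()
            rows = [
                tuple(float(x) for x in line.split())
                for line in text.splitlines()
                if line.strip() and not line.startswith("#")
            ]
            t_ev = np.array([r[0] for r in rows])
            imfp_per_nm = np.array([r[1] for r in rows])
        self.t_grid = np.asarray(t_ev, dtype=float)
        self.imfp_grid = np.asarray(imfp_per_nm, dtype=float)
        self._log_t = np.log(self.t_grid)
        self._log_imfp = np.log(self.imfp_grid)

    def imfp(self, t_ev: float) -> float:
        """Elastic inverse mean free path (nm^-1), log-log interpolated."""
        if t_ev <= 0:
            raise ValueError("energy must be positive")
        x = math.log(min(max(t_ev, self.t_grid[0]), self.t_grid[-1]))
        return math.exp(float(np.interp(x, self._log_t, self._log_imfp)))
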