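"""Zero-one-inflated beta distribution on [0, 1].

Mixture of point masses at the boundaries and a beta density inside:
with probability ``zoi`` the response is a boundary value (1 with
conditional probability ``coi``, else 0); otherwise it is
``Beta(mu * phi, (1 - mu) * phi)``.  ``mu`` is the beta mean and ``phi``
the precision, the (mu, phi) parameterization used throughout the
hierarchical model.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import betaln

__all__ = ["zoib_logpdf", "zoib_rvs", "zoib_mean"]


def _check_params(mu, phi, zoi, coi):
    mu, phi, zoi, coi = (np.asarray(v, dtype=float) for v in (mu, phi, zoi, coi))
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie in (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    if np.any((zoi < 0) | (zoi >= 1)):
        raise ValueError("zoi must lie in [0, 1)")
    if np.any((coi < 0) | (coi > 1)):
        raise ValueError("coi must lie in [0, 1]")
    return mu, phi, zoi, coi


def zoib_logpdf(y, mu, phi, zoi, coi):
    """Log-density (with point masses) of the zero-one-inflated beta.

    ``y = 0`` has mass ``zoi * (1 - coi)``, ``y = 1`` mass ``zoi * coi``;
    interior values carry ``(1 - zoi)`` times the beta density.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    mu, phi, zoi, coi = _check_params(mu, phi, zoi, coi)
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0,
            np.log(zoi) + np.log1p(-coi),
            np.where(
                y == 1,
                np.log(zoi) + np.log(np.maximum(coi, 0.0)),
                np.log1p(-zoi) + _beta_logpdf(y, mu, phi),
            ),
        )
    return out if out.shape else float(out)


def _beta_logpdf(y, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    # evaluate only where y is interior to avoid log(0) noise
    yc = np.clip(y, 1e-300, 1 - 1e-16)
    return (a - 1) * np.log(yc) + (b - 1) * np.log1p(-yc) - betaln(a, b)


def zoib_rvs(mu, phi, zoi, coi, size=None, rng=None):
    """Draw from the zero-one-inflated beta; vectorized over parameters."""
    mu, phi, zoi, coi = _check_params(mu, phi, zoi, coi)
    rng = np.random.default_rng() if rng is None else rng
    shape = np.broadcast_shapes(mu.shape, phi.shape, zoi.shape, coi.shape)
    if size is not None:
        shape = (size,) if np.isscalar(size) else tuple(size)
    u = rng.uniform(size=shape)
    boundary = u < zoi
    ones = rng.uniform(size=shape) < coi
    beta = rng.beta(np.broadcast_to(mu * phi, shape), np.broadcast_to((1 - mu) * phi, shape))
    out = np.where(boundary, np.where(ones, 1.0, 0.0), beta)
    return out if out.shape else float(out)


def zoib_mean(mu, phi, zoi, coi):
    """Expected value of the mixture: zoi * coi + (1 - zoi) * mu."""
    mu, phi, zoi, coi = _check_params(mu, phi, zoi, coi)
    out = zoi * coi + (1 - zoi) * mu
    return out if np.shape(out) else float(out)
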