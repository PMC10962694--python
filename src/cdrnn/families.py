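"""Response-distribution families.

A family maps the raw (pre-link) parameter vector ``s`` produced by the
convolution stage onto the natural parameters of the predictive distribution
and evaluates log densities and their gradients. Only the normal family is
fully implemented; the interface is pluggable so other continuous families
can be added.
"""

from __future__ import annotations

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))


def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


class Family:
    """Interface for response families.

    ``n_params`` raw parameters per response dimension; ``link`` maps raw to
    natural scale; ``loglik``/``nll_grad`` evaluate log density and the
    gradient of the negative log likelihood with respect to the *raw*
    parameters.
    """

    name: str = "abstract"
    n_params: int = 0

    def link(self, s_raw: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def loglik(self, y: np.ndarray, linked: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def nll_grad(self, y: np.ndarray, s_raw: np.ndarray):
        raise NotImplementedError


class Normal(Family):
    """Normal response: location mu (identity link), scale sigma (log link).

    The log link is the standard choice for scale parameters in
    distributional regression: it keeps sigma strictly positive, makes
    additive contributions to the raw parameter act multiplicatively on the
    scale, and gives a bounded likelihood gradient (1 - z^2) with respect to
    the raw parameter. The raw value is clipped to avoid overflow.
    """

    name = "normal"
    n_params = 2
    _CLIP = 20.0

    def link(self, s_raw):
        s_raw = np.atleast_2d(np.asarray(s_raw, dtype=float))
        mu = s_raw[:, 0]
        sigma = np.exp(np.clip(s_raw[:, 1], -self._CLIP, self._CLIP))
        return np.column_stack([mu, sigma])

    def loglik(self, y, linked):
        y = np.asarray(y, dtype=float)
        mu, sigma = linked[:, 0], linked[:, 1]
        if np.any(sigma <= 0):
            raise ValueError("non-positive sigma after link; link is broken")
        z = (y - mu) / sigma
        return -0.5 * LOG_2PI - np.log(sigma) - 0.5 * z * z

    def nll_grad(self, y, s_raw):
        """Returns ``(nll_values, d_nll/d_s_raw)`` with shapes (n,), (n, 2)."""
        s_raw = np.atleast_2d(np.asarray(s_raw, dtype=float))
        y = np.asarray(y, dtype=float)
        mu = s_raw[:, 0]
        s1 = np.clip(s_raw[:, 1], -self._CLIP, self._CLIP)
        sigma = np.exp(s1)
        z = (y - mu) / sigma
        nll = 0.5 * LOG_2PI + s1 + 0.5 * z * z
        dmu = -z / sigma
        ds1 = 1.0 - z * z
        return nll, np.column_stack([dmu, ds1])

    def init_raw(self, y):
        """Raw parameters matching the sample mean and SD of ``y``."""
        y = np.asarray(y, dtype=float)
        sd = max(float(np.std(y)), 1e-3)
        return np.array([float(np.mean(y)), float(np.log(sd))])


class Gamma(Family):
    """Placeholder for a gamma response family (not yet implemented)."""

    name = "gamma"
    n_params = 2

    def link(self, s_raw):  # pragma: no cover - interface stub
        raise NotImplementedError("gamma family is a stub")


class Bernoulli(Family):
    """Placeholder for a Bernoulli response family (not yet implemented)."""

    name = "bernoulli"
    n_params = 1

    def link(self, s_raw):  # pragma: no cover - interface stub
        raise NotImplementedError("bernoulli family is a stub")


_FAMILIES = {"normal": Normal, "gamma": Gamma, "bernoulli": Bernoulli}


def get_family(name: str) -> Family:
    if name not in _FAMILIES:
        raise ValueError(f"unknown response family {name!r}")
    return _FAMILIES[name]()


def loglik(y, s, family="normal"):
    """Log density of ``y`` under the family with *linked* parameters ``s``.

    ``s`` rows are on the natural scale (e.g. ``[mu, sigma]`` with
    ``sigma > 0``). The dataset log likelihood is the sum over samples.
    """
    fam = get_family(family) if isinstance(family, str) else family
    return fam.loglik(np.asarray(y, dtype=float), np.atleast_2d(np.asarray(s, float)))
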