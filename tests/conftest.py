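"""Shared fixtures and independent numerical oracles for the test suite.

The oracles here deliberately use different numerics from the package
(complex arithmetic for the HN function, a piecewise-linear Filon-type
log-grid transform for the KWW shape, dense grid searches for peak
positions and tangent constructions) so that agreement is a genuine
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from glasspharm.dielectric_models import RelaxationProcess, hn_loss


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def hn_loss_complex(delta_eps, tau, a, b, frequencies):
    """HN loss via direct complex arithmetic on eps* = de/(1+(iwt)^a)^b."""
    w = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
    eps = delta_eps / (1.0 + (1j * w * tau) ** a) ** b
    return -eps.imag


def kww_loss_filon(beta, tau, frequencies, delta_eps=1.0, n_grid=30000):
    """KWW loss by exact cosine transform of the piecewise-linear
    interpolant of phi(t) = exp(-(t/tau)^beta) on a log grid."""
    f = np.asarray(frequencies, dtype=float)
    t_hi = tau * (45.0 ** (1.0 / beta))
    t = np.logspace(np.log10(tau) - 8.0, np.log10(t_hi), n_grid)
    phi = np.exp(-((t / tau) ** beta))
    out = np.empty_like(f)
    t1, t2 = t[:-1], t[1:]
    p1, p2 = phi[:-1], phi[1:]
    slope = (p2 - p1) / (t2 - t1)
    a0 = p1 - slope * t1
    for i, fi in enumerate(f):
        w = 2.0 * np.pi * fi
        s1, s2 = np.sin(w * t1), np.sin(w * t2)
        c1, c2 = np.cos(w * t1), np.cos(w * t2)
        # int (a0 + slope*t) cos(wt) dt over [t1, t2], exactly
        seg = a0 * (s2 - s1) / w + slope * (
            (t2 * s2 - t1 * s1) / w + (c2 - c1) / w**2
        )
        head = np.sin(w * t[0]) / w  # phi ~ 1 on [0, t_min]
        out[i] = delta_eps * w * (head + np.sum(seg))
    return out


def brute_force_tau_max(process: RelaxationProcess, n=20001, span=6.0):
    """Peak relaxation time of an HN process by dense log-grid search
    plus parabolic refinement."""
    f0 = 1.0 / (2.0 * np.pi * process.tau_hn)
    logf = np.linspace(np.log10(f0) - span, np.log10(f0) + span, n)
    y = hn_loss(process, 10.0**logf)
    i = int(np.argmax(y))
    sl = slice(i - 2, i + 3)
    c = np.polyfit(logf[sl], y[sl], 2)
    log_fmax = -c[1] / (2.0 * c[0])
    return 1.0 / (2.0 * np.pi * 10.0**log_fmax)


def numeric_gaussian_onset(center, sigma, step=1e-3):
    """Tangent-construction onset of a sampled Gaussian: steepest
    leading-edge tangent intersected with the zero baseline."""
    T = np.arange(center - 8 * sigma, center, step)
    y = np.exp(-0.5 * ((T - center) / sigma) ** 2)
    g = np.gradient(y, T)
    j = int(np.argmax(g))
    return T[j] - y[j] / g[j]


def fwhm_decades(logf, y):
    """Full width at half maximum of a single peak, in decades of f."""
    y = np.asarray(y)
    half = 0.5 * y.max()
    above = np.flatnonzero(y >= half)
    lo, hi = above[0], above[-1]
    x_lo = np.interp(half, [y[lo - 1], y[lo]], [logf[lo - 1], logf[lo]])
    x_hi = np.interp(half, [y[hi + 1], y[hi]], [logf[hi + 1], logf[hi]])
    return x_hi - x_lo


@pytest.fixture(scope="session")
def freq_grid():
    """The standard measurement frequency window, 8 points per decade."""
    return np.logspace(-1, 6, 57)
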