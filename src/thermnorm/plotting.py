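"""Diagnostic plots: fitted reaction-norm fans and MCMC traces."""

from __future__ import annotations

import numpy as np


def plot_reaction_norms(norms, ax=None, temp_range=(10.0, 35.0)):
    """Fan of fitted lines R = a + bT over the given temperature range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    T = np.linspace(*temp_range, 50)
    for nm in norms:
        ax.plot(T, nm.intercept_a + nm.slope_b * T, lw=0.8, alpha=0.6)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("developmental rate (1/day)")
    return ax


def plot_trace(results, param="rho", ax=None):
    """Thinned-sample trace for one parameter of a fitted Brownian model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(results.samples["iteration"], results.samples[param], lw=0.7)
    ax.set_xlabel("iteration")
    ax.set_ylabel(param)
    return ax
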