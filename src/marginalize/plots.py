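"""Diagnostic plots: CCF panels and complementary log-log survival curves."""

from __future__ import annotations

import numpy as np

from .ccf import ccf_eval, get_link
from .survival import StepCurve

__all__ = ["plot_ccf_panel", "plot_cloglog_survival"]


def plot_ccf_panel(links, nus, ax=None, n_grid=200):
    """Overlay CCF curves g_nu(p) for several links and effect sizes.

    A linear curve signals a collapsible effect measure; concave (nu > 0)
    or convex (nu < 0) curves signal attenuation or inflation of the
    marginal effect relative to the conditional one.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p = np.linspace(0.005, 0.995, n_grid)
    for link in links:
        link = get_link(link)
        for nu in nus:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                g = np.asarray(ccf_eval(link, nu, p))
            ax.plot(p, g, label=f"{link.name}, nu={nu:g}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("Pr(Y=1 | X=0, C)")
    ax.set_ylabel("Pr(Y=1 | X=1, C)")
    ax.set_xlim(0, 1)
    ax.legend(fontsize="small")
    return ax


def plot_cloglog_survival(curves: dict[int, StepCurve], ax=None):
    """Plot log(-log S_x(t)) against t for the standardized survival curves.

    Near-parallel curves indicate that a single marginal hazard ratio is a
    reasonable summary of the (generally time-varying) marginal contrast.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for x, curve in sorted(curves.items()):
        s = np.clip(curve.values, 1e-12, 1 - 1e-12)
        ax.step(curve.times, np.log(-np.log(s)), where="post", label=f"x={x}")
    ax.set_xlabel("time")
    ax.set_ylabel("log(-log S_x(t))")
    ax.legend()
    return ax
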