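"""Plot helpers for the fitted analyses (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .boundary import PolarDensityMap
from .ms_binding import BindingCurve, BinomialBindingModel, expected_bound


def plot_binding_curve(curve: BindingCurve, model: BinomialBindingModel | None = None, ax=None):
    """Average bound lipids versus concentration, with an optional model line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        curve.concentrations, curve.avg_bound,
        yerr=[p[2] for p in curve.points], fmt="o", label=curve.species.name,
    )
    if model is not None:
        cs = np.linspace(0, curve.concentrations.max() * 1.2, 200)
        ax.plot(cs, [expected_bound(model, c) for c in cs], "-",
                label=f"N={model.n_sites}, K={model.k_d:.3g} uM")
    ax.set_xlabel("lipid concentration (uM)")
    ax.set_ylabel("average bound lipids per pentamer")
    ax.legend()
    return ax


def plot_density_map(dmap: PolarDensityMap, ax=None):
    """Polar heat map of phosphate-bead area density."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta, r = np.meshgrid(dmap.angular_edges, dmap.radial_edges)
    pcm = ax.pcolormesh(theta, r, dmap.values, shading="auto")
    ax.figure.colorbar(pcm, ax=ax, label="beads / A^2")
    ax.set_title(f"{dmap.leaflet} leaflet")
    return ax


def plot_rate_course(points, results=None, ax=None):
    """Influx rate versus agonist delay with an optional fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = [p.delay for p in points]
    ax.errorbar(t, [p.k_mean for p in points], yerr=[p.k_sd for p in points], fmt="o")
    if results is not None:
        tt = np.geomspace(min(t), max(t), 300)
        ax.plot(tt, results.predict(tt), "-")
    ax.set_xscale("log")
    ax.set_xlabel("agonist delay (s)")
    ax.set_ylabel("influx rate at 2 ms (1/s)")
    return ax
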