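"""Operating-characteristic plots.

Two figures mirror the standard design-report graphics: all eleven
quantities against a common effect shift theta (tau_1 = ... = tau_K =
theta), and the marginal powers P_k against theta with the other arms at
theta - (delta1 - delta0).  Reference lines mark alpha, 1 - beta, delta1
and delta0.  The `quality` knob maps to the theta-grid density:
low/medium/high -> 33/66/100 points.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

QUALITY_GRID_POINTS = {"low": 33, "medium": 66, "high": 100}

__all__ = ["QUALITY_GRID_POINTS", "theta_grid", "render_plots"]


def theta_grid(spec, n_points: int):
    """Effect grid spanning delta0 .. delta1 with a 25% margin each side,
    clipped for Bernoulli outcomes so every response rate stays in (0, 1)."""
    import numpy as np

    lo = min(spec.delta0, 0.0)
    hi = spec.delta1
    pad = 0.25 * (hi - lo)
    lo, hi = lo - pad, hi + pad
    if spec.outcome.family == "bernoulli":
        pi0 = spec.outcome.pi0
        gap = spec.delta1 - spec.delta0
        lo = max(lo, -pi0 + gap + 1e-3)
        hi = min(hi, 1.0 - pi0 - 1e-3)
    return np.linspace(lo, hi, n_points)


def render_plots(curve_all, curve_one, spec, outdir) -> list:
    """Write the two curve figures; returns the created file paths.

    Either curve may be ``None``/empty, in which case its figure is
    skipped (an empty request produces no files and no error).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created = []

    def refs(ax, vertical=True):
        ax.axhline(spec.alpha, ls=":", c="grey", lw=0.8)
        ax.axhline(1 - spec.beta, ls=":", c="grey", lw=0.8)
        if vertical:
            ax.axvline(spec.delta1, ls=":", c="grey", lw=0.8)
            ax.axvline(spec.delta0, ls=":", c="grey", lw=0.8)

    if curve_all is not None and len(curve_all):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for col in curve_all.columns:
            if col == "theta":
                continue
            ax.plot(curve_all["theta"], curve_all[col], label=col, lw=1)
        refs(ax)
        ax.set_xlabel(r"$\theta$ (common treatment effect)")
        ax.set_ylabel("probability / rate")
        ax.legend(fontsize=6, ncol=3)
        path = outdir / "opchar_vs_theta.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        created.append(path)

    if curve_one is not None and len(curve_one):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for col in curve_one.columns:
            if col == "theta":
                continue
            ax.plot(curve_one["theta"], curve_one[col], label=col, lw=1)
        refs(ax)
        ax.set_xlabel(r"$\theta$ (effect of the shifted arm)")
        ax.set_ylabel("marginal power")
        ax.legend(fontsize=8)
        path = outdir / "marginal_power_vs_theta.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        created.append(path)
    return created
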