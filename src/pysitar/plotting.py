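"""Quick-look plots: unadjusted vs SITAR-adjusted growth curves and the
tempo scatter matrix."""

from __future__ import annotations

import numpy as np

from .data import inverse_transform
from .model import SitarResults


def plot_fit(fit: SitarResults, ax=None, adjusted: bool = False):
    """Spaghetti plot of the individual curves with the mean curve.

    ``adjusted=True`` shows each subject's data after undoing their
    size/tempo/velocity adjustment, which superimposes the curves onto
    the mean.
    """
    import matplotlib.pyplot as plt

    if fit.model is None:
        raise ValueError("plotting needs a fit with attached data")
    if ax is None:
        _, ax = plt.subplots()
    g = fit.model._grouped
    ids = fit.model.subject_ids
    for i, sid in enumerate(ids):
        mask = g.idx == i
        t = g.t[mask] + fit.age_center
        y = g.y[mask]
        if adjusted:
            e = fit.subject_effects(sid)
            t = fit.age_center + (t - fit.age_center - e.tempo) * np.exp(e.velocity)
            y = y - e.size
        ax.plot(t, inverse_transform(y, fit.spec.transform),
                lw=0.5, alpha=0.5)
    curve = fit.mean_curve(grid_step=0.05)
    ax.plot(curve.ages, curve.values, "k-", lw=2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel(fit.outcome)
    ax.set_title(("adjusted" if adjusted else "unadjusted") + f" {fit.outcome}")
    return ax


def plot_tempo_matrix(table, path=None):
    """Scatterplot matrix of tempo random effects across outcomes, with
    the pairwise correlations above the diagonal."""
    import matplotlib.pyplot as plt

    from .tempo import TempoTable, tempo_correlations

    df = table.table if isinstance(table, TempoTable) else table
    cols = list(df.columns)
    k = len(cols)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k))
    rep = tempo_correlations(table if isinstance(table, TempoTable)
                             else TempoTable(df))
    rmat = rep.matrix()
    for i in range(k):
        for j in range(k):
            ax = axes[i, j]
            if i == j:
                ax.annotate(cols[i], (0.5, 0.5), xycoords="axes fraction",
                            ha="center", va="center")
            elif i > j:
                ax.scatter(df[cols[j]], df[cols[i]], s=8)
            else:
                ax.annotate(f"r = {rmat.loc[cols[i], cols[j]]:.2f}",
                            (0.5, 0.5), xycoords="axes fraction",
                            ha="center", va="center")
            ax.set_xticks([])
            ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
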