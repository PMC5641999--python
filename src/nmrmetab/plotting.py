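"""Basic score and loading figures."""

from __future__ import annotations

import numpy as np

from .chemometrics import LoadingProfile, OplsModel

__all__ = ["score_plot", "loading_plot"]


def score_plot(model: OplsModel, labels, ax=None):
    """Predictive vs orthogonal score scatter, coloured by class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(model.t_pred[m], model.t_orth[m], label=str(lab), s=18)
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel("t[1] (predictive)")
    ax.set_ylabel("t[1]o (orthogonal)")
    ax.legend()
    return ax


def loading_plot(profile: LoadingProfile, ax=None):
    """Back-scaled loading profile coloured by |r| (hot = discriminating)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    sc = ax.scatter(
        profile.bin_ppm,
        profile.backscaled,
        c=np.abs(profile.r),
        cmap="coolwarm",
        vmin=0.0,
        vmax=1.0,
        s=4,
    )
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.invert_xaxis()
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("back-scaled loading")
    plt.colorbar(sc, ax=ax, label="|r|")
    return ax
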