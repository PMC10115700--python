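"""Basic renderings of the mesa plot, lens plot, and sum-score scatter."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def mesa_plot(mesa, ax=None):
    """PVAF of the best q-vector per attribute count, with the epsilon line.

    The filled marker is the item's original q-vector.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ms = np.arange(1, len(mesa.best_pvafs) + 1)
    labels = ["".join(map(str, q)) for q in mesa.best_qvectors]
    ax.plot(ms, mesa.best_pvafs, "o-", color="tab:blue", mfc="white")
    m_orig = int(mesa.original_qvector.sum())
    ax.plot([m_orig], [mesa.original_pvaf], "o", color="tab:blue")
    ax.axhline(mesa.epsilon, ls="--", color="gray", lw=1,
               label=f"eps = {mesa.epsilon:.2f}")
    ax.set_xticks(ms, labels)
    ax.set_xlabel("q-vector")
    ax.set_ylabel("PVAF")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"Mesa plot: {mesa.item_id}")
    ax.legend(loc="lower right", frameon=False)
    return ax


def lens_plot(lens, k: int, ax=None, jitter: float = 0.01, seed: int = 0):
    """Posterior attribute probability under independence (x) vs prevalence (y) prior.

    Seeded jitter is applied only in rendering, never to stored data.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(seed)
    x = lens.p_in[:, k] + rng.normal(0, jitter, lens.p_in.shape[0])
    y = lens.p_pr[:, k] + rng.normal(0, jitter, lens.p_pr.shape[0])
    ax.scatter(x, y, s=8, c=lens.endorsed_counts[:, k], cmap="viridis", alpha=0.7)
    ax.plot([0, 1], [0, 1], color="gray", lw=1)
    ax.set_xlabel("P(attribute) | independence prior")
    ax.set_ylabel("P(attribute) | prevalence prior")
    ax.set_title(f"{lens.attribute_names[k]}  (RMSD = {lens.rmsd[k]:.2f})")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    return ax


def sumscore_plot(table, attribute: str, ax=None, jitter: float = 0.08, seed: int = 0):
    """EAP attribute probability against the attribute sum score."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    sub = table[table["attribute"] == attribute]
    rng = np.random.default_rng(seed)
    x = sub["sum_score"].to_numpy() + rng.normal(0, jitter, len(sub))
    ax.scatter(x, sub["eap_probability"], s=8, alpha=0.6)
    ax.set_xlabel(f"{attribute} sum score")
    ax.set_ylabel("EAP probability")
    ax.set_ylim(-0.05, 1.05)
    return ax
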