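"""Plot-ready data tables for van Krevelen and composition figures.

The core emits tidy tables keyed by class label; rendering to an image
is optional and kept behind a flag so the analysis surface stays
backend-agnostic.
"""

from __future__ import annotations

import pandas as pd


def vk_plot_data(
    traits: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
    scheme: str = "vk_class",
    abundances: pd.Series | None = None,
) -> pd.DataFrame:
    """One row per molecule: O/C, H/C, class label and point size.

    ``scheme`` selects the label column of ``assignment`` (``vk_class``,
    ``element_group`` or ``fraction``); ``abundances`` (e.g. mean relative
    abundance) set the point size, defaulting to 1.
    """
    if len(traits) == 0:
        return pd.DataFrame(columns=["o_c", "h_c", "label", "size"])
    out = pd.DataFrame({"o_c": traits["o_c"], "h_c": traits["h_c"]},
                       index=traits.index)
    if assignment is not None and scheme in assignment.columns:
        out["label"] = assignment.loc[traits.index, scheme]
    else:
        out["label"] = "all"
    out["size"] = (abundances.reindex(traits.index).fillna(0.0)
                   if abundances is not None else 1.0)
    return out


def composition_plot_data(class_composition: pd.DataFrame) -> pd.DataFrame:
    """Long-format (sample, class, share) table from a samples x classes
    composition matrix."""
    long = class_composition.reset_index().melt(
        id_vars="sample", var_name="class", value_name="share")
    return long


def render_vk_diagram(points: pd.DataFrame, path) -> None:
    """Optional matplotlib rendering of a van Krevelen point table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, sub in points.groupby("label"):
        ax.scatter(sub["o_c"], sub["h_c"], s=10 + 40 * sub["size"],
                   label=str(label), alpha=0.6, edgecolors="none")
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
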