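"""Molecular class assignment schemes.

Three orthogonal labelings are supported:

* element-composition groups (CHO, CHON, ..., CHONSP),
* van Krevelen biomolecular classes from the (O/C, H/C) plane,
* reactivity-activity fractions combining the H/C lability cutoff with
  the transformation count (labile/recalcitrant x active/inactive).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

#: van Krevelen boxes as (label, o_c_lo, o_c_hi, h_c_lo, h_c_hi), matched
#: first-to-last with lower-inclusive / upper-exclusive interval bounds.
VK_BOXES = (
    ("lipids", 0.0, 0.3, 1.5, 2.0),
    ("proteins", 0.3, 0.55, 1.5, 2.2),
    ("amino sugars", 0.55, 0.67, 1.5, 2.2),
    ("carbohydrates", 0.67, 1.2, 1.5, 2.0),
    ("UnsatHC", 0.0, 0.1, 0.7, 1.5),
    ("lignin", 0.1, 0.67, 0.7, 1.5),
    ("tannin", 0.67, 1.2, 0.5, 1.5),
    ("ConHC", 0.0, 0.67, 0.2, 0.7),
)

FRACTION_LABELS = ("LA", "RA", "LI", "RI", "others")


def element_group(c: int, h: int, o: int, n: int = 0, s: int = 0, p: int = 0) -> str:
    """Element-composition group label: CHO plus present heteroatoms (N, S, P order)."""
    if c < 1 or h < 1:
        raise ValueError("element_group requires C >= 1 and H >= 1")
    if o == 0:
        return "non-CHO"
    return "CHO" + ("N" if n > 0 else "") + ("S" if s > 0 else "") + ("P" if p > 0 else "")


def vk_class(o_c: float, h_c: float) -> str:
    """van Krevelen class of a single (O/C, H/C) point; 'others' outside all boxes."""
    if not (np.isfinite(o_c) and np.isfinite(h_c)) or o_c < 0 or h_c < 0:
        raise ValueError("O/C and H/C must be finite and nonnegative")
    for label, olo, ohi, hlo, hhi in VK_BOXES:
        if olo <= o_c < ohi and hlo <= h_c < hhi:
            return label
    return "others"


def reactivity_activity(
    h_c: float,
    n_transformations: int,
    labile_cut: float = 1.5,
    active_above: int = 10,
    inactive_below: int = 1,
) -> str:
    """Reactivity-activity fraction.

    Labile means H/C >= 1.5; active means > 10 putative transformations,
    inactive means <= 1; counts in between fall into 'others'.
    """
    if n_transformations < 0:
        raise ValueError("n_transformations must be nonnegative")
    labile = h_c >= labile_cut
    if n_transformations > active_above:
        return "LA" if labile else "RA"
    if n_transformations <= inactive_below:
        return "LI" if labile else "RI"
    return "others"


def assign_classes(
    traits: pd.DataFrame,
    formulas: pd.DataFrame | None = None,
    n_transformations: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply all three schemes to a trait table.

    Returns a table indexed like ``traits`` with columns ``element_group``
    (needs ``formulas`` with C/H/O/N/S/P columns), ``vk_class`` and — when a
    transformation count is supplied — ``fraction``; without counts the
    fraction column is 'unclassified'.
    """
    out = pd.DataFrame(index=traits.index)
    if formulas is not None:
        f = formulas.set_index("id") if "id" in formulas.columns else formulas
        f = f.loc[traits.index]
        out["element_group"] = [
            element_group(int(r["C"]), int(r["H"]), int(r["O"]),
                          int(r.get("N", 0)), int(r.get("S", 0)), int(r.get("P", 0)))
            for _, r in f.iterrows()
        ]
    out["vk_class"] = [vk_class(oc, hc) for oc, hc in zip(traits["o_c"], traits["h_c"])]
    if n_transformations is not None:
        counts = n_transformations.reindex(traits.index).fillna(0).astype(int)
        out["fraction"] = [
            reactivity_activity(hc, k) for hc, k in zip(traits["h_c"], counts)
        ]
    else:
        out["fraction"] = "unclassified"
    return out


def class_relative_abundance(
    relative_abundance: pd.DataFrame,
    labels: pd.Series,
    include_unlabelled: bool = True,
) -> pd.DataFrame:
    """Per-sample class composition: summed relative abundance by class label.

    Parameters
    ----------
    relative_abundance
        Molecules x samples, columns summing to 1.
    labels
        Class label per molecule (one scheme).
    include_unlabelled
        Keep molecules whose label is missing under 'others' (default) or
        drop them and renormalize.

    Rows of the result (samples x classes) sum to 1 for nonempty samples.
    """
    totals = relative_abundance.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total intensity: {bad}")
    lab = labels.reindex(relative_abundance.index)
    if include_unlabelled:
        lab = lab.fillna("others")
        ra = relative_abundance
    else:
        keep = lab.notna()
        lab = lab[keep]
        ra = relative_abundance.loc[keep]
        ra = ra / ra.sum(axis=0)
    comp = ra.groupby(lab).sum().T
    comp.index.name = "sample"
    return comp
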