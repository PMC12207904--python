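"""Molecular formulas and per-molecule chemical traits.

Every assigned FT-ICR MS peak carries an element composition
(C, H, N, O, S, P counts) from which a battery of standard molecular
traits is derived: stoichiometric ratios, double-bond equivalents and
variants, the modified aromaticity index, nominal oxidation state of
carbon and the affine Gibbs free energy estimate, and the CH2-based
Kendrick mass defect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Monoisotopic atomic masses (Da), neutral atoms.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (Da), used to convert [M-H]- ion masses to neutral masses.
PROTON_MASS = 1.00727646688

#: Exact monoisotopic mass of a CH2 unit; the Kendrick scale divisor. Using
#: the exact value keeps the defect constant along CH2 homologous series to
#: float precision.
CH2_MASS = MONOISOTOPIC["C"] + 2 * MONOISOTOPIC["H"]

ELEMENTS = ("C", "H", "N", "O", "S", "P")

_HILL_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element composition with its exact neutral monoisotopic mass.

    ``is_dark`` marks compositions without carbon ("dark-matter-like");
    they are excluded from trait computation.
    """

    id: str
    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0
    mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name.upper()} count in formula {self.id!r}")
        if self.mass == 0.0:
            object.__setattr__(self, "mass", self.monoisotopic_mass())
        if self.mass <= 0:
            raise ValueError(f"nonpositive mass for formula {self.id!r}")

    @property
    def is_dark(self) -> bool:
        return self.c == 0

    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s, "P": self.p}

    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC[el] * cnt for el, cnt in self.counts().items())


def parse_hill(string: str) -> dict[str, int]:
    """Parse a Hill-notation formula string (e.g. ``C6H12O6``) into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _HILL_RE.finditer(string.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula string {string!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise ValueError(f"unsupported element {el!r} in {string!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(string.strip()):
        raise ValueError(f"cannot parse formula string {string!r}")
    return counts


def parse_formula(
    record: Mapping[str, object] | str,
    *,
    id: str | None = None,
    ion_mode: str = "neutral",
    mass_tolerance_da: float = 0.005,
) -> MolecularFormula:
    """Build a :class:`MolecularFormula` from a composition record.

    Parameters
    ----------
    record
        Mapping with case-insensitive element-count keys (``C``, ``H``, ...)
        plus optional ``mass`` and ``id``, or a Hill-notation string.
    ion_mode
        ``"neutral"`` (default) leaves a supplied mass untouched;
        ``"neg"`` treats it as an [M-H]- ion mass and adds one proton.
    mass_tolerance_da
        When both counts and a measured mass are supplied, warn if they
        disagree by more than this (Da).
    """
    if isinstance(record, str):
        counts = parse_hill(record)
        supplied_mass = None
    else:
        lowered = {str(k).lower(): v for k, v in record.items()}
        counts = {el: int(lowered.get(el.lower(), 0) or 0) for el in ELEMENTS}
        supplied_mass = lowered.get("mass")
        if supplied_mass is not None:
            supplied_mass = float(supplied_mass)
            if np.isnan(supplied_mass):
                supplied_mass = None
        if id is None and "id" in lowered:
            id = str(lowered["id"])
    counts = {el: counts.get(el, 0) for el in ELEMENTS}
    if supplied_mass is not None and ion_mode == "neg":
        supplied_mass = supplied_mass + PROTON_MASS
    elif ion_mode not in ("neutral", "neg"):
        raise ValueError(f"unknown ion_mode {ion_mode!r}")

    has_counts = any(counts.values())
    if not has_counts and supplied_mass is None:
        raise ValueError("record supplies neither atom counts nor a mass")

    mol = MolecularFormula(
        id=id or "",
        c=counts["C"], h=counts["H"], n=counts["N"],
        o=counts["O"], s=counts["S"], p=counts["P"],
        mass=supplied_mass if (supplied_mass is not None and not has_counts) else 0.0,
    )
    if supplied_mass is not None and has_counts:
        theoretical = mol.monoisotopic_mass()
        if abs(theoretical - supplied_mass) > mass_tolerance_da:
            warnings.warn(
                f"formula {mol.id!r}: measured mass {supplied_mass:.4f} deviates from "
                f"composition mass {theoretical:.4f} by more than {mass_tolerance_da} Da",
                stacklevel=2,
            )
    return mol


def formulas_from_table(table: pd.DataFrame, **kwargs) -> list[MolecularFormula]:
    """Parse each row of a formula table (columns id, C, H, N, O, S, P[, mass])."""
    out = []
    for _, row in table.iterrows():
        out.append(parse_formula(row.to_dict(), **kwargs))
    return out


def kendrick_defect_ch2(mass: np.ndarray | float) -> np.ndarray | float:
    """CH2-based Kendrick mass defect: nominal (round) Kendrick mass minus Kendrick mass."""
    km = np.asarray(mass, dtype=float) * (14.0 / CH2_MASS)
    return np.round(km) - km


def compute_traits(
    formulas: Sequence[MolecularFormula] | pd.DataFrame,
    y_met: Callable[[pd.DataFrame], pd.Series] | None = None,
    kendrick_nominal: str = "round",
) -> pd.DataFrame:
    """Compute the standard per-molecule trait table.

    Traits: mass, C, Kendrick defect (CH2 series), O/C, H/C, N/C, P/C, S/C,
    AImod (clamped to [0, 1]), DBE, DBE_O, DBE_AI, NOSC,
    GFE = 60.3 - 28.5 * NOSC (kJ per mol C), and optionally Y_met via a
    user-supplied hook.

    Parameters
    ----------
    formulas
        Parsed formulas (all must have C >= 1) or a raw composition table.
    y_met
        Optional callable mapping the trait table to a carbon-use-efficiency
        column. The package ships no default definition; absent a hook the
        column is omitted with a warning suppressed (pass ``y_met`` to enable).
    kendrick_nominal
        ``"round"`` (default) or ``"floor"`` — dialect for the nominal
        Kendrick mass.
    """
    if isinstance(formulas, pd.DataFrame):
        formulas = formulas_from_table(formulas)
    if any(f.c < 1 for f in formulas):
        bad = [f.id for f in formulas if f.c < 1][:5]
        raise ValueError(f"trait computation requires C >= 1; offending ids: {bad}")

    ids = [f.id for f in formulas]
    c = np.array([f.c for f in formulas], dtype=float)
    h = np.array([f.h for f in formulas], dtype=float)
    n = np.array([f.n for f in formulas], dtype=float)
    o = np.array([f.o for f in formulas], dtype=float)
    s = np.array([f.s for f in formulas], dtype=float)
    p = np.array([f.p for f in formulas], dtype=float)
    mass = np.array([f.mass for f in formulas], dtype=float)

    dbe = 1.0 + (2.0 * c - h + n + p) / 2.0
    dbe_o = dbe - o
    dbe_ai = 1.0 + c - o - s - 0.5 * (h + n + p)

    ai_num = 1.0 + c - 0.5 * o - s - 0.5 * (n + p + h)
    ai_den = c - 0.5 * o - n - s - p
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(ai_den > 0, ai_num / ai_den, 0.0)
    ai_mod = np.clip(ai, 0.0, 1.0)

    nosc = 4.0 - (4.0 * c + h - 3.0 * n - 2.0 * o + 5.0 * p - 2.0 * s) / c
    gfe = 60.3 - 28.5 * nosc

    km = mass * (14.0 / CH2_MASS)
    nominal = np.round(km) if kendrick_nominal == "round" else np.floor(km)
    if kendrick_nominal not in ("round", "floor"):
        raise ValueError(f"unknown kendrick_nominal {kendrick_nominal!r}")
    kdefect = nominal - km

    out = pd.DataFrame(
        {
            "mass": mass,
            "C": c.astype(int),
            "kdefect_CH2": kdefect,
            "o_c": o / c,
            "h_c": h / c,
            "n_c": n / c,
            "p_c": p / c,
            "s_c": s / c,
            "ai_mod": ai_mod,
            "dbe": dbe,
            "dbe_o": dbe_o,
            "dbe_ai": dbe_ai,
            "nosc": nosc,
            "gfe": gfe,
        },
        index=pd.Index(ids, name="id"),
    )
    if y_met is not None:
        out["y_met"] = y_met(out)
    return out
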