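"""Run configuration: every tunable threshold, seed and repeat count.

The file format is flat ``key = value`` lines with dotted namespaces
(``icer.ratio = 0.8``); ``#`` starts a comment. Defaults are the
protocol's printed values. Every parameter is validated against its
documented range at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class RunConfig:
    # trait / transformation layer
    trans_tolerance_da: float = 0.001
    # classification
    fraction_active_above: int = 10
    fraction_inactive_below: int = 1
    labile_hc_cut: float = 1.5
    # assembly
    bnti_n_null: int = 999
    bnti_cut: float = 2.0
    # thermal response
    icer_ratio: float = 0.8
    icer_repeats: int = 999
    icer_min_occupancy: float = 0.30
    icer_p_threshold: float = 0.05
    icer_seed: int = 0
    # dark-matter networks
    idme_rho_min: float = 0.30
    idme_n_nodes: int = 400
    idme_replicates: int = 100
    idme_dark_ratio: str = "half"
    idme_metric: str = "degree"
    idme_min_occupancy: float = 0.30
    idme_seed: int = 0
    # bipartite specialization
    h2_rho_cut: float = 0.50
    h2_weight_scale: int = 100_000
    h2_min_occupancy: float = 0.30
    h2_n_null: int = 999
    h2_seed: int = 0

    _RANGES = {
        "trans_tolerance_da": (0.0, 1.0),
        "labile_hc_cut": (0.0, 5.0),
        "bnti_n_null": (99, 100_000),
        "bnti_cut": (0.0, 10.0),
        "icer_ratio": (0.0, 1.0),
        "icer_repeats": (1, 100_000),
        "icer_min_occupancy": (0.0, 1.0),
        "icer_p_threshold": (0.0, 1.0),
        "idme_rho_min": (0.0, 1.0),
        "idme_n_nodes": (4, 100_000),
        "idme_replicates": (1, 100_000),
        "idme_min_occupancy": (0.0, 1.0),
        "h2_rho_cut": (0.0, 1.0),
        "h2_weight_scale": (1, 10**9),
        "h2_min_occupancy": (0.0, 1.0),
        "h2_n_null": (99, 100_000),
    }

    _STRICT_LOWER = ("trans_tolerance_da", "icer_ratio", "icer_p_threshold")
    _STRICT_UPPER = ("icer_ratio",)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
            if name in self._STRICT_LOWER and v <= lo:
                raise ValueError(f"{name} must be > {lo}")
            if name in self._STRICT_UPPER and v >= hi:
                raise ValueError(f"{name} must be < {hi}")
        if self.idme_dark_ratio not in ("half", "observed"):
            try:
                r = float(self.idme_dark_ratio)
            except (TypeError, ValueError):
                raise ValueError("idme_dark_ratio must be 'half', 'observed' or a fraction")
            if not 0 < r < 1:
                raise ValueError("idme_dark_ratio fraction must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {raw.rstrip()!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                attr = key.replace(".", "_")
                if attr not in types:
                    raise ValueError(f"unknown config key {key!r}")
                values[attr] = casts.get(types[attr], str)(val)
        return cls(**values)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name.replace('_', '.', 1)} = {getattr(self, f.name)}\n")
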