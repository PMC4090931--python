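"""The histomorphometry report: every static, dynamic and cellular measurement.

Field naming follows standard histomorphometric nomenclature (BV/TV, Tb.Th,
sLS/BS, MS/BS, MAR, BFR, ...) flattened to valid identifiers.  A value of
``None`` means *not measurable* (zero denominator, e.g. no labeled surface),
which is deliberately distinct from a measured 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

__all__ = ["HistomorphometryReport", "MEASUREMENT_UNITS"]

#: units for every measurement, in report order
MEASUREMENT_UNITS: dict[str, str] = {
    # static
    "bv_tv": "%",
    "tb_th": "um",
    "tb_n": "/mm",
    "tb_sp": "um",
    # dynamic
    "l2_bs": "%",
    "l1_bs": "%",
    "l2_only_bs": "%",
    "l1_only_bs": "%",
    "sls_bs": "%",
    "dls_bs": "%",
    "ls_bs": "%",
    "ms_bs": "%",
    "sls_ls": "%",
    "dls_ls": "%",
    "dls_sls": "%",
    "ir_l_th": "um",
    "mar": "um/day",
    "bfr": "um^3/um^2/day",
    # cellular
    "ap_bs": "%",
    "ap_l2_bs": "%",
    "ap_only_bs": "%",
    "trap_bs": "%",
    "trap_l2_bs": "%",
    "trap_only_bs": "%",
    "trap_tv": "%",
    "trap_on_trap": "%",
}

_FIELD_NAMES = list(MEASUREMENT_UNITS)


@dataclass
class HistomorphometryReport:
    """All Table-style measurements for one section / ROI, plus provenance."""

    # static
    bv_tv: Optional[float] = None
    tb_th: Optional[float] = None
    tb_n: Optional[float] = None
    tb_sp: Optional[float] = None
    # dynamic
    l2_bs: Optional[float] = None
    l1_bs: Optional[float] = None
    l2_only_bs: Optional[float] = None
    l1_only_bs: Optional[float] = None
    sls_bs: Optional[float] = None
    dls_bs: Optional[float] = None
    ls_bs: Optional[float] = None
    ms_bs: Optional[float] = None
    sls_ls: Optional[float] = None
    dls_ls: Optional[float] = None
    dls_sls: Optional[float] = None
    ir_l_th: Optional[float] = None
    mar: Optional[float] = None
    bfr: Optional[float] = None
    # cellular
    ap_bs: Optional[float] = None
    ap_l2_bs: Optional[float] = None
    ap_only_bs: Optional[float] = None
    trap_bs: Optional[float] = None
    trap_l2_bs: Optional[float] = None
    trap_only_bs: Optional[float] = None
    trap_tv: Optional[float] = None
    trap_on_trap: Optional[float] = None
    #: run configuration snapshot: pixel size, site, label interval, ...
    provenance: dict[str, Any] = field(default_factory=dict)

    def measurements(self) -> dict[str, Optional[float]]:
        """Measurement name -> value (None = absent), in canonical order."""
        return {name: getattr(self, name) for name in _FIELD_NAMES}

    def update(self, values: dict[str, Optional[float]]) -> None:
        for k, v in values.items():
            if k not in MEASUREMENT_UNITS:
                raise KeyError(f"unknown measurement {k!r}")
            setattr(self, k, v)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = dict(self.measurements())
        d["provenance"] = self.provenance
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "HistomorphometryReport":
        kwargs = {k: d.get(k) for k in _FIELD_NAMES}
        return cls(provenance=d.get("provenance", {}), **kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HistomorphometryReport":
        return cls.from_dict(json.loads(text))

    def rows(self) -> list[tuple[str, Optional[float], str]]:
        """(name, value, units) triples for tabular serialization."""
        return [(n, getattr(self, n), MEASUREMENT_UNITS[n]) for n in _FIELD_NAMES]
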