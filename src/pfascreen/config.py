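"""Run configuration: every tolerance, window and toggle in one place.

Defaults are the published operating point of the workflow this package
implements: 0.01 Da mass window, 2% CCS window, mass-defect flag window
[-0.11, 0.12], negative polarity, order flagging on, 5x field-blank ratio,
and the CCS-vs-m/z ceiling CCS = 0.1799 m/z + 96.308.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .io_tables import ColumnMapping, SAMPLE_ROLES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    mz_tol_da: float = 0.01
    ccs_tol_pct: float = 2.0
    md_window: tuple[float, float] = (-0.11, 0.12)
    flag_order: bool = True
    polarity: str = "Neg"
    blank_ratio: float = 5.0
    trendline_slope: float = 0.1799
    trendline_intercept: float = 96.308
    kmd_tol: float = 0.005
    columns: ColumnMapping = field(default_factory=ColumnMapping)
    sample_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mz_tol_da <= 0:
            raise ValueError("mz_tol_da must be > 0")
        if self.ccs_tol_pct <= 0:
            raise ValueError("ccs_tol_pct must be > 0")
        if self.kmd_tol <= 0:
            raise ValueError("kmd_tol must be > 0")
        if self.blank_ratio <= 0:
            raise ValueError("blank_ratio must be > 0")
        lo, hi = self.md_window
        if not lo < hi:
            raise ValueError("md_window must satisfy lo < hi")
        self.md_window = (float(lo), float(hi))
        for sid, role in self.sample_roles.items():
            if role not in SAMPLE_ROLES:
                raise ValueError(f"unknown role {role!r} for sample {sid!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        cols = data.pop("columns", None)
        if isinstance(cols, Mapping):
            data["columns"] = ColumnMapping(**cols)
        md = data.get("md_window")
        if md is not None:
            data["md_window"] = tuple(md)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["md_window"] = list(self.md_window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
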