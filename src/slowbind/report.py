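"""Structured analysis report with per-constant provenance.

Every numeric constant in a report carries a provenance tag: ``fitted``
(estimated from the data in this run), ``assumed`` (a configuration value
standing in for an unmeasured quantity), ``derived`` (computed from other
constants in the report) or ``config`` (an operational setting). A report
containing an untagged constant fails schema validation. The derived
block is recomputable from the stored elementary constants, which is
checked on construction so that a report can always be audited offline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .models import derive_constants

__all__ = ["TaggedValue", "AnalysisReport"]

Provenance = Literal["fitted", "assumed", "derived", "config"]


class TaggedValue(BaseModel):
    """A reported constant: value, optional SE, units and provenance."""

    value: float
    se: Optional[float] = None
    units: str
    provenance: Provenance


class AnalysisReport(BaseModel):
    """Full result of the slow-binding inhibition analysis pipeline."""

    reversible_mechanism: str
    sbi_type: str
    constants: Dict[str, TaggedValue]
    occupancy: List[dict] = []  # entries: {"I_molar": ..., "FO_percent": ...}
    warnings: List[str] = []
    config_fingerprint: str = ""
    seed: Optional[int] = None
    software: str = "slowbind"

    @model_validator(mode="after")
    def _derived_recomputable(self) -> "AnalysisReport":
        """Derived constants must follow from the stored elementary ones."""
        c = self.constants
        needed = ("Ki", "k_plus4", "k_minus4", "k_plus3")
        derived = ("Ki_star", "k_minus3", "tau", "koff_overall", "t_half_diss")
        if all(k in c for k in needed) and any(k in c for k in derived):
            rc = derive_constants(
                c["Ki"].value, c["k_plus4"].value, c["k_minus4"].value,
                c["k_plus3"].value,
            )
            for name in derived:
                if name in c and not np.isclose(
                    c[name].value, getattr(rc, name), rtol=1e-6
                ):
                    raise ValueError(
                        f"derived constant {name}={c[name].value!r} is not "
                        "reproducible from the stored elementary constants"
                    )
        return self

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.model_dump(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        return cls.model_validate(json.loads(Path(path).read_text()))
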