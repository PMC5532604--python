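"""Cross-validation of the input bundle before a model run.

Checks that every animal appearing in the focal table has covariates, and
reports animals absent from the pedigree (they are treated as founders with
a warning rather than an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data import FocalTable
from .pedigree import Pedigree

__all__ = ["ValidationReport", "validate_inputs"]


@dataclass
class ValidationReport:
    n_focals: int
    n_animals: int
    warnings: list[str] = field(default_factory=list)
    founders_by_default: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return True  # errors raise; a constructed report passed


def validate_inputs(
    focal: FocalTable,
    covariates: pd.DataFrame | None = None,
    pedigree: Pedigree | None = None,
) -> ValidationReport:
    """Cross-check animal ids across the focal, covariate and pedigree tables.

    Raises ``ValueError`` naming offenders when a focal animal lacks
    covariates; animals missing from the pedigree are recorded as
    founders-by-default warnings.
    """
    animals = sorted(set(focal.animal_id))
    report = ValidationReport(n_focals=focal.n_obs, n_animals=len(animals))

    if covariates is not None:
        cov_ids = set(covariates["animal_id"].astype(str))
        missing = [a for a in animals if a not in cov_ids]
        if missing:
            raise ValueError(
                f"animals present in focal data but missing covariates: {missing}"
            )
        extra = sorted(cov_ids - set(animals))
        if extra:
            report.warnings.append(
                f"{len(extra)} covariate rows for animals without focal data"
            )
    if pedigree is not None:
        ped_ids = set(pedigree.ids)
        absent = [a for a in animals if a not in ped_ids]
        if absent:
            report.founders_by_default = absent
            report.warnings.append(
                f"{len(absent)} animals absent from pedigree; treated as founders"
            )
    return report
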