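"""Model specifications and design-matrix assembly.

The texture-based progression models combine up to four blocks of features:

* ``TBT`` — the 64 baseline texture descriptors (or a compartment subset);
* ``dTBT`` — their 24-month changes (follow-up minus baseline);
* adjustment covariates: ``CLIN`` (age, sex, BMI), ``BIO`` (uCTX-II, sNTXI,
  sHA, entered on the log scale), ``KL`` and ``JSNM`` radiological grades.

The canonical specifications, written "left-hand block <- adjusted for
right-hand blocks", are:

=====  =======================  =============================
name   texture blocks           adjustment
=====  =======================  =============================
M1     TBT                      CLIN + KL + JSNM  (reference)
M2     dTBT                     CLIN + KL + JSNM
M3     TBT + dTBT               CLIN + KL + JSNM
M4     TBT + dTBT               (none)
M5     TBT + dTBT               BIO + CLIN + KL + JSNM
M6     TBT + dTBT, medial       CLIN + KL + JSNM
M7     TBT + dTBT, lateral      CLIN + KL + JSNM
M8     TBT + dTBT, central      CLIN + KL + JSNM
M4B    TBT + dTBT               CLIN + BIO
=====  =======================  =============================

Texture blocks are LASSO-penalised at fit time; adjustment covariates are
forced in (never penalised). Continuous features are standardised by
training-fold statistics at fit time, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .texture import DEFAULT_COMPARTMENT_COLS, descriptor_names

__all__ = ["ModelSpec", "MODEL_SPECS", "assemble_features", "texture_columns"]

_CLIN = ("age", "sex", "bmi")
_BIO = ("uctx2", "sntx1", "sha")
_ADJUST_BLOCKS = ("CLIN", "BIO", "KL", "JSNM")
_TEXTURE_BLOCKS = ("TBT", "dTBT")


@dataclass(frozen=True)
class ModelSpec:
    """One model formula: texture blocks, compartment, forced adjustment."""

    name: str
    texture_blocks: tuple[str, ...] = ("TBT", "dTBT")
    compartment: str = "all"
    adjust_blocks: tuple[str, ...] = ("CLIN", "KL", "JSNM")

    def __post_init__(self) -> None:
        if not self.texture_blocks:
            raise ParameterError("at least one texture block is required")
        for b in self.texture_blocks:
            if b not in _TEXTURE_BLOCKS:
                raise ParameterError(f"unknown texture block {b!r}")
        for b in self.adjust_blocks:
            if b not in _ADJUST_BLOCKS:
                raise ParameterError(f"unknown adjustment block {b!r}")
        if self.compartment not in ("all", "medial", "central", "lateral"):
            raise ParameterError(f"unknown compartment {self.compartment!r}")

    def describe(self) -> str:
        lhs = " + ".join(self.texture_blocks)
        if self.compartment != "all":
            lhs += f" [{self.compartment}]"
        rhs = " + ".join(self.adjust_blocks)
        return f"{lhs} <- {rhs}" if rhs else lhs


#: The canonical model registry (M1 is the reference model).
MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", ("TBT",), "all", ("CLIN", "KL", "JSNM")),
    "M2": ModelSpec("M2", ("dTBT",), "all", ("CLIN", "KL", "JSNM")),
    "M3": ModelSpec("M3", ("TBT", "dTBT"), "all", ("CLIN", "KL", "JSNM")),
    "M4": ModelSpec("M4", ("TBT", "dTBT"), "all", ()),
    "M5": ModelSpec("M5", ("TBT", "dTBT"), "all", ("BIO", "CLIN", "KL", "JSNM")),
    "M6": ModelSpec("M6", ("TBT", "dTBT"), "medial", ("CLIN", "KL", "JSNM")),
    "M7": ModelSpec("M7", ("TBT", "dTBT"), "lateral", ("CLIN", "KL", "JSNM")),
    "M8": ModelSpec("M8", ("TBT", "dTBT"), "central", ("CLIN", "KL", "JSNM")),
    "M4B": ModelSpec("M4B", ("TBT", "dTBT"), "all", ("CLIN", "BIO")),
}


def _compartment_rois(compartment: str) -> list[int]:
    """ROI ids of one compartment under the default 2x8 grid (column tags)."""
    if compartment == "all":
        return list(range(16))
    return [r for r in range(16) if DEFAULT_COMPARTMENT_COLS[r % 8] == compartment]


def texture_columns(block: str, compartment: str = "all") -> list[str]:
    """Design-matrix column names of one texture block, compartment-restricted."""
    rois = set(_compartment_rois(compartment))
    prefix = "tbt0" if block == "TBT" else "dtbt"
    return [
        name
        for name, roi in zip(descriptor_names(prefix), [i // 4 for i in range(64)])
        if roi in rois
    ]


def assemble_features(
    records: pd.DataFrame,
    spec: ModelSpec,
    log_biomarkers: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the design matrix, response and penalty mask for one model.

    *records* must carry the cohort schema columns plus a boolean/0-1
    ``case`` column (the scenario response). Returns ``(X, y, penalized)``
    where ``penalized`` marks the texture columns (True) versus the forced
    adjustment covariates (False). Column order is
    ``[TBT | dTBT | CLIN | BIO | KL | JSNM]``.

    Raises :class:`DataError` naming the knee and column on missing values.
    """
    if "case" not in records.columns:
        raise DataError("records lack the 'case' response column; apply a scenario first")

    needed: list[str] = []
    for block in spec.texture_blocks:
        cols = texture_columns(block, spec.compartment)
        needed += cols if block == "TBT" else [
            c.replace("dtbt", p, 1) for c in cols for p in ("tbt0", "tbt24")
        ]
    if "CLIN" in spec.adjust_blocks:
        needed += list(_CLIN)
    if "BIO" in spec.adjust_blocks:
        needed += list(_BIO)
    needed += [b.lower() for b in ("KL", "JSNM") if b in spec.adjust_blocks]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise DataError(f"records lack required columns {missing[:5]}")

    columns: dict[str, np.ndarray] = {}
    penalized: list[bool] = []

    for block in _TEXTURE_BLOCKS:
        if block not in spec.texture_blocks:
            continue
        for col in texture_columns(block, spec.compartment):
            if block == "TBT":
                columns[col] = records[col].to_numpy(dtype=float)
            else:
                base = col.replace("dtbt", "tbt0", 1)
                follow = col.replace("dtbt", "tbt24", 1)
                columns[col] = records[follow].to_numpy(dtype=float) - records[
                    base
                ].to_numpy(dtype=float)
            penalized.append(True)

    if "CLIN" in spec.adjust_blocks:
        for col in _CLIN:
            columns[col] = records[col].to_numpy(dtype=float)
            penalized.append(False)
    if "BIO" in spec.adjust_blocks:
        for col in _BIO:
            vals = records[col].to_numpy(dtype=float)
            if log_biomarkers:
                if np.any(vals <= 0):
                    raise DataError(f"biomarker {col!r} must be positive for log transform")
                columns[f"log_{col}"] = np.log(vals)
            else:
                columns[col] = vals
            penalized.append(False)
    if "KL" in spec.adjust_blocks:
        columns["kl"] = records["kl"].to_numpy(dtype=float)
        penalized.append(False)
    if "JSNM" in spec.adjust_blocks:
        columns["jsnm"] = records["jsnm"].to_numpy(dtype=float)
        penalized.append(False)

    X = pd.DataFrame(columns, index=records.index)

    bad = np.argwhere(~np.isfinite(X.to_numpy()))
    if len(bad):
        i, j = bad[0]
        knee = records["knee_id"].iloc[i] if "knee_id" in records.columns else records.index[i]
        raise DataError(f"non-finite value for knee {knee!r}, column {X.columns[j]!r}")

    y = records["case"].to_numpy().astype(int)
    return X, y, np.asarray(penalized)
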