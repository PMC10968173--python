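"""High-level progression-risk model: cohort in, fitted results out.

:class:`ProgressionModel` is the package's front door for tabular work. It
binds a labelled cohort table, a model specification (M1-M8 or a custom
:class:`~tbtoa.design.ModelSpec`) and a case/control scenario, assembles the
design matrix, and exposes the two things an analyst wants: a single
penalised fit (:meth:`fit`) and the repeated cross-validated performance
(:meth:`cross_validate`).

Example
-------
>>> from tbtoa import CohortSpec, generate_cohort, label_cohort
>>> from tbtoa.progression import ProgressionModel
>>> cohort = label_cohort(generate_cohort(CohortSpec(n_knees=597, seed=7)))
>>> model = ProgressionModel(cohort, spec="M3", scenario="primary")
>>> res = model.fit()
>>> print(res.summary())                        # doctest: +SKIP
>>> cvres = model.cross_validate()              # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import MODEL_SPECS, ModelSpec, assemble_features
from .evaluation import (
    CVConfig,
    EvaluationResult,
    repeated_cv_evaluate,
    _scenario_frame,
)
from .exceptions import ParameterError
from .labels import label_cohort
from .regression import PenalizedLogit, PenalizedLogitResults

__all__ = ["ProgressionModel"]


class ProgressionModel:
    """A texture-based progression model bound to one cohort and scenario."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        spec: str | ModelSpec = "M3",
        scenario: str = "primary",
    ) -> None:
        if isinstance(spec, str):
            if spec not in MODEL_SPECS:
                raise ParameterError(
                    f"unknown model {spec!r}; choose from {sorted(MODEL_SPECS)}"
                )
            spec = MODEL_SPECS[spec]
        self.spec = spec
        self.scenario = scenario
        if "group" not in cohort.columns:
            cohort = label_cohort(cohort)
        self.cohort = cohort
        self.frame = _scenario_frame(cohort, scenario)
        X, y, penalized = assemble_features(self.frame, spec)
        self.exog = X
        self.endog = y
        self.penalized = penalized

    @classmethod
    def from_csv(
        cls, path: str | Path, spec: str | ModelSpec = "M3", scenario: str = "primary"
    ) -> "ProgressionModel":
        """Build from a cohort CSV (the schema written by the generator)."""
        return cls(pd.read_csv(path), spec=spec, scenario=scenario)

    @property
    def n_cases(self) -> int:
        return int(self.endog.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.endog) - self.endog.sum())

    def fit(self, lambda_grid: np.ndarray | None = None) -> PenalizedLogitResults:
        """Single penalised fit on the full scenario cohort."""
        model = PenalizedLogit(self.endog, self.exog, penalized=self.penalized)
        return model.fit(lambda_grid=lambda_grid)

    def cross_validate(
        self,
        cv: CVConfig = CVConfig(),
        reference: EvaluationResult | None = None,
        lambda_grid: np.ndarray | None = None,
        permute_labels: bool = False,
    ) -> EvaluationResult:
        """Repeated stratified k-fold evaluation of this model."""
        return repeated_cv_evaluate(
            self.cohort,
            self.spec,
            self.scenario,
            cv,
            reference=reference,
            lambda_grid=lambda_grid,
            permute_labels=permute_labels,
        )
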