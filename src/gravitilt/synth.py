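"""Synthetic response tables with the study's statistical structure.

The default design emulates the hyper-gravity roll-tilt study the modified
shear model was fit to: roll tilts of -20, 10, 20 and 40 degrees crossed
with gravito-inertial levels of 1, 1.5 and 2 G, haptic reports with a
per-subject intercept and independent trial noise, and 48 reports per
condition (12 subjects x 4 repetitions; the split is configurable since
only the product is reported).

    reported = rho_i + K * sin(theta) * [1 + M * (G - 1)] + eps
    rho_i ~ Normal(0, subject_intercept_sd^2)   (one draw per subject)
    eps   ~ Normal(0, trial_noise_sd^2)          (one draw per trial)

Gaussian components match the assumptions of the hierarchical regression
the tables are meant to exercise.  The true variance components of the
original dataset are unpublished; the defaults are for recovery and power
studies, not a claim about the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import RESPONSE_COLUMNS
from .static_models import StaticModelParams, TiltCondition, modified_shear_roll

__all__ = ["SynthDesign", "generate"]


@dataclass(frozen=True)
class SynthDesign:
    """Design of a synthetic roll-tilt response experiment."""

    angles_deg: tuple = (-20.0, 10.0, 20.0, 40.0)
    g_levels: tuple = (1.0, 1.5, 2.0)
    n_subjects: int = 12
    reps_per_condition: int = 4
    subject_intercept_sd: float = 3.0   # deg
    trial_noise_sd: float = 4.0         # deg
    true_K: float = 64.6
    true_M: float = 0.26
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.reps_per_condition < 1:
            raise ValueError("reps_per_condition must be >= 1")
        if self.subject_intercept_sd < 0 or self.trial_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def n_per_condition(self) -> int:
        return self.n_subjects * self.reps_per_condition


def generate(design: SynthDesign = SynthDesign()) -> pd.DataFrame:
    """Draw one synthetic response table; deterministic given the seed."""
    rng = np.random.default_rng(design.seed)
    params = StaticModelParams(K=design.true_K, M=design.true_M, rho=0.0)
    rho = rng.normal(0.0, design.subject_intercept_sd, size=design.n_subjects)

    rows = []
    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        for angle in design.angles_deg:
            for g in design.g_levels:
                mean = modified_shear_roll(TiltCondition("roll", angle, g), params)
                noise = rng.normal(0.0, design.trial_noise_sd,
                                   size=design.reps_per_condition)
                for rep in range(design.reps_per_condition):
                    rows.append((sid, "roll", float(angle), float(g),
                                 float(rho[i] + mean + noise[rep]), rep + 1))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
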