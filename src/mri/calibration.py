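"""Calibration of the expression-to-flux constant C.

C (mmol/gDCW/h per expression unit) is the single global scalar that maps
expression levels onto flux capacity.  It is fitted per carbon source by a
sensitivity sweep: for each candidate C, growth is predicted for every
strain by maximizing biomass flux under the expression-capacity constraints
(with free slacks, so expression only limits, never forces, flux) and the
direction-exclusivity binaries; the C minimizing the mean relative growth
error against measured rates is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .milp import MediumSpec, apply_medium, build_mri_problem, _solve
from .transform import IrreversibleModel

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "predict_growth_rate",
    "calibrate_C",
    "default_C_grid",
]


@dataclass
class CalibrationCurve:
    """Growth-error profile over a grid of candidate C values."""

    C_grid: np.ndarray
    errors: np.ndarray  # mean relative (or absolute) growth error per C
    optimum: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.C_grid) <= 0):
            raise ValueError("C grid must be strictly increasing")
        if np.any(self.errors < 0):
            raise ValueError("errors must be >= 0")


def predict_growth_rate(
    model: IrreversibleModel,
    profile,
    medium: MediumSpec,
    C: float,
) -> float:
    """Maximum biomass flux (1/h) under expression-capacity constraints.

    The usage slacks are free (alpha_j >= 0), so each gene's constraint
    caps the summed flux of its reactions at E_j * C without forcing any
    usage; the z indicators play no role and are relaxed.  Direction
    exclusivity stays integral so cycles cannot feed the biomass optimum.
    """
    base_biomass = model.base.biomass_reaction
    if base_biomass is None:
        raise ValueError("model has no biomass reaction")
    bounded = apply_medium(model, medium)
    problem = build_mri_problem(bounded, profile, C)
    q = problem.usage_vector(base_biomass)
    # biomass throughput: forward copies minus nothing (biomass irreversible
    # in practice; for a split biomass the backward copies would subtract)
    objective = np.zeros(problem.n_vars)
    objective[: problem.n_flux] = -q
    res = _solve(problem, objective, relax_z=True)
    if not res.success:
        raise RuntimeError(
            f"growth prediction failed (status {res.status}): {res.message}"
        )
    return float(-res.fun)


def default_C_grid(profile, n: int = 30, decades: float = 4.0) -> np.ndarray:
    """Log-spaced candidate grid centred scale-free on the data.

    The centre is the flux cap divided by the median expression level, i.e.
    the C at which a median gene's capacity equals the model's flux cap;
    the grid spans ``decades`` decades around it.
    """
    from .milp import FLUX_CAP

    levels = np.array([v for v in profile.values.values() if v > 0])
    if levels.size == 0:
        raise ValueError("profile has no positive expression levels")
    center = FLUX_CAP / np.median(levels)
    half = 10 ** (decades / 2)
    return np.geomspace(center / half, center * half, n)


def calibrate_C(
    model: IrreversibleModel,
    profiles: list,
    phenotypes,
    medium: MediumSpec,
    C_grid,
    relative: bool = True,
) -> CalibrationCurve:
    """Sweep the C grid and pick the growth-error minimum.

    The error at each C is the mean over strains (wild-type and evolved
    alike) of |mu_pred(C) - mu_exp| / mu_exp (or the absolute error with
    ``relative=False``).  Strains without a measured growth rate are
    skipped; no strain with one is an error.  Ties take the smallest C.
    """
    C_grid = np.asarray(list(C_grid), float)
    if C_grid.size == 0:
        raise ValueError("empty C grid")
    measured = [
        (p, phenotypes.get(p.strain_label, "growth_rate")) for p in profiles
    ]
    measured = [(p, mu) for p, mu in measured if mu is not None]
    if not measured:
        raise ValueError("no strains with measured growth rate")

    errors = np.zeros(C_grid.size)
    for k, C in enumerate(C_grid):
        errs = []
        for profile, mu_exp in measured:
            mu_pred = predict_growth_rate(model, profile, medium, float(C))
            err = abs(mu_pred - mu_exp)
            if relative:
                if mu_exp == 0:
                    raise ValueError(
                        f"strain {profile.strain_label}: measured growth 0 "
                        f"is incompatible with relative error"
                    )
                err /= mu_exp
            errs.append(err)
        errors[k] = float(np.mean(errs))
    optimum = float(C_grid[int(np.argmin(errors))])
    return CalibrationCurve(C_grid=C_grid, errors=errors, optimum=optimum)
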