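"""Field-dependent electrical conductivity for electroporated myocardium.

Electroporation opens cell membranes, so tissue conductivity rises with the
local electric-field magnitude. The model used here is the standard one in
tissue-scale electroporation simulations: each tissue carries a baseline
conductivity sigma0, and myocardium additionally follows a monotone sigmoid
transition from sigma0 at low field to ``sigma_factor * sigma0`` at high
field, parameterised by an onset field E_low and a saturation field E_high
(both in V/cm). Non-myocardial tissues (blood, torso bulk, patch) are not
electroporation-responsive in this model and keep their baseline values at
any field strength.

Baseline defaults (myocardium 0.20 S/m, blood 0.70 S/m, torso bulk
0.20 S/m) are literature-typical low-frequency values and, like the sigmoid
parameters, are configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Label, LabeledGrid

DEFAULT_SIGMA0 = {
    Label.MYOCARDIUM: 0.20,
    Label.BLOOD: 0.70,
    Label.TORSO: 0.20,
    Label.PATCH: 0.20,
}


@dataclass(frozen=True)
class ConductivityModel:
    """Baseline conductivities plus the myocardial electroporation sigmoid.

    sigma0: S/m per tissue label.
    sigma_factor: electroporated / baseline conductivity ratio (>= 1);
        setting it to 1 reduces the model to the linear, constant-sigma case.
    E_low_V_per_cm, E_high_V_per_cm: onset and saturation field magnitudes
        of the conductivity transition.
    transition: 'smoothed_heaviside' (cubic smoothstep, exact at both ends)
        or 'logistic' (rescaled so sigma(0) = sigma0 exactly).
    """

    sigma0: dict = field(
        default_factory=lambda: dict(DEFAULT_SIGMA0))
    sigma_factor: float = 2.5
    E_low_V_per_cm: float = 400.0
    E_high_V_per_cm: float = 800.0
    transition: str = "smoothed_heaviside"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma0.values()):
            raise ValueError("all baseline conductivities must be positive")
        if self.sigma_factor < 1.0:
            raise ValueError("sigma_factor must be >= 1")
        if not 0 < self.E_low_V_per_cm < self.E_high_V_per_cm:
            raise ValueError("must satisfy 0 < E_low < E_high")
        if self.transition not in ("smoothed_heaviside", "logistic"):
            raise ValueError(f"unknown transition {self.transition!r}")

    def baseline(self, label: Label | int) -> float:
        lab = Label(label)
        try:
            return self.sigma0[lab]
        except KeyError:
            raise KeyError(f"no baseline conductivity for label {lab.name}")

    def _shape(self, E: np.ndarray) -> np.ndarray:
        """Transition shape s(E) in [0, 1], monotone, s(0) = 0, s(inf) = 1."""
        lo, hi = self.E_low_V_per_cm, self.E_high_V_per_cm
        t = np.clip((np.asarray(E, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
        if self.transition == "smoothed_heaviside":
            return t * t * (3.0 - 2.0 * t)
        # logistic, shifted/rescaled for exact endpoints at E=0 and E->inf
        k = 10.0 / (hi - lo)
        Em = 0.5 * (lo + hi)
        g = 1.0 / (1.0 + np.exp(-k * (np.asarray(E, dtype=float) - Em)))
        g0 = 1.0 / (1.0 + np.exp(k * Em))
        return (g - g0) / (1.0 - g0)


def sigma_of_field(model: ConductivityModel, label: Label | int, E):
    """Conductivity (S/m) of ``label`` tissue at field magnitude ``E`` (V/cm).

    Scalar or array ``E``. Non-myocardium labels return their baseline
    regardless of E; myocardium follows the sigmoid between sigma0 and
    sigma_factor * sigma0.
    """
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 0):
        raise ValueError("field magnitude E must be nonnegative")
    lab = Label(label)
    s0 = model.baseline(lab)
    if lab != Label.MYOCARDIUM or model.sigma_factor == 1.0:
        out = np.full_like(E_arr, s0)
        return float(out) if np.isscalar(E) else out
    out = s0 * (1.0 + (model.sigma_factor - 1.0) * model._shape(E_arr))
    return float(out) if np.isscalar(E) else out


def conductivity_field(
    model: ConductivityModel, grid: LabeledGrid, E_per_cell: np.ndarray
) -> np.ndarray:
    """Per-cell conductivities (S/m) for the whole grid.

    ``E_per_cell`` is the field magnitude in V/cm on ``grid.cell_shape``.
    Non-conductive cells (ELECTRODE, OUTSIDE) get 0 and are excluded from
    assembly; blood/torso/patch cells are field-independent.
    """
    E = np.asarray(E_per_cell, dtype=float)
    if E.shape != grid.cell_shape:
        raise ValueError(
            f"E_per_cell shape {E.shape} does not match cell shape "
            f"{grid.cell_shape}"
        )
    if np.any(E < 0):
        raise ValueError("field magnitude E must be nonnegative")
    sigma = np.zeros(grid.cell_shape, dtype=float)
    for lab in (Label.BLOOD, Label.TORSO, Label.PATCH):
        if lab in model.sigma0:
            sigma[grid.labels == lab] = model.sigma0[lab]
    myo = grid.labels == Label.MYOCARDIUM
    if myo.any():
        sigma[myo] = sigma_of_field(model, Label.MYOCARDIUM, E[myo])
    return sigma
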