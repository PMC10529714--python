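"""One-off calibration of the packaged default composition.

The shipped scenario quotes typical effective properties
(rho = 1064.5 kg/m^3, cp = 3535.5 J/(kg K), k = 0.47 W/(m K)) but not the
composition behind them. This script solves for the water/protein/fat
fractions (carbohydrate and ash pinned at plausible values for a salted
lean pork product) plus the conductivity mixing weight g so that the three
mixture-rule estimators reproduce those typical values exactly. The
result is frozen into ``coldspot.properties.DEFAULT_COMPOSITION`` and
``DEFAULT_G``.

Run from the repository root::

    python scripts/calibrate_composition.py
"""

import numpy as np
from scipy.optimize import fsolve

from coldspot.properties import (
    CHOI_OKOS_20C,
    Composition,
    estimate_all,
)

TARGET = dict(rho=1064.5, cp=3535.5, k=0.47)
X_CARB = 0.008
X_ASH = 0.034


def residuals(theta):
    x_w, x_p, g = theta
    x_f = 1.0 - x_w - x_p - X_CARB - X_ASH
    comp = Composition(
        water=x_w, protein=x_p, fat=x_f, carbohydrate=X_CARB, ash=X_ASH
    )
    props = estimate_all(comp, CHOI_OKOS_20C, g=min(max(g, 0.0), 1.0))
    return [
        props.rho - TARGET["rho"],
        props.cp - TARGET["cp"],
        props.k - TARGET["k"],
    ]


def main():
    theta0 = np.array([0.715, 0.195, 0.35])
    theta, info, ier, msg = fsolve(residuals, theta0, full_output=True)
    if ier != 1:
        raise SystemExit(f"calibration failed: {msg}")
    x_w, x_p, g = theta
    x_f = 1.0 - x_w - x_p - X_CARB - X_ASH
    comp = Composition(
        water=round(x_w, 6),
        protein=round(x_p, 6),
        fat=round(1.0 - round(x_w, 6) - round(x_p, 6) - X_CARB - X_ASH, 6),
        carbohydrate=X_CARB,
        ash=X_ASH,
    )
    props = estimate_all(comp, CHOI_OKOS_20C, g=round(g, 6))
    print(f"water        = {comp.water:.6f}")
    print(f"protein      = {comp.protein:.6f}")
    print(f"fat          = {comp.fat:.6f}")
    print(f"carbohydrate = {comp.carbohydrate:.6f}")
    print(f"ash          = {comp.ash:.6f}")
    print(f"g            = {round(g, 6):.6f}")
    print(f"-> rho = {props.rho:.3f}  (target {TARGET['rho']})")
    print(f"-> cp  = {props.cp:.3f}  (target {TARGET['cp']})")
    print(f"-> k   = {props.k:.5f}  (target {TARGET['k']})")
    for key, got in (("rho", props.rho), ("cp", props.cp), ("k", props.k)):
        rel = abs(got - TARGET[key]) / TARGET[key]
        assert rel < 5e-3, (key, rel)


if __name__ == "__main__":
    main()
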