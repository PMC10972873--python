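#!/usr/bin/env python
"""Map the weight-distribution parameter sigma_star to the synaptic balance b.

The signed coefficient of variation sigma_star = sigma/mu of the reservoir's
normal weight law determines the excitatory-inhibitory balance
b = (S+ - S-)/S analytically, b = erf(1/(sqrt(2) sigma_star)).  This script
tabulates the curve over the studied range |sigma_star| in [1e-2, 1e3] and
verifies it against the empirical sign census of actually-built reservoirs.

Writes results/balance_curve.csv and prints the verification summary.
"""

import numpy as np
import pandas as pd

from rbnres.network import (
    ReservoirSpec,
    balance_of_sigma_star,
    build_reservoir,
    summarize_balance,
)

OUT = "results/balance_curve.csv"


def main() -> None:
    mags = np.logspace(-2, 3, 41)
    rows = []
    for sign in (-1, 1):
        for mag in mags:
            sigma = sign * mag
            rows.append(dict(sigma_star=sigma, b=balance_of_sigma_star(sigma)))
    df = pd.DataFrame(rows)

    # empirical spot checks: built reservoirs at a few sigma_star values
    checks = []
    for sigma in (-10.0, -2.0, 2.0, 30.0):
        res = build_reservoir(ReservoirSpec(N=2000, K=8, sigma_star=sigma, seed=0))
        s = summarize_balance(res)
        se = np.sqrt((1 - s.b_analytic**2) / s.S)
        checks.append(dict(sigma_star=sigma, b_analytic=s.b_analytic,
                           b_empirical=s.b_empirical, binomial_se=se,
                           within_4se=abs(s.b_empirical - s.b_analytic) < 4 * se))
    checks = pd.DataFrame(checks)

    import pathlib
    pathlib.Path("results").mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(f"wrote {OUT} ({len(df)} grid points)")
    print("\nEmpirical sign census vs analytic balance (N=2000, K=8):")
    print(checks.to_string(index=False))
    print("\nAnchor: sigma_star = -10 maps to b ="
          f" {balance_of_sigma_star(-10.0):+.4f} (about -0.08).")


if __name__ == "__main__":
    main()
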