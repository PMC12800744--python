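"""Literal per-trial transliteration of the belief-update equations.

Kept deliberately independent of the production filter: plain floats, one
assignment per equation, no vectorisation and no shared helpers, so it can
serve as the oracle the production trajectories are checked against.
"""

import math


def filter_oracle(u_seq, kappa2, omega2, theta, phi3, m3,
                  mu2_0, sigma2_0, mu3_0, sigma3_0, mean_reverting):
    mu2 = mu2_0
    sigma2 = sigma2_0
    mu3 = mu3_0
    sigma3 = sigma3_0
    rows = []
    for u in u_seq:
        # predictions
        muhat2 = mu2
        if mean_reverting:
            muhat3 = mu3 + phi3 * (m3 - mu3)
        else:
            muhat3 = mu3
        muhat1 = 1.0 / (1.0 + math.exp(-muhat2))
        # predicted environmental volatility and level-2 precisions
        v2 = math.exp(kappa2 * muhat3 + omega2)
        pihat2 = 1.0 / (sigma2 + v2)
        delta1 = u - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        mu2 = muhat2 + delta1 / pi2
        # volatility prediction error
        delta2 = (1.0 / pi2 + (mu2 - muhat2) ** 2) * pihat2 - 1.0
        # third level
        pihat3 = 1.0 / (sigma3 + theta)
        w2 = v2 * pihat2
        pi3 = pihat3 + (kappa2 ** 2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0.0:
            raise ArithmeticError("negative precision")
        mu3 = muhat3 + (kappa2 / 2.0) * (w2 / pi3) * delta2
        sigma2 = 1.0 / pi2
        sigma3 = 1.0 / pi3
        rows.append({
            "muhat1": muhat1, "muhat2": muhat2, "mu2": mu2,
            "pihat2": pihat2, "pi2": pi2, "muhat3": muhat3, "mu3": mu3,
            "pihat3": pihat3, "pi3": pi3, "delta1": delta1,
            "delta2": delta2, "v2": v2, "gamma2": kappa2 * w2,
        })
    return rows
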