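"""Independent oracles used by the tests.

The extinction probability of a continuous-time multi-type branching process
is computed here from the offspring generating-function fixed point by
iteration — a route completely independent of the mean-matrix eigenvalue
analysis it is used to check.
"""

import numpy as np


def mtbp_extinction_prob(birth, death, sigma, max_iter=200000, tol=1e-13):
    """Extinction probability per starting type for a continuous-time MTBP.

    Type i branches at total rate r_i = birth_i + death_i + sum_j sigma_ij;
    the embedded offspring distribution replaces an individual by two of its
    own type (birth), none (death), or one of type j (switch).  The
    extinction vector q is the minimal fixed point of

        q_i = (birth_i q_i^2 + death_i + sum_j sigma_ij q_j) / r_i,

    found by monotone iteration from q = 0.
    """
    birth = np.asarray(birth, dtype=float)
    death = np.asarray(death, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    r = birth + death + sigma.sum(axis=1)
    if np.any(r <= 0):
        raise ValueError("every type needs a positive total branching rate")
    q = np.zeros_like(birth)
    for _ in range(max_iter):
        q_new = (birth * q ** 2 + death + sigma @ q) / r
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    return q
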