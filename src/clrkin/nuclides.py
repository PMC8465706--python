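"""Physical decay constants for the iodine theranostic pair.

Half-lives are conventional nuclide data; the decay constant is
``lambda = ln 2 / T_half`` with time measured in hours throughout the
package.  Both values are plain module constants so a user modelling a
different label (or wanting a different evaluation of the half-life) can
pass an explicit ``lam`` wherever one is accepted.
"""

import math

#: Half-life of 131-I in days (therapy label).
T_HALF_I131_DAYS = 8.0252

#: Half-life of 124-I in days (PET imaging label).
T_HALF_I124_DAYS = 4.176


def decay_constant(t_half_days: float) -> float:
    """Decay constant [1/h] from a half-life in days."""
    if t_half_days <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / (t_half_days * 24.0)


#: Decay constant of 131-I [1/h] (~3.5988e-3).
LAMBDA_I131 = decay_constant(T_HALF_I131_DAYS)

#: Decay constant of 124-I [1/h].
LAMBDA_I124 = decay_constant(T_HALF_I124_DAYS)
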