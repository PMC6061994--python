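"""Independent closed-form oracles used by the test suite.

The double-pendulum dynamics below are the textbook relative-angle closed
form (mass matrix, Coriolis, and gravity terms written out by hand from the
Lagrangian), coded without reference to the package's spatial-algebra
implementation.
"""

import numpy as np

GRAVITY = 9.80665


def double_pendulum_closed_form(q, u, udot, m1, m2, L1, d1, d2, I1, I2, g=GRAVITY):
    """Generalized forces and mass matrix of a planar double pendulum.

    Link 1 pivots at the origin (angle q1 from straight down), link 2 hangs
    from link 1's tip (relative angle q2).  ``d1``/``d2`` are the distances
    from each pivot to the link's center of mass; ``I1``/``I2`` are the
    rotational inertias about the centers of mass.
    """
    q1, q2 = q
    u1, u2 = u
    a1, a2 = udot
    c2, s2 = np.cos(q2), np.sin(q2)
    M11 = I1 + I2 + m1 * d1**2 + m2 * (L1**2 + d2**2 + 2.0 * L1 * d2 * c2)
    M12 = I2 + m2 * (d2**2 + L1 * d2 * c2)
    M22 = I2 + m2 * d2**2
    tau1 = (M11 * a1 + M12 * a2
            - m2 * L1 * d2 * s2 * (2.0 * u1 * u2 + u2**2)
            + (m1 * d1 + m2 * L1) * g * np.sin(q1)
            + m2 * d2 * g * np.sin(q1 + q2))
    tau2 = (M12 * a1 + M22 * a2
            + m2 * L1 * d2 * s2 * u1**2
            + m2 * d2 * g * np.sin(q1 + q2))
    return np.array([tau1, tau2]), np.array([[M11, M12], [M12, M22]])


def double_pendulum_energy(q, u, m1, m2, L1, d1, d2, I1, I2, g=GRAVITY):
    """Closed-form total energy 0.5 u' M u + sum m g h of the same system."""
    _, M = double_pendulum_closed_form(q, u, np.zeros(2), m1, m2, L1, d1, d2, I1, I2, g)
    y1 = -d1 * np.cos(q[0])
    y2 = -L1 * np.cos(q[0]) - d2 * np.cos(q[0] + q[1])
    return 0.5 * u @ M @ u + m1 * g * y1 + m2 * g * y2


def rod_pendulum_args(masses, lengths):
    """(m1, m2, L1, d1, d2, I1, I2) for uniform-rod links."""
    m1, m2 = masses
    L1, L2 = lengths
    return m1, m2, L1, L1 / 2.0, L2 / 2.0, m1 * L1**2 / 12.0, m2 * L2**2 / 12.0
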