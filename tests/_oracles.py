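"""Independent straight-line oracles used across test modules.

These deliberately avoid the package's table/kernel machinery: a plain
dict keyed by (stage, state, action), explicit softmax formulas, and
per-trial materialized updates.
"""

import numpy as np

Q0 = 0.5


def oracle_trial(q, c1, c2, c3, r, a1, a2, a3, lam, b1, b2, b3):
    s2, s3 = c1, 2 * c1 + c2

    def soft(v_ch, v_un, beta):
        e1, e2 = np.exp(beta * v_ch), np.exp(beta * v_un)
        return np.log(e1 / (e1 + e2))

    ll = (soft(q[("s1", 0, c1)], q[("s1", 0, 1 - c1)], b1)
          + soft(q[("s2", s2, c2)], q[("s2", s2, 1 - c2)], b2)
          + soft(q[("s3", s3, c3)], q[("s3", s3, 1 - c3)], b3))
    v1, v2, v3 = q[("s1", 0, c1)], q[("s2", s2, c2)], q[("s3", s3, c3)]
    q[("s1", 0, c1)] = v1 + a1 * (v2 - v1) + a1 * lam * (v3 - v2) + a1 * lam ** 2 * (r - v3)
    q[("s2", s2, c2)] = v2 + a2 * (v3 - v2) + a2 * lam * (r - v3)
    q[("s3", s3, c3)] = v3 + a3 * (r - v3)
    return ll


def fresh_table(q0=Q0):
    q = {("s1", 0, a): q0 for a in (0, 1)}
    q.update({("s2", s, a): q0 for s in range(2) for a in (0, 1)})
    q.update({("s3", s, a): q0 for s in range(4) for a in (0, 1)})
    return q


def oracle_sequence(choices, rewards, params, q0=Q0):
    q = fresh_table(q0)
    p = params
    total = sum(oracle_trial(q, c1, c2, c3, r, p.alpha1, p.alpha2, p.alpha3,
                             p.lam, p.beta1, p.beta2, p.beta3)
                for (c1, c2, c3), r in zip(choices, rewards))
    return total, q


def oracle_offered_values(choices, rewards, params, q0=Q0):
    """Pre-update offered value pairs per trial and stage."""
    q = fresh_table(q0)
    p = params
    out = []
    for (c1, c2, c3), r in zip(choices, rewards):
        s2, s3 = c1, 2 * c1 + c2
        out.append([[q[("s1", 0, 0)], q[("s1", 0, 1)]],
                    [q[("s2", s2, 0)], q[("s2", s2, 1)]],
                    [q[("s3", s3, 0)], q[("s3", s3, 1)]]])
        oracle_trial(q, c1, c2, c3, r, p.alpha1, p.alpha2, p.alpha3,
                     p.lam, p.beta1, p.beta2, p.beta3)
    return np.array(out)
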