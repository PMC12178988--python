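"""Independent oracles for the tests.

``exact_ld`` computes the within- and between-parent LD coefficients for
one locus pair by exact iteration of the 256-state Markov chain over the
two homologs' parental-origin configurations under selfing — a route
entirely separate from the closed forms in :mod:`ucross.uc`.
"""

import itertools

import numpy as np


def _initial(c):
    p = np.zeros(256)
    h1 = {(a, b): (1 - c) / 2 if a == b else c / 2
          for a, b in itertools.product((0, 1), repeat=2)}
    h2 = {(a, b): (1 - c) / 2 if a == b else c / 2
          for a, b in itertools.product((2, 3), repeat=2)}
    for (a, b), pa in h1.items():
        for (a2, b2), pb in h2.items():
            p[((a * 4 + b) * 4 + a2) * 4 + b2] = pa * pb
    return p


def _transition(c):
    T = np.zeros((256, 256))
    for s in range(256):
        a, b = (s >> 6) & 3, (s >> 4) & 3
        a2, b2 = (s >> 2) & 3, s & 3
        gam = {}
        for (ol, olp), pr in (((a, b), (1 - c) / 2), ((a, b2), c / 2),
                              ((a2, b2), (1 - c) / 2), ((a2, b), c / 2)):
            gam[(ol, olp)] = gam.get((ol, olp), 0.0) + pr
        for (g1, p1), (g2, p2) in itertools.product(gam.items(), repeat=2):
            T[s, ((g1[0] * 4 + g1[1]) * 4 + g2[0]) * 4 + g2[1]] += p1 * p2
    return T


def exact_ld(c, g):
    """(D_within, D_between) for recombination fraction c at generation g
    (g=1 is the F1), from the exact origin-state chain."""
    p = _initial(c)
    T = _transition(c)
    for _ in range(g - 1):
        p = p @ T
    e12 = e13 = 0.0
    for s in range(256):
        if p[s] == 0:
            continue
        a, b = (s >> 6) & 3, (s >> 4) & 3
        a2, b2 = (s >> 2) & 3, s & 3
        n1l = (a == 0) + (a2 == 0)
        e12 += p[s] * n1l * ((b == 1) + (b2 == 1))
        e13 += p[s] * n1l * ((b == 2) + (b2 == 2))
    return -(e12 - 0.25), -(e13 - 0.25)
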