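"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: plain Python loops over flattened voxel lists, no numpy
vectorisation, no shared code with the package internals.
"""

import math


def aeration_oracle(hu_values, boundaries):
    """Percentages (normo, hypo, non, other) by explicit per-voxel counting."""
    b0, b1, b2, b3 = boundaries
    normo = hypo = non = other = 0
    for hu in hu_values:
        if b0 <= hu <= b1:
            normo += 1
        elif b1 < hu < b2:
            hypo += 1
        elif b2 <= hu <= b3:
            non += 1
        else:
            other += 1
    n = normo + hypo + non + other
    return tuple(100.0 * c / n for c in (normo, hypo, non, other))


def mla_oracle(hu_values):
    total = 0.0
    count = 0
    for hu in hu_values:
        total += hu
        count += 1
    return total / count


def gas_tissue_oracle(hu_values, voxel_volume):
    gas = tissue = 0.0
    for hu in hu_values:
        g = -hu / 1000.0
        g = 0.0 if g < 0 else (1.0 if g > 1 else g)
        gas += g * voxel_volume
        tissue += (1.0 - g) * voxel_volume
    pct = 100.0 * gas / (len(hu_values) * voxel_volume)
    return gas, tissue, pct


def classify_oracle(svg1, svg2, delta, alpha_i, alpha_e, beta):
    """Per-voxel triple-condition evaluation; 1=Normal, 2=Low, 3=Fibrosis."""
    out = []
    for s1, s2, d in zip(svg1, svg2, delta):
        if d >= beta:
            out.append(1)
        elif s1 < alpha_i and s2 < alpha_e:
            out.append(3)
        else:
            out.append(2)
    return out


def mean_sem_oracle(values):
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0, 1
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n), n
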