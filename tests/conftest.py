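import numpy as np
import pytest

from promoscan.pwm import Pwm
from promoscan.simulate import (PlantSpec, SimConfig, make_oe_pwm,
                                simulate_promoters)


@pytest.fixture(scope="session")
def toy_pwm():
    """A sharp 6-column matrix (consensus TGACGT-like) for oracle tests."""
    counts = np.array([
        [1, 1, 90, 1, 2, 5],    # A
        [2, 1, 4, 88, 3, 5],    # C
        [5, 92, 3, 4, 90, 5],   # G
        [92, 6, 3, 7, 5, 85],   # T
    ], dtype=float)
    return Pwm.from_counts("V$TOY_01", counts, family_id="V$TOY",
                           opt_threshold=0.85)


@pytest.fixture(scope="session")
def oe_pwm():
    return make_oe_pwm()


@pytest.fixture(scope="session")
def planted_promoters(oe_pwm):
    """A small promoter set with an O/E-like motif planted near the TSS."""
    cfg = SimConfig(n_promoters=40,
                    planted=[PlantSpec(oe_pwm, 1.4, ("gaussian", -75.0, 40.0))],
                    seed=11)
    return simulate_promoters(cfg)


def brute_force_scores(seq, pwm):
    """Independent window scoring oracle: (strand, start, core, mss) for
    every window of both strands, by direct evaluation of the similarity
    formulas in pure Python."""
    import math

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    out = []
    L = pwm.length
    f = pwm.frequencies
    ci = [(100.0 / math.log(4)) * sum(f[b, i] * math.log(4 * f[b, i])
                                      for b in range(4) if f[b, i] > 0)
          for i in range(L)]
    ci = [max(c, 0.0) for c in ci]
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score(window, positions):
        num = den = 0.0
        for i in positions:
            den += ci[i] * max(f[b, i] for b in range(4))
            b = window[i]
            if b in base_idx and window[i].isupper():
                num += ci[i] * f[base_idx[b], i]
        return num / den if den else 0.0

    for strand in "+-":
        for start in range(len(seq) - L + 1):
            window = seq[start:start + L]
            if strand == "-":
                window = "".join(comp.get(c.upper(), "N") if c.isupper() else "n"
                                 for c in reversed(window))
            mss = score(window, range(L))
            core = score(window, pwm.core_positions)
            out.append((strand, start, core, mss))
    return out
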