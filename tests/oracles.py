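"""Independent brute-force reference implementations used as oracles.

These deliberately re-derive the model arithmetic from the written
formulas with plain Python floats and dicts, sharing no code with the
package's likelihood kernels.
"""

import math
from typing import Dict, Sequence, Tuple


def logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def brute_force_loglik(trials: Sequence[dict],
                       v0: Dict[str, Tuple[float, float]],
                       alphas: Dict[Tuple[str, int], float],
                       betas: Dict[str, float],
                       bias: float = 0.0) -> float:
    """Trial-by-trial recursion over the biased two-action choice rule.

    trials: dicts with keys group, block, action ('accept'/'punish'),
    reward (0/1), in causal order.  v0 maps group -> (v_accept, v_punish).
    """
    va = {g: v0[g][0] for g in v0}
    vp = {g: v0[g][1] for g in v0}
    total = 0.0
    for t in trials:
        g = t["group"]
        shift = bias if g == "ingroup" else 0.0
        p_acc = logistic((va[g] - vp[g] + shift) / betas[g])
        p = p_acc if t["action"] == "accept" else 1.0 - p_acc
        total += math.log(p)
        a = alphas[(g, t["block"])]
        if t["action"] == "accept":
            va[g] = va[g] + a * (t["reward"] - va[g])
        else:
            vp[g] = vp[g] + a * (t["reward"] - vp[g])
    return total
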