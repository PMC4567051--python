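"""Independent brute-force references for the fusion rules.

These re-derive the uncertainty measure and both fusion strategies with
explicit Python loops and no shared code with the package, so they can
stand as oracles against the vectorized implementations.
"""

import math


def oracle_entropy(p, alpha=0.5, n=None):
    if n is None:
        n = len(p)
    total = 0.0
    for pk in p:
        total += (pk * (1.0 - pk)) ** alpha
    return (2.0 ** (2 * alpha) / n) * total


def oracle_mvote(labels, uncertainties):
    """Literal majority vote with least-uncertainty tie-break (one pixel)."""
    votes = {}
    for lab in labels:
        votes[lab] = votes.get(lab, 0) + 1
    top = max(votes.values())
    tied = sorted(lab for lab, v in votes.items() if v == top)
    if len(tied) == 1:
        return tied[0]
    best_f, best_u = None, math.inf
    for f, (lab, u) in enumerate(zip(labels, uncertainties)):
        if lab in tied and u < best_u:
            best_f, best_u = f, u
    return labels[best_f]


def oracle_pfusion(probas, uncertainties, weight_mode="complement"):
    """Literal per-class weighted score and argmax (one pixel)."""
    K = len(probas[0])
    scores = []
    for k in range(K):
        s = 0.0
        for p, u in zip(probas, uncertainties):
            w = (1.0 - u) if weight_mode == "complement" else u
            s += w * p[k]
        scores.append(s)
    if all(s == 0 for s in scores):
        scores = [sum(p[k] for p in probas) / len(probas) for k in range(K)]
    best = max(scores)
    return scores.index(best) + 1  # lowest class index on ties


def oracle_mvote_object(labels_by_pixel, unc_by_pixel):
    """Pooled object vote: every pixel-classifier pair casts one vote."""
    votes = {}
    for labs in labels_by_pixel:
        for lab in labs:
            votes[lab] = votes.get(lab, 0) + 1
    top = max(votes.values())
    tied = sorted(lab for lab, v in votes.items() if v == top)
    if len(tied) == 1:
        return tied[0]
    best_lab, best_u = None, math.inf
    for labs, uncs in zip(labels_by_pixel, unc_by_pixel):
        for lab, u in zip(labs, uncs):
            if lab in tied and u < best_u:
                best_lab, best_u = lab, u
    return best_lab


def oracle_pfusion_object(probas_by_pixel, unc_by_pixel, weight_mode="complement"):
    K = len(probas_by_pixel[0][0])
    scores = [0.0] * K
    for probas, uncs in zip(probas_by_pixel, unc_by_pixel):
        for p, u in zip(probas, uncs):
            w = (1.0 - u) if weight_mode == "complement" else u
            for k in range(K):
                scores[k] += w * p[k]
    best = max(scores)
    return scores.index(best) + 1
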