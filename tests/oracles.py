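"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: plain Python loops and the statistics module, no shared
code with the package internals.
"""

import math
import statistics

import numpy as np


def genorm_m_oracle(frame) -> dict:
    """M per gene: mean over partners of stdev of pairwise log2 ratios."""
    genes = list(frame.index)
    logs = {g: [math.log2(v) for v in frame.loc[g]] for g in genes}
    m = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            ratios = [a - b for a, b in zip(logs[g], logs[h])]
            sds.append(statistics.stdev(ratios))
        m[g] = sum(sds) / len(sds)
    return m


def genorm_stepwise_oracle(frame):
    """Removal order + final pair, recomputing the full matrix each round."""
    surviving = list(frame.index)
    removed = []
    while len(surviving) > 2:
        m = genorm_m_oracle(frame.loc[surviving])
        worst_val = max(m.values())
        worst = sorted(g for g in surviving if m[g] == worst_val)[0]
        surviving.remove(worst)
        removed.append(worst)
    return tuple(removed), tuple(sorted(surviving))


def delta_ct_oracle(ct, genes) -> dict:
    """Mean pairwise delta-Ct SD per gene, from raw loops."""
    scores = {}
    for i, g in enumerate(genes):
        sds = []
        for j, h in enumerate(genes):
            if i == j:
                continue
            diffs = [a - b for a, b in zip(ct[i], ct[j])]
            sds.append(statistics.stdev(diffs))
        scores[g] = sum(sds) / len(sds)
    return scores


def geometric_mean_oracle(values) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def permutation_corr_null(x_rows, index, n_perm=200, seed=0):
    """Null distribution of mean |pearson r vs geometric-mean index|."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        perm = np.array([rng.permutation(row) for row in x_rows])
        idx = np.exp(np.log(perm).mean(axis=0))
        rs = [abs(np.corrcoef(row, idx)[0, 1]) for row in perm]
        out.append(float(np.mean(rs)))
    return np.array(out)
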