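"""Independent brute-force / direct-formula metric oracles.

Deliberately naive re-implementations (double loops, literal formulas) kept
separate from the package so the equivalence tests compare two independent
code paths.
"""

import numpy as np


def ci_bruteforce(y, yhat) -> float:
    conc = z = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] > y[j]:
                z += 1
                if yhat[i] > yhat[j]:
                    conc += 1
                elif yhat[i] == yhat[j]:
                    conc += 0.5
    return conc / z


def mse_direct(y, yhat) -> float:
    return sum((a - b) ** 2 for a, b in zip(y, yhat)) / len(y)


def r2_direct(y, yhat) -> float:
    ybar = sum(y) / len(y)
    return 1.0 - sum((a - b) ** 2 for a, b in zip(y, yhat)) / sum((a - ybar) ** 2 for a in y)


def pearson_direct(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    num = np.sum((y - y.mean()) * (yhat - yhat.mean()))
    den = np.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((yhat - yhat.mean()) ** 2))
    return float(num / den)


def spearman_untied_direct(y, yhat) -> float:
    """1 - 6*sum(d^2)/(N(N^2-1)); valid only for tie-free vectors."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    ry = np.empty(len(y))
    ry[np.argsort(y)] = np.arange(1, len(y) + 1)
    rh = np.empty(len(y))
    rh[np.argsort(yhat)] = np.arange(1, len(y) + 1)
    d2 = np.sum((ry - rh) ** 2)
    n = len(y)
    return float(1 - 6 * d2 / (n * (n**2 - 1)))


def ef_direct(scores, labels, k_percent) -> float:
    order = np.argsort(-np.asarray(scores), kind="stable")
    n = len(scores)
    top = int(np.ceil(k_percent / 100 * n))
    hits = int(np.asarray(labels)[order][:top].sum())
    return hits / (k_percent / 100 * int(np.sum(labels)))


def precision_direct(scores, labels, n_top) -> float:
    order = np.argsort(-np.asarray(scores), kind="stable")
    return float(np.asarray(labels)[order][:n_top].sum() / n_top)


def bedroc_rdkit(scores, labels, alpha) -> float:
    """Reference Truchon-Bayly implementation shipped with RDKit."""
    from rdkit.ML.Scoring.Scoring import CalcBEDROC

    order = np.argsort(-np.asarray(scores), kind="stable")
    ranked = [[0.0, int(l)] for l in np.asarray(labels)[order]]
    return float(CalcBEDROC(ranked, 1, alpha))
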