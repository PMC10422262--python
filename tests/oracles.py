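"""Independent brute-force oracles for the regularity statistics.

Each oracle transcribes the published definition directly — explicit
template loops, row-at-a-time Chebyshev distances — sharing no code with
the package's vectorized implementations.
"""

import numpy as np


def _cheb_row(templates: np.ndarray, i: int) -> np.ndarray:
    return np.max(np.abs(templates - templates[i]), axis=1)


def approximate_entropy_oracle(x, m, r):
    x = np.asarray(x, float)
    n = len(x)
    tol = r * np.std(x)

    def phi(mm):
        t = np.array([x[i : i + mm] for i in range(n - mm + 1)])
        logs = []
        for i in range(len(t)):
            c = np.count_nonzero(_cheb_row(t, i) <= tol) / len(t)
            logs.append(np.log(c))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def sample_entropy_oracle(x, m, r):
    x = np.asarray(x, float)
    n = len(x)
    tol = r * np.std(x)
    n_t = n - m

    def pairs(mm):
        t = np.array([x[i : i + mm] for i in range(n - mm + 1)])[:n_t]
        count = 0
        for i in range(len(t)):
            d = _cheb_row(t, i)
            count += np.count_nonzero(d[i + 1 :] <= tol)
        return count

    b = pairs(m)
    a = pairs(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(b))
    return -np.log(a / b)


def fuzzy_entropy_oracle(x, m, r, n_exp=2.0):
    x = np.asarray(x, float)
    n = len(x)
    tol = r * np.std(x)
    n_t = n - m

    def phi(mm):
        t = np.array([x[i : i + mm] for i in range(n - mm + 1)])[:n_t]
        t = t - t.mean(axis=1, keepdims=True)
        total = 0.0
        for i in range(len(t)):
            d = _cheb_row(t, i)
            mu = np.exp(-((d / tol) ** n_exp)) if tol > 0 else (d <= 0).astype(float)
            total += mu.sum() - mu[i]
        return total / (n_t * (n_t - 1))

    return np.log(phi(m)) - np.log(phi(m + 1))
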