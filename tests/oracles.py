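"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-state the rules in the most literal form possible
(explicit loops, no shared code with the package) so that agreement with
the package is meaningful.
"""

from __future__ import annotations

import numpy as np


def ma_bruteforce(scores: np.ndarray, epoch_length: float = 4.0) -> np.ndarray:
    """Literal enumeration of the microarousal rule.

    For every maximal wake run, check the three conditions word for word:
    run duration <= 12 s; the 16 s immediately before are all NREMS; the
    4 s immediately after are NREMS.  Relabel qualifying runs as 'M'.
    """
    out = np.array(scores, dtype="<U1")
    n = len(out)
    n_ma = int(12.0 // epoch_length)
    n_pre = int(np.ceil(16.0 / epoch_length))
    n_post = int(np.ceil(4.0 / epoch_length))
    i = 0
    while i < n:
        if scores[i] != "W":
            i += 1
            continue
        j = i
        while j < n and scores[j] == "W":
            j += 1
        run_len = j - i
        ok = run_len <= n_ma
        if ok:
            for k in range(i - n_pre, i):
                if k < 0 or scores[k] != "N":
                    ok = False
                    break
        if ok:
            for k in range(j, j + n_post):
                if k >= n or scores[k] != "N":
                    ok = False
                    break
        if ok:
            for k in range(i, j):
                out[k] = "M"
        i = j
    return out


def rle_bruteforce(labels) -> list[tuple[str, int, int]]:
    """Literal run-length encoding: (label, start, end-exclusive) triples."""
    runs = []
    i, n = 0, len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((str(labels[i]), i, j))
        i = j
    return runs


def polyfit_normal_equations(t: np.ndarray, y: np.ndarray, degree: int = 2) -> np.ndarray:
    """Least-squares polynomial via explicit normal equations (highest first)."""
    X = np.vander(t, degree + 1)
    coeffs = np.linalg.solve(X.T @ X, X.T @ y)
    return coeffs


def crosscorr_lag_scan(x: np.ndarray, y: np.ndarray, max_shift: int) -> tuple[int, float]:
    """Direct lag scan: Pearson r of overlapping parts for each shift.

    Positive shift aligns x[k + shift] with y[k] (x follows y).  Returns
    the shift maximizing |r| and that r.
    """
    best = (0, 0.0)
    n = len(x)
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            xa, ya = x[shift:], y[: n - shift]
        else:
            xa, ya = x[: n + shift], y[-shift:]
        if len(xa) < 3:
            continue
        r = np.corrcoef(xa, ya)[0, 1]
        if abs(r) > abs(best[1]):
            best = (shift, float(r))
    return best
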