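"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from blinkbro import synth, workflows


@pytest.fixture(scope="session")
def processed_low():
    """One fully processed 240 s low-workload synthetic recording."""
    cfg = synth.SynthConfig.preset("low", duration_s=240.0, seed=7)
    return workflows.simulate_and_process(cfg)


# ---------------------------------------------------------------------------
# brute-force statistical oracles (deliberately naive, loop-based)
# ---------------------------------------------------------------------------

def rm_anova_bruteforce(x: np.ndarray) -> dict:
    """Textbook one-way repeated-measures ANOVA with GG/HF epsilon, by loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    cond_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    subj_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    ss_cond = n * sum((m - grand) ** 2 for m in cond_means)
    ss_err = sum(
        (x[i][j] - cond_means[j] - subj_means[i] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)

    # Greenhouse-Geisser from the condition covariance matrix
    s = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            s[a, b] = sum(
                (x[i][a] - cond_means[a]) * (x[i][b] - cond_means[b])
                for i in range(n)
            ) / (n - 1)
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    diag_mean = np.trace(s) / k
    num = (k * (diag_mean - mean_all)) ** 2
    den = (k - 1) * (
        np.sum(s * s) - 2 * k * np.sum(row_means ** 2) + k * k * mean_all ** 2
    )
    gg = num / den if den > 0 else 1.0
    hf = (n * (k - 1) * gg - 2) / ((k - 1) * (n - 1 - (k - 1) * gg))
    hf = min(1.0, max(hf, 1.0 / (k - 1)))
    p_raw = float(sps.f.sf(f, df1, df2))
    p_hf = float(sps.f.sf(f, df1 * hf, df2 * hf))
    return {"F": f, "gg": gg, "hf": hf, "p_raw": p_raw, "p_hf": p_hf}


def paired_t_bruteforce(x, y) -> dict:
    """Closed-form paired t, written out longhand."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    var = sum((v - m) ** 2 for v in d) / (n - 1)
    t = m / np.sqrt(var / n)
    return {"t": t, "df": n - 1, "p": 2 * float(sps.t.sf(abs(t), n - 1))}
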