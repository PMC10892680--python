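"""Shared statistical engine.

Repeated-measures ANOVA (one- and two-way, within-subject) with Huynh-Feldt
sphericity correction, paired t-tests, Bonferroni correction, and generic
permutation machinery with the add-one p-value rule.

Notation: n subjects, k within-subject levels. Sphericity epsilon is
estimated as Greenhouse-Geisser from the covariance of orthonormal contrasts
of the level scores, then adjusted to Huynh-Feldt

    eps_HF = (n (k-1) eps_GG - 2) / ((k-1) (n - 1 - (k-1) eps_GG))

and clamped to [1/(k-1), 1]. Corrected degrees of freedom are
(k-1) eps, (k-1)(n-1) eps.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .core_io import StatResult


# ---------------------------------------------------------------------------
# epsilon machinery
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, sum zero)."""
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    # orthonormal basis of the contrast space via QR of the centering matrix
    q, _ = np.linalg.qr(h.T)
    c = q[:, :k - 1].T
    return c


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an n x k within-subject score matrix."""
    n, k = scores.shape
    c = _orthonormal_contrasts(k)
    y = scores @ c.T                       # n x (k-1) contrast scores
    s = np.cov(y, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    denom = (k - 1) * np.sum(s * s)
    if denom <= 0:
        return 1.0
    return float(tr ** 2 / denom)


def _hf_epsilon(scores: np.ndarray) -> tuple[float, float]:
    """(eps_GG, eps_HF) with HF clamped to [1/(k-1), 1]."""
    n, k = scores.shape
    gg = _gg_epsilon(scores)
    num = n * (k - 1) * gg - 2.0
    den = (k - 1) * (n - 1 - (k - 1) * gg)
    hf = num / den if den > 0 else 1.0
    lo = 1.0 / (k - 1)
    return gg, float(np.clip(hf, lo, 1.0))


def _f_result(name: str, ss_effect: float, df1: int, ss_error: float,
              df2: int, scores: np.ndarray) -> StatResult:
    if ss_error <= 0 and ss_effect <= 0:
        # degenerate but well-defined: no effect, no noise
        return StatResult(test_name=name, statistic=0.0,
                          df=(float(df1), float(df2)), epsilon=1.0,
                          p_raw=1.0, p_corrected=1.0,
                          correction="huynh-feldt")
    if ss_error <= 0:
        raise ValueError(f"zero residual variance in {name}")
    f = (ss_effect / df1) / (ss_error / df2)
    _, eps = _hf_epsilon(scores)
    p_raw = float(sps.f.sf(f, df1, df2))
    p_corr = float(sps.f.sf(f, df1 * eps, df2 * eps))
    return StatResult(
        test_name=name, statistic=float(f),
        df=(df1 * eps, df2 * eps),
        epsilon=eps, p_raw=p_raw, p_corrected=max(p_corr, p_raw),
        correction="huynh-feldt",
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova(data: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on an n-subjects x k-levels array."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected subjects x levels array")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 subjects and >=2 levels")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete design (non-finite cells)")
    grand = x.mean()
    subj = x.mean(axis=1)
    cond = x.mean(axis=0)
    ss_cond = n * np.sum((cond - grand) ** 2)
    resid = x - subj[:, None] - cond[None, :] + grand
    ss_err = np.sum(resid ** 2)
    return _f_result("rm_anova", ss_cond, k - 1, ss_err, (k - 1) * (n - 1), x)


def rm_anova_two_way(data: np.ndarray,
                     factor_names: tuple[str, str] = ("A", "B"),
                     ) -> list[StatResult]:
    """Two-way fully within-subject ANOVA on an n x a x b array.

    Returns main effects and the interaction, each tested against its own
    subject-by-effect error term, each with its own Huynh-Feldt epsilon.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected subjects x levelsA x levelsB array")
    n, a, b = x.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >=2 subjects and >=2 levels per factor")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete design (non-finite cells)")

    grand = x.mean()
    m_s = x.mean(axis=(1, 2))            # subject means
    m_a = x.mean(axis=(0, 2))            # factor-A level means
    m_b = x.mean(axis=(0, 1))
    m_sa = x.mean(axis=2)                # n x a
    m_sb = x.mean(axis=1)                # n x b
    m_ab = x.mean(axis=0)                # a x b

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (x - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = np.sum(resid ** 2)

    name_a, name_b = factor_names
    # interaction contrast scores: subject cell vectors projected onto the
    # Kronecker product of the two contrast spaces
    c_ab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
    scores_ab = x.reshape(n, a * b)
    y_ab = scores_ab @ c_ab.T
    # reuse the one-way epsilon path by passing contrast scores through a
    # covariance-based epsilon on the raw cell matrix restricted per effect
    res = [
        _f_result(name_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1), m_sa),
        _f_result(name_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1), m_sb),
        _interaction_result(f"{name_a}*{name_b}", ss_ab, (a - 1) * (b - 1),
                            ss_abs, (a - 1) * (b - 1) * (n - 1), y_ab, n),
    ]
    return res


def _interaction_result(name: str, ss_effect: float, df1: int,
                        ss_error: float, df2: int, contrast_scores: np.ndarray,
                        n: int) -> StatResult:
    if ss_error <= 0 and ss_effect <= 0:
        return StatResult(test_name=name, statistic=0.0,
                          df=(float(df1), float(df2)), epsilon=1.0,
                          p_raw=1.0, p_corrected=1.0,
                          correction="huynh-feldt")
    if ss_error <= 0:
        raise ValueError(f"zero residual variance in {name}")
    f = (ss_effect / df1) / (ss_error / df2)
    s = np.atleast_2d(np.cov(contrast_scores, rowvar=False, ddof=1))
    tr = np.trace(s)
    denom = df1 * np.sum(s * s)
    gg = float(tr ** 2 / denom) if denom > 0 else 1.0
    num = n * df1 * gg - 2.0
    den = df1 * (n - 1 - df1 * gg)
    hf = num / den if den > 0 else 1.0
    eps = float(np.clip(hf, 1.0 / df1, 1.0))
    p_raw = float(sps.f.sf(f, df1, df2))
    p_corr = float(sps.f.sf(f, df1 * eps, df2 * eps))
    return StatResult(test_name=name, statistic=float(f),
                      df=(df1 * eps, df2 * eps), epsilon=eps, p_raw=p_raw,
                      p_corrected=max(p_corr, p_raw),
                      correction="huynh-feldt")


# ---------------------------------------------------------------------------
# paired t and Bonferroni
# ---------------------------------------------------------------------------

def paired_t(x: np.ndarray, y: np.ndarray, two_sided: bool = True,
             contrast: str | None = None) -> StatResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need >=2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0 and d.mean() == 0:
        return StatResult(test_name="paired_t", statistic=0.0,
                          df=(1.0, float(n - 1)), p_raw=1.0,
                          contrast=contrast)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(sps.t.sf(abs(t), n - 1))
    p = 2 * p if two_sided else (p if t > 0 else 1 - p)
    return StatResult(test_name="paired_t", statistic=float(t),
                      df=(1.0, float(n - 1)), p_raw=min(p, 1.0),
                      contrast=contrast)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_corr = min(1, m*p), order preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p values")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permutation_null(stat_fn, data, permute_fn, n_perm: int = 1000,
                     seed: int | None = None) -> tuple[np.ndarray, float]:
    """Generic permutation test with the add-one rule.

    ``stat_fn(data) -> float`` computes the observed statistic;
    ``permute_fn(rng, data) -> data'`` returns one resampled dataset whose
    labels are exchangeable under the null. Two-sided p-value:

        p = (1 + #{|t_null| >= |t_obs|}) / (1 + n_perm)

    Returns (null_distribution, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    t_obs = float(stat_fn(data))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat_fn(permute_fn(rng, data))
    p = (1.0 + np.sum(np.abs(null) >= abs(t_obs))) / (1.0 + n_perm)
    return null, float(p)


def paired_t_map(diff: np.ndarray) -> np.ndarray:
    """Vectorized paired t over axis 0 of a trials-x-cells difference array."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return m / (sd / np.sqrt(n))


def signflip_t_pvalues(diff: np.ndarray, n_perm: int = 1000,
                       seed: int | None = None,
                       chunk: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise sign-flip permutation p-values for paired differences.

    ``diff`` is trials x cells (cells may be a flattened frequency-time
    plane). The null is built by randomly flipping each trial's sign, which
    is the exact exchangeability operation for swapping paired labels.
    Returns (t_observed, p_two_sided) with the add-one rule.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    d = np.asarray(diff, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need >=2 paired observations")
    t_obs = paired_t_map(d)
    sumsq = np.sum(d * d, axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(d.shape[1:], dtype=np.int64)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(k, n)) * 2 - 1
        m = (signs @ d) / n                       # k x cells
        var = (sumsq[None, :] - n * m * m) / (n - 1)
        var = np.where(var <= 0, np.inf, var)
        t_null = m / np.sqrt(var / n)
        exceed += np.sum(np.abs(t_null) >= np.abs(t_obs)[None, :], axis=0)
        done += k
    p = (1.0 + exceed) / (1.0 + n_perm)
    return t_obs, p
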