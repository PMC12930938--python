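"""Inter-rater and classifier-vs-truth agreement statistics.

Four statistics cover the reliability analysis of a two-reader measurement
study:

* Gwet's AC1 — chance-corrected agreement between two binary ratings,
  robust to skewed prevalence (unlike kappa). Chance agreement is modelled
  as ``2*pi*(1-pi)`` with ``pi`` the mean of the two raters' positive
  marginals; the variance is the unconditional subject-level estimator,
  without finite-population correction.
* ICC(2,1) — two-way random-effects, absolute-agreement, single-measures
  intraclass correlation, computed from the ANOVA mean squares, with the
  F-distribution-based 95% confidence interval of McGraw & Wong.
* Bland–Altman — bias (mean of reader-1 minus reader-2 differences) and
  95% limits of agreement ``bias +/- 1.96*SD`` (SD with n-1 denominator).
* Spearman's rho — Pearson correlation of mid-ranks, two-sided p by the
  t-approximation, replaced by exact permutation enumeration for n <= 8.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "gwet_ac1",
    "icc_2_1",
    "bland_altman",
    "spearman_rho",
]

_Z95 = 1.959963984540054


@dataclass
class AgreementResult:
    statistic_name: str
    estimate: float
    ci: tuple[float, float] | None
    n_pairs: int
    extras: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def _binary(ratings) -> np.ndarray:
    out = []
    for r in ratings:
        if isinstance(r, str):
            out.append(r in ("metastatic", "positive", "1", "True", "true"))
        else:
            out.append(bool(r))
    return np.asarray(out, dtype=bool)


def gwet_ac1(ratings_a, ratings_b) -> AgreementResult:
    """Gwet's AC1 between two binary rating vectors, with 95% CI."""
    a, b = _binary(ratings_a), _binary(ratings_b)
    if a.size != b.size:
        raise ValueError(f"rating vectors differ in length: {a.size} vs {b.size}")
    n = a.size
    if n < 2:
        raise ValueError("AC1 requires at least 2 rated items")
    agree = (a == b).astype(float)
    pa = agree.mean()
    pi = (a.mean() + b.mean()) / 2.0
    pe = 2.0 * pi * (1.0 - pi)
    ac1 = (pa - pe) / (1.0 - pe)

    # subject-level variance (two categories, two raters): each item's
    # chance-agreement share uses its own rater-classification fractions
    pi_i_pos = (a.astype(float) + b.astype(float)) / 2.0
    pe_i = pi_i_pos * (1.0 - pi) + (1.0 - pi_i_pos) * pi
    g_star = (agree - pe) / (1.0 - pe)
    g = g_star - 2.0 * (1.0 - ac1) * (pe_i - pe) / (1.0 - pe)
    var = float(np.sum((g - g.mean()) ** 2)) / (n * (n - 1))
    se = math.sqrt(var)
    t = stats.t.ppf(0.975, n - 1)
    ci = (ac1 - t * se, min(ac1 + t * se, 1.0))
    return AgreementResult(
        statistic_name="AC1",
        estimate=float(ac1),
        ci=ci,
        n_pairs=n,
        extras={"pa": float(pa), "pe": float(pe), "se": se},
    )


def icc_2_1(paired_values) -> AgreementResult:
    """ICC(2,1): absolute agreement, single measures, two-way random model.

    ``paired_values`` is an n x 2 array of both readers' measurements;
    incomplete pairs are excluded (count reported in ``extras``). Requires
    at least 3 complete pairs.
    """
    x = np.asarray(paired_values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"expected an n x 2 matrix, got shape {x.shape}")
    complete = ~np.isnan(x).any(axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 3:
        raise ValueError(f"ICC needs at least 3 complete pairs, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("no variance in the measurements; ICC undefined")
    icc = (msr - mse) / denom

    if mse <= 0 and msc <= 0:  # readers numerically identical
        return AgreementResult(
            statistic_name="ICC21",
            estimate=float(icc),
            ci=(float(icc), float(icc)),
            n_pairs=n,
            extras={"msr": msr, "msc": msc, "mse": mse, "n_dropped": n_dropped},
            flags=("degenerate-zero-error",),
        )

    # McGraw & Wong F-based interval for ICC(A,1)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_l = stats.f.ppf(0.975, n - 1, v)
    f_u = stats.f.ppf(0.975, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return AgreementResult(
        statistic_name="ICC21",
        estimate=float(icc),
        ci=(float(lower), min(float(upper), 1.0)),
        n_pairs=n,
        extras={"msr": msr, "msc": msc, "mse": mse, "n_dropped": n_dropped},
    )


def bland_altman(x_r1, x_r2) -> AgreementResult:
    """Bias and 95% limits of agreement of paired differences (R1 - R2)."""
    a = np.asarray(x_r1, dtype=float)
    b = np.asarray(x_r2, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - _Z95 * sd, bias + _Z95 * sd)
    return AgreementResult(
        statistic_name="BLAND_ALTMAN",
        estimate=bias,
        ci=None,
        n_pairs=a.size,
        extras={"bias": bias, "loa_lower": loa[0], "loa_upper": loa[1], "sd_diff": sd},
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    rhos = pc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_rho(x, y) -> AgreementResult:
    """Spearman rank correlation with two-sided p.

    Mid-ranks handle ties. The p-value uses the t-approximation, replaced
    by exact enumeration over all rank permutations when n <= 8. A constant
    input leaves the coefficient undefined (NaN, flagged).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size:
        raise ValueError(f"vectors differ in length: {a.size} vs {b.size}")
    n = a.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return AgreementResult(
            statistic_name="SPEARMAN",
            estimate=float("nan"),
            ci=None,
            n_pairs=n,
            extras={"p_value": float("nan")},
            flags=("constant-input",),
        )
    rho, p_t = stats.spearmanr(a, b)
    rho = float(rho)
    if n <= 8:
        rx, ry = stats.rankdata(a), stats.rankdata(b)
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        p, method = float(p_t), "t-approximation"
    return AgreementResult(
        statistic_name="SPEARMAN",
        estimate=rho,
        ci=None,
        n_pairs=n,
        extras={"rho": rho, "p_value": p, "p_method": method},
    )
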