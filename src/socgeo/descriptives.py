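"""Per-layer descriptive statistics, normality testing and mean separation.

Conventions follow the common desktop statistics packages: the standard
deviation uses the n-1 denominator, skewness and kurtosis are the
small-sample adjusted (bias-corrected) estimators with kurtosis reported
as excess, and the CV is reported in percent of the mean.  Mean
separation across depth layers uses one-way ANOVA followed by pairwise
least-significant-difference (LSD) t-tests on the pooled error mean
square, summarised as a compact letter display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError, InsufficientDataError


@dataclass(frozen=True)
class LayerSummary:
    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float
    cv_percent: float
    skewness: float
    kurtosis: float
    ks_d: float | None
    ks_p: float | None
    log_transform: bool


def summarize(values, *, ks_alpha: float = 0.05) -> LayerSummary:
    """Descriptive summary of one variable for one layer.

    The Kolmogorov-Smirnov normality test (against a normal with the
    sample's own mean and SD) is run on the raw and, for positive data,
    on the ln-transformed values; ``log_transform`` flags samples that
    fail normality raw but pass after the log transform.  K-S fields are
    None when n < 5.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {v.size}")
    if not np.isfinite(v).all():
        raise DomainError("values must be finite")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        raise DegenerateDataError("CV undefined for zero mean")
    if sd == 0:
        skew = kurt = 0.0  # constant sample: symmetric by convention
    else:
        skew = float(stats.skew(v, bias=False))
        kurt = float(stats.kurtosis(v, bias=False, fisher=True))

    ks_d = ks_p = None
    log_flag = False
    if v.size >= 5 and sd > 0:
        ks_d, ks_p = ks_normality(v)
        if (v > 0).all():
            _, p_ln = ks_normality(np.log(v))
            log_flag = ks_p <= ks_alpha < p_ln
    return LayerSummary(
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
        mean=mean,
        median=float(np.median(v)),
        sd=sd,
        cv_percent=100.0 * sd / mean,
        skewness=skew,
        kurtosis=kurt,
        ks_d=ks_d,
        ks_p=ks_p,
        log_transform=log_flag,
    )


def ks_normality(values, *, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    D is the supremum distance between the empirical CDF and the CDF of
    Normal(mean, sd) with both parameters estimated from the sample; p
    comes from the asymptotic Kolmogorov distribution.  Because the
    parameters are estimated, this p is anticonservative; pass
    ``lilliefors=True`` for the corrected (Lilliefors) p-value.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise InsufficientDataError(f"K-S test needs n >= 5, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("K-S test undefined for zero variance")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(v, dist="norm")
        return float(d), float(p)
    d, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(d), float(p)


@dataclass(frozen=True)
class AnovaLsdResult:
    f: float
    p: float
    df_error: int
    mse: float
    means: tuple[float, ...]
    letters: tuple[str, ...]  #: compact letter display, one per group

    def same_letter(self, i: int, j: int) -> bool:
        return bool(set(self.letters[i]) & set(self.letters[j]))


def anova_lsd(groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with LSD mean separation and compact letters.

    Pairwise t statistics use the pooled error mean square with N - k
    degrees of freedom.  Groups sharing any display letter are not
    significantly different at ``alpha``; letters are assigned by the
    insert-and-absorb algorithm on means sorted descending.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise DomainError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise InsufficientDataError("each group needs n >= 2")
    k = len(gs)
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    big_n = int(ns.sum())
    df_err = big_n - k
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    mse = sse / df_err
    grand = np.concatenate(gs).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    if mse == 0:
        f = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / (k - 1)) / mse
        p = float(stats.f.sf(f, k - 1, df_err))

    # pairwise LSD decisions
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            if se == 0:
                diff = means[i] != means[j]
            else:
                t = abs(means[i] - means[j]) / se
                diff = 2 * stats.t.sf(t, df_err) <= alpha
            sig[i, j] = sig[j, i] = diff

    letters = _compact_letter_display(means, sig)
    return AnovaLsdResult(
        f=float(f), p=p, df_error=df_err, mse=mse,
        means=tuple(float(m) for m in means), letters=letters,
    )


def _compact_letter_display(means: np.ndarray, sig: np.ndarray) -> tuple[str, ...]:
    """Insert-and-absorb compact letter display.

    Each letter column is a set of mutually non-different groups; a
    significant pair found in a column splits it in two, and columns
    that become subsets of another are absorbed.
    """
    k = len(means)
    order = np.argsort(-means, kind="stable")  # descending means
    columns: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            i, j = order[a], order[b]
            if not sig[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                for new in (col - {j}, col - {i}):
                    if not any(new <= other for other in columns):
                        columns.append(new)
            columns = [c for c in columns
                       if not any(c < other for other in columns)]
    # order columns by the rank of their best (largest-mean) member
    rank = {int(g): r for r, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = ["" for _ in range(k)]
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return tuple("".join(sorted(s)) for s in letters)
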