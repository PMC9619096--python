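"""Proportion correct, mAFC d′, confusion matrices, and rank statistics.

Because the disyllabic task is a 3AFC (chance 1/3) and the monosyllabic
comparison a 4AFC (chance 1/4), raw percentages are not comparable across
tasks.  Scores are therefore converted to the signal-detection sensitivity
index d′ for the unbiased m-alternative forced-choice observer
(Hacker & Ratcliff mapping):

    P(c) = ∫ φ(x − d′) · Φ(x)^{m−1} dx

inverted numerically.  Group contrasts use Wilcoxon signed-rank (paired) /
rank-sum (unpaired) tests with Holm–Bonferroni correction across each
declared family, and performance–experience association uses Spearman rank
correlation — the full statistical stack of the study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .corpus import CorpusManifest
from .experiment import ResponseLog, TrialRecord, group_sessions

__all__ = [
    "Dprime",
    "pc_given_dprime",
    "dprime_mafc",
    "summarize_log",
    "confusion",
    "compare_groups",
    "holm_adjust",
    "experience_correlation",
]

D_BRACKET = (-2.0, 8.0)
QUAD_EPS = 1e-9


@dataclass(frozen=True)
class Dprime:
    """A proportion correct with its mAFC d′ equivalent."""

    d_prime: float
    m: int
    p: float
    n: int | None = None
    clamped: bool = False  # True when p hit 1 or chance and was edge-corrected


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(128)


def pc_given_dprime(d: float, m: int, method: str = "gauss-hermite") -> float:
    """Proportion correct of the unbiased m-AFC observer at sensitivity ``d``.

    The signal interval is N(d, 1), the m−1 noise intervals N(0, 1); the
    observer picks the largest sample, so
    P(c) = ∫ φ(x − d) Φ(x)^{m−1} dx = E_{y~N(0,1)}[Φ(y + d)^{m−1}].
    The default 128-node Gauss–Hermite rule is exact to well below 1e−8 for
    this smooth integrand; ``method="quad"`` uses adaptive quadrature as a
    slower cross-check.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    if method == "quad":
        integrand = lambda x: stats.norm.pdf(x - d) * stats.norm.cdf(x) ** (m - 1)
        lo, hi = -8.0 + min(d, 0.0), 8.0 + max(d, 0.0)
        val, _ = quad(integrand, lo, hi, epsabs=QUAD_EPS, limit=200)
        return float(val)
    y = np.sqrt(2.0) * _GH_NODES
    vals = stats.norm.cdf(y + d) ** (m - 1)
    return float(np.sum(_GH_WEIGHTS * vals) / np.sqrt(np.pi))


def dprime_mafc(p: float, m: int, n: int | None = None) -> Dprime:
    """Invert the mAFC mapping: the d′ whose predicted P(c) equals ``p``.

    Edge handling (the observed proportion, not the model, hits the edges):
    p = 1 is clamped to 1 − 1/(2n) and p ≤ 1/m to 1/m + 1/(2n) when the
    trial count ``n`` is known, and flagged; without ``n`` these raise.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion correct {p} outside [0, 1]")
    clamped = False
    chance = 1.0 / m
    if p >= 1.0 or p <= chance:
        if n is None:
            raise ValueError(
                f"p={p} is at or beyond the invertible range (chance {chance:.3f}"
                f" .. 1); supply the trial count n for edge correction"
            )
        p = min(1.0 - 1.0 / (2 * n), max(p, chance + 1.0 / (2 * n)))
        clamped = True
    d = brentq(lambda x: pc_given_dprime(x, m) - p, *D_BRACKET, xtol=1e-8)
    assert abs(pc_given_dprime(d, m) - p) < 1e-7
    return Dprime(float(d), m, float(p), n, clamped)


def _subset_trials(log: ResponseLog, manifest: CorpusManifest | None,
                   subset: str) -> list[tuple[TrialRecord, int]]:
    """(trial, m) pairs belonging to a named subset of the log."""
    di = [(t, t.n_alternatives) for t in log.di_trials()]
    mono = [(t, t.n_alternatives) for t in log.mono_trials()]
    if subset == "all":
        return di + mono
    if subset == "Di":
        return di
    if subset == "Mono":
        return mono
    if subset in ("Cov", "Conf"):
        return [(t, m) for t, m in di if t.congruence == subset]
    if subset.startswith("Di") and "&" in subset or subset == "Di3-6":
        grouping = "pooled" if subset == "Di3-6" else "pairs"
        groups = group_sessions(log, grouping)
        if subset not in groups:
            raise KeyError(f"unknown session group {subset!r}")
        return [(t, t.n_alternatives) for t in groups[subset]]
    if subset.startswith("Mono-part"):
        groups = group_sessions(log, "thirds")
        return [(t, t.n_alternatives) for t in groups[subset]]
    if subset.startswith("tone"):
        tone = int(subset[4:])
        return [(t, m) for t, m in di + mono if t.stimulus_tone == tone]
    raise KeyError(f"unknown subset {subset!r}")


def summarize_log(log: ResponseLog, manifest: CorpusManifest | None = None,
                  subsets: tuple[str, ...] = ("Di", "Cov", "Conf"),
                  ) -> pd.DataFrame:
    """Per-subset proportion correct and d′ (with trial counts).

    Subsets mixing different m (e.g. "all") report percent correct with
    d′ = NaN, since a single m-AFC inversion is undefined there.  Empty
    subsets are reported with n = 0 and NaN scores rather than dropped
    silently.
    """
    rows = []
    for name in subsets:
        pairs = _subset_trials(log, manifest, name)
        n = len(pairs)
        if n == 0:
            rows.append({"subset": name, "n": 0, "p": np.nan,
                         "d_prime": np.nan, "clamped": False})
            continue
        p = sum(t.correct for t, _ in pairs) / n
        ms = {m for _, m in pairs}
        if len(ms) == 1:
            dp = dprime_mafc(p, ms.pop(), n=n)
            rows.append({"subset": name, "n": n, "p": p,
                         "d_prime": dp.d_prime, "clamped": dp.clamped})
        else:
            rows.append({"subset": name, "n": n, "p": p,
                         "d_prime": np.nan, "clamped": False})
    return pd.DataFrame(rows)


def confusion(log: ResponseLog, task: str = "Di") -> pd.DataFrame:
    """Row-normalized confusion matrix (%): stimulus tone × response tone."""
    trials = log.di_trials() if task == "Di" else log.mono_trials()
    if not trials:
        raise ValueError(f"log has no {task} trials")
    tones = sorted({t.stimulus_tone for t in trials} |
                   {t.response_tone for t in trials})
    mat = pd.DataFrame(0.0, index=tones, columns=tones)
    for t in trials:
        mat.loc[t.stimulus_tone, t.response_tone] += 1
    mat = mat.div(mat.sum(axis=1), axis=0) * 100.0
    mat.index.name = "stimulus_tone"
    mat.columns.name = "response_tone"
    return mat


def compare_groups(values_a, values_b, design: str = "paired",
                   family_pvalues: list[float] | None = None) -> dict:
    """Wilcoxon signed-rank (paired) or rank-sum (unpaired) contrast.

    When ``family_pvalues`` lists the raw p-values of the other tests in the
    same comparison family, the returned ``p_adjusted`` is this test's
    Holm–Bonferroni step-down value within that family.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            "fewer than 3 observations per group: rank tests are meaningless "
            "at this size, refusing to compute"
        )
    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires equal-length vectors")
        diffs = a - b
        if np.all(diffs == 0):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(a, b)
            statistic, p = float(res.statistic), float(res.pvalue)
    elif design == "unpaired":
        res = stats.ranksums(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown design {design!r}")
    out = {"statistic": statistic, "p_value": p,
           "median_a": float(np.median(a)), "median_b": float(np.median(b))}
    if family_pvalues is not None:
        family = list(family_pvalues) + [p]
        reject, p_adj, *_ = multipletests(family, method="holm")
        out["p_adjusted"] = float(p_adj[-1])
    else:
        out["p_adjusted"] = p
    return out


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm–Bonferroni step-down adjusted p-values for one family."""
    _, p_adj, *_ = multipletests(pvalues, method="holm")
    return [float(x) for x in p_adj]


def experience_correlation(scores, experience_years) -> dict:
    """Spearman rank correlation between performance and listening experience."""
    s = np.asarray(scores, dtype=float)
    e = np.asarray(experience_years, dtype=float)
    if len(s) != len(e) or len(s) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
        raise ValueError("inputs must be finite")
    if np.ptp(s) == 0 or np.ptp(e) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(s, e)
    return {"rho": float(rho), "p": float(p), "n": len(s)}
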