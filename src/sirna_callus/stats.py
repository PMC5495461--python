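"""Count statistics for unreplicated tag-sequencing libraries.

Every comparison in the pipeline is one pooled library against the
uninduced control (CK): no replicates exist, so differential calls rest on
an exact test for two observed tag counts given two known library depths
(the Audic-Claverie statistic).  Writing N1, N2 for the clean-read totals
and x, y for a tag's counts in the two libraries, the probability of
observing y given x is

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is a negative-binomial mass in y with x+1 "successes" and success
probability N1/(N1+N2).  That identity is what makes exact, closed-form
tail probabilities available through the regularized incomplete beta
function; no series truncation is involved.

The two-sided p-value doubles the smaller of the two one-sided enrichment
tails, with the sample roles exchanged for the second tail:

    p = min(1, 2 * min( P(K >= y | x; N1,N2), P(K' >= x | y; N2,N1) ))

This form is symmetric under swapping (x, N1) with (y, N2) by construction,
which is the behaviour one wants from a test that does not privilege either
library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountProfile",
    "DECall",
    "normalize_rpm",
    "ac_mass",
    "ac_pvalue",
    "bh_adjust",
    "call_de",
    "log_profile",
    "profile_correlation",
    "DE_MODES",
]

LIBRARIES = ("CK", "I", "II", "III")
STAGES = ("I", "II", "III")

#: per-feature-kind defaults: (p/q threshold, |log2fc| threshold, strict lfc, use BH q)
DE_MODES = {
    "sirna": dict(p_thresh=0.01, lfc_thresh=1.0, lfc_strict=False, fdr_mode=False),
    "gene": dict(p_thresh=0.001, lfc_thresh=1.0, lfc_strict=True, fdr_mode=True),
    "methyl": dict(p_thresh=0.05, lfc_thresh=0.0, lfc_strict=False, fdr_mode=True),
}


@dataclass
class CountProfile:
    """Raw counts and RPM for one feature across the four libraries."""

    feature_id: str
    kind: str  # sirna | gene | methyl_region
    counts: np.ndarray  # raw reads, order CK, I, II, III
    rpm: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.rpm = np.asarray(self.rpm, dtype=float)
        if (self.counts < 0).any():
            raise ValueError(f"negative counts for {self.feature_id}")


@dataclass
class DECall:
    feature_id: str
    comparison: str  # e.g. "I_vs_CK"
    x: int  # CK raw count
    y: int  # stage raw count
    N1: float
    N2: float
    rpm_ck: float
    rpm_stage: float
    log2fc: float
    p: float
    q: float
    direction: str  # up | down | ns


def normalize_rpm(counts, library_totals):
    """Reads-per-million normalization: count * 1e6 / library total.

    ``counts`` may be a vector (one feature) or a matrix with libraries in
    columns; ``library_totals`` are the clean-read totals, which must be
    positive.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(library_totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts * 1e6 / totals


def ac_mass(x, y, N1, N2):
    """Probability of stage count ``y`` given control count ``x``.

    Evaluated in log space via log-gamma; finite for x+y well beyond 1e6.
    Accepts scalars or broadcastable arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    r = N2 / N1
    logp = (
        y * np.log(r)
        + special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )
    out = np.exp(logp)
    return float(out) if out.ndim == 0 else out


def _upper_tail(x, y, N1, N2):
    """P(K >= y) for K ~ the stage-count distribution conditioned on x.

    K is negative binomial with x+1 successes and success probability
    N1/(N1+N2); the survival function is a regularized incomplete beta.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    frac2 = N2 / (N1 + N2)
    out = np.where(y <= 0, 1.0, special.betainc(np.maximum(y, 1.0), x + 1.0, frac2))
    return out


def ac_pvalue(x, y, N1, N2, alternative: str = "two-sided"):
    """Exact p-value for a tag's counts in two libraries of known depth.

    ``alternative='greater'`` tests enrichment in the second library,
    ``'less'`` tests depletion, and ``'two-sided'`` (default) doubles the
    smaller one-sided tail, capped at 1.  Vectorized over x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    p_up = _upper_tail(x, y, N1, N2)  # y surprisingly large given x
    p_down = _upper_tail(y, x, N2, N1)  # x surprisingly large given y
    if alternative == "greater":
        out = p_up
    elif alternative == "less":
        out = p_down
    elif alternative == "two-sided":
        out = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(out) if out.ndim == 0 else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    profiles: Sequence[CountProfile],
    library_totals,
    mode: str = "sirna",
    comparisons: Iterable[str] = STAGES,
    p_thresh: float | None = None,
    lfc_thresh: float | None = None,
    pseudocount: float = 0.5,
    fdr_mode: bool | None = None,
) -> list[DECall]:
    """Differential calls, one per feature per stage-vs-CK comparison.

    Thresholds default per ``mode`` (sirna: raw p < 0.01 and |log2fc| >= 1;
    gene: BH q < 0.001 and |log2fc| > 1; methyl: BH q < 0.05).  log2 fold
    changes are computed on RPM with ``pseudocount`` added to both sides,
    so features absent from one library stay finite.
    """
    defaults = DE_MODES[mode]
    p_thresh = defaults["p_thresh"] if p_thresh is None else p_thresh
    lfc_thresh = defaults["lfc_thresh"] if lfc_thresh is None else lfc_thresh
    fdr_mode = defaults["fdr_mode"] if fdr_mode is None else fdr_mode
    lfc_strict = defaults["lfc_strict"]

    totals = np.asarray(library_totals, dtype=float)
    if totals.shape != (4,):
        raise ValueError("library_totals must give the four library depths")
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")

    counts = np.array([pr.counts for pr in profiles], dtype=float)
    if counts.size == 0:
        return []
    rpm = normalize_rpm(counts, totals)
    calls: list[DECall] = []
    for stage in comparisons:
        j = LIBRARIES.index(stage)
        x = counts[:, 0]
        y = counts[:, j]
        p = np.atleast_1d(ac_pvalue(x, y, totals[0], totals[j]))
        q = bh_adjust(p)
        lfc = np.log2((rpm[:, j] + pseudocount) / (rpm[:, 0] + pseudocount))
        crit = q if fdr_mode else p
        if lfc_strict:
            lfc_ok = np.abs(lfc) > lfc_thresh
        else:
            lfc_ok = np.abs(lfc) >= lfc_thresh
        signif = (crit < p_thresh) & lfc_ok
        for i, pr in enumerate(profiles):
            direction = "ns"
            if signif[i]:
                direction = "up" if lfc[i] > 0 else "down"
            calls.append(
                DECall(
                    feature_id=pr.feature_id,
                    comparison=f"{stage}_vs_CK",
                    x=int(x[i]),
                    y=int(y[i]),
                    N1=float(totals[0]),
                    N2=float(totals[j]),
                    rpm_ck=float(rpm[i, 0]),
                    rpm_stage=float(rpm[i, j]),
                    log2fc=float(lfc[i]),
                    p=float(p[i]),
                    q=float(q[i]),
                    direction=direction,
                )
            )
    return calls


def log_profile(rpm, pseudocount: float = 0.5) -> np.ndarray:
    """log2(RPM + pseudocount), the scale on which profiles are correlated."""
    return np.log2(np.asarray(rpm, dtype=float) + pseudocount)


def profile_correlation(profile_a, profile_b) -> float:
    """Pearson correlation of two expression profiles over the same libraries.

    Inputs are expected on the log2(RPM + pseudocount) scale (see
    :func:`log_profile`).  Returns NaN (the undefined marker) when either
    profile has zero variance.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have the same libraries")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
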