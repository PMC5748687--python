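"""Two-library digital differential expression for collapsed small-RNA tags.

Expression is depth-normalised to tags per million clean reads (TPM).
Significance between two un-replicated count libraries uses the
Audic-Claverie conditional exact test: given x reads in library 1 (total n1),
the count y in library 2 (total n2) follows

    P(y | x) = (n2/n1)^y * (x+y)! / (x! * y! * (1 + n2/n1)^(x+y+1))

which is the negative binomial NB(x + 1, n1/(n1+n2)) -- the identity used
here for log-space numerical stability at counts up to 1e7.  Calls follow a
raw p < 0.01 and |log2 ratio| > 1 rule with no multiple-testing correction
by default (a Benjamini-Hochberg flag is available); features seen in only
one library are reported as library-specific rather than given a fold
change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TagLibrary

__all__ = [
    "tpm",
    "exact_count_test",
    "classify_de",
    "de_table",
    "ddct",
    "DEResult",
]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_LOG2 = 1.0
DEFAULT_MIN_SPECIFIC = 2


def tpm(count, total):
    """Tags per million clean reads."""
    count = np.asarray(count, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total < 1):
        raise ValueError("library total must be >= 1 for TPM")
    if np.any(count < 0):
        raise ValueError("negative count")
    out = 1e6 * count / total
    return float(out) if out.ndim == 0 else out


def _ac_one_direction(x, y, n1, n2):
    """Doubled smaller tail of the conditional distribution P(y | x)."""
    p0 = np.asarray(n1, dtype=float) / (np.asarray(n1, dtype=float) + np.asarray(n2, dtype=float))
    left = stats.nbinom.cdf(y, x + 1, p0)
    right = stats.nbinom.sf(y - 1, x + 1, p0)
    return np.minimum(1.0, 2.0 * np.minimum(left, right))


def exact_count_test(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value for counts x (total n1) vs y (total n2).

    Doubles the smaller conditional tail, capped at 1.  The conditional
    construction is directional on a discrete lattice, so the test is
    symmetrised by taking the smaller of the two conditioning directions,
    which makes p(x, y, n, n) == p(y, x, n, n) exactly.  Accepts scalars or
    arrays (broadcast).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative counts")
    if np.any(np.asarray(n1) < 1) or np.any(np.asarray(n2) < 1):
        raise ValueError("library totals must be >= 1")
    p = np.minimum(_ac_one_direction(x, y, n1, n2), _ac_one_direction(y, x, n2, n1))
    return float(p) if p.ndim == 0 else p


@dataclass
class DEResult:
    """One feature's two-library comparison."""

    feature: str
    count_control: int
    count_treatment: int
    tpm_control: float
    tpm_treatment: float
    log2_ratio: float  # NaN when undefined (a zero count)
    p_value: float
    de_class: str  # up | down | ns | specific_control | specific_treatment


def classify_de(
    feature: str,
    count_control: int,
    count_treatment: int,
    total_control: int,
    total_treatment: int,
    *,
    alpha: float = DEFAULT_ALPHA,
    min_log2: float = DEFAULT_MIN_LOG2,
    min_specific: int = DEFAULT_MIN_SPECIFIC,
) -> DEResult | None:
    """Classify one feature; returns None when both counts are zero.

    ``up``/``down`` (treatment relative to control, so "up" means higher
    under treatment) require p < alpha and |log2 ratio| strictly > min_log2.
    A feature with a zero count in exactly one library and at least
    ``min_specific`` reads in the other is library-specific; a zero/nonzero
    pair below ``min_specific`` stays ``ns`` (fold change undefined).
    """
    if count_control == 0 and count_treatment == 0:
        return None
    tc = tpm(count_control, total_control)
    tt = tpm(count_treatment, total_treatment)
    p = exact_count_test(count_control, count_treatment, total_control, total_treatment)
    log2_ratio = float("nan")
    if count_control > 0 and count_treatment > 0:
        log2_ratio = float(np.log2(tt / tc))
        if p < alpha and abs(log2_ratio) > min_log2:
            de_class = "up" if log2_ratio > 0 else "down"
        else:
            de_class = "ns"
    elif count_control == 0 and count_treatment >= min_specific:
        de_class = "specific_treatment"
    elif count_treatment == 0 and count_control >= min_specific:
        de_class = "specific_control"
    else:
        de_class = "ns"
    return DEResult(feature, count_control, count_treatment, tc, tt, log2_ratio, p, de_class)


def de_table(
    control: TagLibrary,
    treatment: TagLibrary,
    features: Sequence[str] | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
    min_log2: float = DEFAULT_MIN_LOG2,
    min_specific: int = DEFAULT_MIN_SPECIFIC,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Vectorised two-library comparison over ``features``.

    ``features`` defaults to the union of tags in both libraries.  Features
    absent from both are dropped.  With ``bh_correct`` the threshold is
    applied to Benjamini-Hochberg adjusted p-values (off by default, matching
    the raw-threshold convention).
    """
    if features is None:
        features = sorted(set(control.tags) | set(treatment.tags))
    feats = [f for f in features if control.count(f) > 0 or treatment.count(f) > 0]
    xc = np.array([control.count(f) for f in feats], dtype=np.int64)
    xt = np.array([treatment.count(f) for f in feats], dtype=np.int64)
    nc, nt = control.total_clean_reads, treatment.total_clean_reads
    tpm_c = tpm(xc, nc)
    tpm_t = tpm(xt, nt)
    p = np.atleast_1d(exact_count_test(xc, xt, nc, nt))
    p_eff = _bh_adjust(p) if bh_correct else p
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.where((xc > 0) & (xt > 0), np.log2(tpm_t / tpm_c), np.nan)

    classes = np.full(len(feats), "ns", dtype=object)
    sig = (p_eff < alpha) & (np.abs(np.nan_to_num(log2_ratio)) > min_log2) & (xc > 0) & (xt > 0)
    classes[sig & (log2_ratio > 0)] = "up"
    classes[sig & (log2_ratio < 0)] = "down"
    classes[(xc == 0) & (xt >= min_specific)] = "specific_treatment"
    classes[(xt == 0) & (xc >= min_specific)] = "specific_control"

    return pd.DataFrame(
        {
            "feature": feats,
            "count_c": xc,
            "count_t": xt,
            "tpm_c": tpm_c,
            "tpm_t": tpm_t,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "class": classes,
        }
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def ddct(dct_treatment: float, dct_control: float) -> float:
    """Relative expression by the 2^(-ddCt) method (qRT-PCR helper)."""
    return float(2.0 ** (-(dct_treatment - dct_control)))
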