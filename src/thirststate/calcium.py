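"""dF/F0 computation, windowed response classification, AUC, and the
contingency statistics for paired drug responses.

Acquisition runs at 5.92 Hz.  The baseline F0 is the mean fluorescence
over the 14 s before drug onset (83 frames); dF/F0 = (F - F0)/F0.  A
cell's response category compares the mean dF/F0 over the 25 s
post-onset window against the pre-window mean +/- its standard
deviation, after normalizing the pre-window mean to 0 per cell:

    activated  iff mu_post > sigma_pre
    inhibited  iff mu_post < -sigma_pre
    no_change  otherwise

Second-based windows are converted to frames by rounding to the nearest
frame.  sigma_pre is the sample (n-1) standard deviation of the raw
(unsmoothed) dF/F0 frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .errors import DataError
from .synthetic_data import TraceSet

__all__ = [
    "FRAME_RATE",
    "ResponseCall",
    "frames_for",
    "compute_dff",
    "classify_response",
    "auc",
    "response_contingency",
    "proportion_shift_test",
]

FRAME_RATE = 5.92
BASELINE_S = 14.0
POST_S = 25.0

CATEGORIES = ("activated", "no_change", "inhibited")


@dataclass
class ResponseCall:
    category: str
    mu_pre: float  # 0 by construction (pre-window normalized per cell)
    sigma_pre: float
    mu_post: float  # relative to the pre-window mean


def frames_for(seconds: float, frame_rate: float = FRAME_RATE) -> int:
    """Nearest-frame count for a second-based window (14 s -> 83)."""
    return int(round(seconds * frame_rate))


def _onset_index(onset_s: float, frame_rate: float) -> int:
    return int(round(onset_s * frame_rate))


def compute_dff(
    values: np.ndarray,
    onset_s: float,
    frame_rate: float = FRAME_RATE,
    baseline_s: float = BASELINE_S,
) -> np.ndarray:
    """dF/F0 with F0 = mean fluorescence over ``baseline_s`` before onset.

    Raises when the baseline window does not fit before onset or when F0
    is non-positive (non-physical baseline).
    """
    values = np.asarray(values, float)
    if not np.all(np.isfinite(values)):
        raise DataError("trace contains non-finite frames")
    i1 = _onset_index(onset_s, frame_rate)
    nb = frames_for(baseline_s, frame_rate)
    if i1 - nb < 0 or i1 > values.shape[-1]:
        raise DataError(
            f"baseline window of {nb} frames does not fit before onset index {i1}"
        )
    f0 = values[..., i1 - nb : i1].mean(axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise DataError("non-positive baseline F0")
    return (values - f0) / f0


def classify_response(
    dff: np.ndarray,
    onset_s: float,
    frame_rate: float = FRAME_RATE,
    pre_s: float = BASELINE_S,
    post_s: float = POST_S,
) -> ResponseCall:
    """Classify one dF/F0 trace as activated / no_change / inhibited."""
    dff = np.asarray(dff, float)
    i1 = _onset_index(onset_s, frame_rate)
    npre, npost = frames_for(pre_s, frame_rate), frames_for(post_s, frame_rate)
    if i1 - npre < 0 or i1 + npost > dff.size:
        raise DataError("pre/post windows not covered by the trace")
    pre = dff[i1 - npre : i1]
    post = dff[i1 : i1 + npost]
    mu_pre_raw = pre.mean()
    sigma_pre = pre.std(ddof=1)
    mu_post = post.mean() - mu_pre_raw  # pre-window mean normalized to 0
    if mu_post > sigma_pre:
        category = "activated"
    elif mu_post < -sigma_pre:
        category = "inhibited"
    else:
        category = "no_change"  # includes the zero-variance, equal-means tie
    return ResponseCall(category, 0.0, float(sigma_pre), float(mu_post))


def classify_traces(traces: TraceSet, pre_s: float = BASELINE_S,
                    post_s: float = POST_S) -> pd.DataFrame:
    """Vector convenience: dF/F0 + classification for every trace in a set."""
    dff = compute_dff(traces.values, traces.onset_s, traces.frame_rate)
    rows = []
    for cid, d in zip(traces.cell_ids, dff):
        call = classify_response(d, traces.onset_s, traces.frame_rate, pre_s, post_s)
        rows.append(dict(cell=cid, category=call.category,
                         sigma_pre=call.sigma_pre, mu_post=call.mu_post))
    return pd.DataFrame(rows)


def auc(
    dff: np.ndarray,
    start_s: float,
    end_s: float,
    frame_rate: float = FRAME_RATE,
    normalize_at_onset: bool = False,
    onset_s: float = None,
) -> float:
    """Trapezoidal integral of dF/F0 over [start_s, end_s] (dF/F0 * s).

    Window bounds are rounded to the nearest frame and both boundary
    frames are included, so adjacent windows sharing a boundary add
    exactly.  With ``normalize_at_onset`` the series is shifted so its
    value at drug onset is 0 (per-cell variance normalization).
    """
    dff = np.asarray(dff, float)
    i0 = int(round(start_s * frame_rate))
    i1 = int(round(end_s * frame_rate))
    if i1 <= i0 or i0 < 0 or i1 >= dff.size:
        raise DataError(f"empty or out-of-range AUC window [{start_s}, {end_s}] s")
    y = dff
    if normalize_at_onset:
        if onset_s is None:
            raise DataError("normalize_at_onset requires onset_s")
        y = dff - dff[_onset_index(onset_s, frame_rate)]
    return float(np.trapezoid(y[i0 : i1 + 1], dx=1.0 / frame_rate))


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

def response_contingency(calls_a, calls_b, mode: str = "2x2") -> dict:
    """Matched/mismatched contingency between per-cell calls to two drugs.

    Default ``2x2`` mode restricts to cells that are activated or
    inhibited under both drugs and builds the 2x2 table drugA
    {activated, inhibited} x drugB {activated, inhibited}; the odds
    ratio ad/bc quantifies matching and the two-sided Fisher exact
    p-value comes from the hypergeometric distribution.  ``3x3`` mode
    returns the full category x category table with a chi-square test.

    With a zero margin the odds ratio is reported with a Haldane
    (add 0.5) correction and flagged; the exact p is unaffected.
    """
    a = np.asarray(calls_a, dtype=object)
    b = np.asarray(calls_b, dtype=object)
    if a.shape != b.shape:
        raise DataError("call vectors must align cell-by-cell")

    if mode == "3x3":
        table = pd.crosstab(
            pd.Categorical(a, categories=CATEGORIES),
            pd.Categorical(b, categories=CATEGORIES),
            dropna=False,
        ).to_numpy()
        matched = int(np.trace(table))
        sub = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        res = chi2_contingency(sub)
        return dict(table=table, matched=matched,
                    mismatched=int(table.sum() - matched), p=float(res.pvalue))
    if mode != "2x2":
        raise DataError(f"unknown contingency mode: {mode}")

    keep = np.isin(a, ("activated", "inhibited")) & np.isin(b, ("activated", "inhibited"))
    aa, bb = a[keep], b[keep]
    t = np.array(
        [
            [(aa == ra).__and__(bb == rb).sum() for rb in ("activated", "inhibited")]
            for ra in ("activated", "inhibited")
        ],
        dtype=int,
    )
    matched = int(t[0, 0] + t[1, 1])
    mismatched = int(t[0, 1] + t[1, 0])
    bc = int(t[0, 1]) * int(t[1, 0])
    if bc > 0:
        odds = t[0, 0] * t[1, 1] / bc
        haldane = False
    else:
        th = t + 0.5
        odds = th[0, 0] * th[1, 1] / (th[0, 1] * th[1, 0])
        haldane = True
    p = float(fisher_exact(t, alternative="two-sided").pvalue)
    return dict(
        table=t, matched=matched, mismatched=mismatched,
        odds_ratio=float(odds), p=p, haldane=haldane, n=int(t.sum()),
    )


def proportion_shift_test(
    counts: pd.DataFrame,
    responsive=("activated",),
) -> pd.DataFrame:
    """Pairwise Fisher exact tests of response proportions across states,
    Bonferroni-corrected.

    ``counts`` is a states x categories table of cell counts (one drug).
    Each state pair is collapsed to responsive-vs-not (categories in
    ``responsive`` count as responsive) and tested; the corrected
    p-value multiplies the raw p by the number of comparisons, capped at
    1.  Empty states are skipped.
    """
    states = [s for s in counts.index if counts.loc[s].sum() > 0]
    if len(states) < 2:
        raise DataError("need at least 2 non-empty states")
    resp_cols = [c for c in counts.columns if c in responsive]
    rows = []
    pairs = list(combinations(states, 2))
    for s1, s2 in pairs:
        r1 = int(counts.loc[s1, resp_cols].sum())
        n1 = int(counts.loc[s1].sum())
        r2 = int(counts.loc[s2, resp_cols].sum())
        n2 = int(counts.loc[s2].sum())
        t = [[r1, n1 - r1], [r2, n2 - r2]]
        p = float(fisher_exact(t, alternative="two-sided").pvalue)
        rows.append(dict(state_a=s1, state_b=s2,
                         prop_a=r1 / n1, prop_b=r2 / n2, p=p))
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out
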