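"""Excitatory/inhibitory balance: ratios, summaries and hypothesis tests.

The E/I ratio is the ratio of GLU (excitatory) to GABA (inhibitory)
concentration, computed per response or per behavioural epoch. Group
summaries use mean ± SEM for stimulated-slice conditions and mean ± SD
for in vivo epochs. Group comparisons use the independent two-sided
Wilcoxon rank-sum test at alpha = 0.05, with exact enumeration of all
rank splits for small samples (combined n <= 16, midranks under ties)
and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .deconvolution import ConcentrationTrace
from .trace_io import EventTable

__all__ = [
    "EIResult",
    "ei_ratio",
    "epoch_summary",
    "pooled_mean",
    "compare_groups",
    "rank_sum_exact",
    "frequency_response_table",
]

EXACT_MAX_N = 16


@dataclass
class EIResult:
    """One E/I summary row (per response, epoch or session)."""

    unit: str  # response | epoch | session
    label: str  # condition (frequency or behaviour)
    glu: float  # µM
    gaba: float  # µM
    ei: float  # glu/gaba; NaN when undefined
    ei_defined: bool
    n: int
    dispersion: float = float("nan")
    dispersion_kind: str = ""  # sem | sd


def ei_ratio(glu: float, gaba: float) -> tuple[float, bool]:
    """GLU/GABA ratio; ``(nan, False)`` when GABA <= 0 (undefined)."""
    if glu < 0:
        raise ValueError("glu must be non-negative")
    if gaba <= 0:
        return float("nan"), False
    return glu / gaba, True


def epoch_summary(conc: ConcentrationTrace, epochs: EventTable | list) -> list[EIResult]:
    """Mean [GLU], [GABA] and their E/I for each behavioural epoch.

    Empty epochs (no samples) are skipped. The per-epoch E/I is the ratio
    of the epoch means; dispersion is the SD of the per-sample ratio's
    numerator/denominator means is not meaningful, so the SD reported is
    that of the per-sample instantaneous ratio within the epoch.
    """
    eps = epochs.epochs if isinstance(epochs, EventTable) else list(epochs)
    t = conc.time
    out = []
    for ep in eps:
        sel = (t >= ep.start) & (t < ep.end)
        n = int(sel.sum())
        if n == 0:
            continue
        glu_m = float(np.mean(conc.glu[sel]))
        gaba_m = float(np.mean(conc.gaba[sel]))
        ei, ok = ei_ratio(glu_m, gaba_m)
        gaba_s = conc.gaba[sel]
        with np.errstate(divide="ignore", invalid="ignore"):
            inst = np.where(gaba_s > 0, conc.glu[sel] / np.where(gaba_s > 0, gaba_s, 1.0), np.nan)
        out.append(
            EIResult(
                unit="epoch",
                label=ep.label,
                glu=glu_m,
                gaba=gaba_m,
                ei=ei,
                ei_defined=ok,
                n=n,
                dispersion=float(np.nanstd(inst, ddof=1)) if n > 1 else 0.0,
                dispersion_kind="sd",
            )
        )
    return out


def pooled_mean(group_means, group_ns) -> float:
    """Sample-size-weighted mean of group means: sum(n_i m_i) / sum(n_i)."""
    if len(group_means) != len(group_ns):
        raise ValueError("group_means and group_ns lengths differ")
    if any(n < 1 for n in group_ns):
        raise ValueError("group sizes must be >= 1")
    ns = np.asarray(group_ns, dtype=float)
    return float(np.dot(group_means, ns) / ns.sum())


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_exact(a, b) -> tuple[float, float]:
    """Exact two-sided rank-sum test by full enumeration.

    Enumerates every assignment of the pooled midranks to a group of
    size len(a); the p-value is the fraction of assignments whose rank
    sum deviates from its mean at least as much as the observed one.
    Handles ties through midranks. Returns (W = rank sum of a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    na, n = len(a), len(pooled)
    w_obs = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = total = 0
    for idx in combinations(range(n), na):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return w_obs, count / total


def compare_groups(sample_a, sample_b, alpha: float = 0.05) -> dict:
    """Independent two-sided Wilcoxon rank-sum comparison of two groups.

    Exact enumeration when the combined sample is small (n <= 16),
    otherwise the normal approximation with tie correction. Returns
    ``{"statistic": W_a, "p": p, "significant": p <= alpha, "method": ...}``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    n = len(a) + len(b)
    if n <= EXACT_MAX_N:
        w, p = rank_sum_exact(a, b)
        method = "exact"
    else:
        ranks = _midranks(np.concatenate([a, b]))
        w = float(ranks[: len(a)].sum())
        na, nb = len(a), len(b)
        mu = na * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / math.sqrt(var)  # continuity corrected
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        p = min(p, 1.0)
        method = "normal_tie_corrected"
    return {"statistic": w, "p": p, "significant": p <= alpha, "method": method}


def frequency_response_table(
    peaks_by_condition: dict,
    alpha: float = 0.05,
    mode: str = "per_response",
) -> tuple[list[EIResult], list[dict]]:
    """Summarise peak concentrations and E/I across stimulation conditions.

    ``peaks_by_condition`` maps a condition label (e.g. ``"control"``,
    ``10``, ``50``, ``140``) to a list of retained ``(glu µM, gaba µM)``
    peak pairs. Per condition and analyte the summary reports mean ± SEM;
    E/I is computed per response then averaged (``mode="per_response"``,
    the default) or as the ratio of condition means
    (``mode="ratio_of_means"``). Pairwise rank-sum tests compare the
    per-response E/I between all condition pairs, unadjusted.

    Empty conditions are excluded (with a warning entry in the tests
    list); fewer than two non-empty conditions is an error.
    """
    if mode not in ("per_response", "ratio_of_means"):
        raise ValueError(f"unknown mode {mode!r}")
    cond_ei: dict = {}
    rows: list[EIResult] = []
    warnings: list[dict] = []
    for label, pairs in peaks_by_condition.items():
        pairs = [(g, i) for g, i in pairs]
        if not pairs:
            warnings.append({"condition": str(label), "warning": "no retained peaks"})
            continue
        glu = np.array([p[0] for p in pairs], dtype=float)
        gaba = np.array([p[1] for p in pairs], dtype=float)
        per_ei = np.array([ei_ratio(g, i)[0] for g, i in pairs])
        defined = np.isfinite(per_ei)
        if mode == "per_response":
            ei = float(np.mean(per_ei[defined])) if defined.any() else float("nan")
        else:
            ei, _ = ei_ratio(float(glu.mean()), float(gaba.mean()))
        n = len(pairs)
        rows.append(
            EIResult(
                unit="response",
                label=str(label),
                glu=float(glu.mean()),
                gaba=float(gaba.mean()),
                ei=ei,
                ei_defined=bool(defined.any()),
                n=n,
                dispersion=float(np.std(per_ei[defined], ddof=1) / math.sqrt(defined.sum()))
                if defined.sum() > 1
                else 0.0,
                dispersion_kind="sem",
            )
        )
        cond_ei[str(label)] = per_ei[defined]
    if len(rows) < 2:
        raise ValueError("need >= 2 conditions with retained peaks")
    tests = list(warnings)
    labels = [r.label for r in rows]
    for la, lb in combinations(labels, 2):
        if len(cond_ei[la]) < 2 or len(cond_ei[lb]) < 2:
            continue
        res = compare_groups(cond_ei[la], cond_ei[lb], alpha=alpha)
        res.update(condition_a=la, condition_b=lb)
        tests.append(res)
    return rows, tests
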