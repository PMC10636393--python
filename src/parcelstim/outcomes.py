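"""Clinical outcome classification and cohort summaries.

Response and remission follow the Riedel BDI criteria: response is a
decrease of >= 47% from the baseline BDI; remission is a BDI of <= 12
(boundary inclusive). Severity bands follow the BDI-II convention.
Group comparisons of percent BDI change use the Mann-Whitney rank-sum
test with exact enumeration at small sample sizes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


class OutcomeError(ValueError):
    pass


BDI_MIN, BDI_MAX = 0, 63
REMISSION_CUTOFF = 12
RESPONSE_DROP = 0.47


def _check_bdi(score, name="score"):
    if not BDI_MIN <= score <= BDI_MAX:
        raise OutcomeError(f"{name} {score} outside BDI scale "
                           f"[{BDI_MIN}, {BDI_MAX}]")


def classify_response(baseline, later) -> bool:
    """True when the BDI decreased by at least 47% from baseline."""
    _check_bdi(baseline, "baseline")
    _check_bdi(later, "later")
    if baseline == 0:
        raise OutcomeError("baseline of 0: percent change undefined")
    return (baseline - later) / baseline >= RESPONSE_DROP


def classify_remission(score) -> bool:
    """True when the BDI is at or below the remission cutoff of 12."""
    _check_bdi(score)
    return score <= REMISSION_CUTOFF


def severity_band(score) -> str:
    """BDI-II severity: 0-13 minimal, 14-19 mild, 20-28 moderate,
    29-63 severe."""
    _check_bdi(score)
    if score < 14:
        return "minimal"
    if score < 20:
        return "mild"
    if score < 29:
        return "moderate"
    return "severe"


def percent_change(baseline, later) -> float:
    """Percent BDI reduction from baseline (positive = improvement)."""
    if baseline == 0:
        raise OutcomeError("baseline of 0: percent change undefined")
    return (baseline - later) / baseline * 100.0


@dataclass
class OutcomeRecord:
    """One patient's BDI / EQ-5D trajectory.

    Follow-up fields are None for patients lost to follow-up. The TRD
    flag (treatment-resistant depression: >= 2 failed adequate
    antidepressant trials) is taken as input, not derived.
    """

    patient_id: object
    bdi_baseline: int
    bdi_post: int
    bdi_followup: int = None
    eq5d_baseline: float = None
    eq5d_post: float = None
    eq5d_followup: float = None
    trd: bool = False
    followup_interval_months: float = 0.0

    def __post_init__(self):
        _check_bdi(self.bdi_baseline, "bdi_baseline")
        _check_bdi(self.bdi_post, "bdi_post")
        if self.bdi_followup is not None:
            _check_bdi(self.bdi_followup, "bdi_followup")
        for name in ("eq5d_baseline", "eq5d_post", "eq5d_followup"):
            v = getattr(self, name)
            if v is not None and not -1.0 <= v <= 1.0:
                raise OutcomeError(f"{name} {v} outside EQ-5D index "
                                   "[-1, 1]")
        if self.followup_interval_months < 0:
            raise OutcomeError("follow-up interval must be >= 0 months")

    @property
    def has_followup(self) -> bool:
        return self.bdi_followup is not None

    def response_post(self) -> bool:
        return classify_response(self.bdi_baseline, self.bdi_post)

    def remission_post(self) -> bool:
        return classify_remission(self.bdi_post)

    def response_followup(self):
        if not self.has_followup:
            return None
        return classify_response(self.bdi_baseline, self.bdi_followup)

    def remission_followup(self):
        if not self.has_followup:
            return None
        return classify_remission(self.bdi_followup)


@dataclass
class CohortSummary:
    """Cohort-level rates and descriptive statistics.

    Post-treatment denominators include every patient; follow-up
    denominators include completers only.
    """

    n: int
    n_followup: int
    response_rate_post: float
    remission_rate_post: float
    response_rate_fu: float
    remission_rate_fu: float
    bdi_mean_sd: dict
    eq5d_mean_sd: dict
    trd_comparison: dict = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def report(self) -> str:
        lines = [
            "Cohort outcome summary",
            "=" * 40,
            f"Patients                   {self.n}",
            f"Follow-up completers       {self.n_followup}",
            f"Response (post)            {self.response_rate_post:.0%}",
            f"Remission (post)           {self.remission_rate_post:.0%}",
        ]
        if self.n_followup:
            lines += [
                f"Response (follow-up)       {self.response_rate_fu:.0%}",
                f"Remission (follow-up)      {self.remission_rate_fu:.0%}",
            ]
        for inst, d in (("BDI", self.bdi_mean_sd),
                        ("EQ-5D", self.eq5d_mean_sd)):
            for tp, ms in d.items():
                if ms["mean"] is not None:
                    lines.append(f"{inst:<6}{tp:<20} "
                                 f"{ms['mean']:.2f} +/- {ms['sd']:.2f}")
        if self.trd_comparison:
            c = self.trd_comparison
            lines.append(
                f"TRD vs non-TRD %change (post): U={c['post']['statistic']:.1f}"
                f" p={c['post']['pvalue']:.4f}")
        return "\n".join(lines)


def _mean_sd(values) -> dict:
    values = [v for v in values if v is not None]
    if not values:
        return {"mean": None, "sd": None, "n": 0}
    arr = np.asarray(values, float)
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size)}


def summarize_cohort(records, compare_trd: bool = True) -> CohortSummary:
    """Response/remission rates plus per-instrument descriptives.

    Group statistics are deliberately descriptive (means/SDs and a
    rank-sum comparison of percent change between TRD and non-TRD
    patients); no longitudinal mixed modelling is attempted.
    """
    if not records:
        raise OutcomeError("need at least one record")
    n = len(records)
    fus = [r for r in records if r.has_followup]
    n_fu = len(fus)
    summary = CohortSummary(
        n=n, n_followup=n_fu,
        response_rate_post=np.mean([r.response_post() for r in records]),
        remission_rate_post=np.mean([r.remission_post() for r in records]),
        response_rate_fu=(np.mean([r.response_followup() for r in fus])
                          if fus else float("nan")),
        remission_rate_fu=(np.mean([r.remission_followup() for r in fus])
                           if fus else float("nan")),
        bdi_mean_sd={
            "baseline": _mean_sd([r.bdi_baseline for r in records]),
            "post": _mean_sd([r.bdi_post for r in records]),
            "followup": _mean_sd([r.bdi_followup for r in fus]),
        },
        eq5d_mean_sd={
            "baseline": _mean_sd([r.eq5d_baseline for r in records]),
            "post": _mean_sd([r.eq5d_post for r in records]),
            "followup": _mean_sd([r.eq5d_followup for r in fus]),
        },
    )
    if compare_trd:
        trd = [r for r in records if r.trd]
        non = [r for r in records if not r.trd]
        comp = {}
        if trd and non:
            comp["post"] = rank_sum_test(
                [percent_change(r.bdi_baseline, r.bdi_post) for r in trd],
                [percent_change(r.bdi_baseline, r.bdi_post) for r in non])
            trd_fu = [r for r in trd if r.has_followup]
            non_fu = [r for r in non if r.has_followup]
            if trd_fu and non_fu:
                comp["followup"] = rank_sum_test(
                    [percent_change(r.bdi_baseline, r.bdi_followup)
                     for r in trd_fu],
                    [percent_change(r.bdi_baseline, r.bdi_followup)
                     for r in non_fu])
        summary.trd_comparison = comp or None
    return summary


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------

def _u_statistic(a, b):
    """U of group a: pairs with a > b, ties counted half."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def rank_sum_test(group_a, group_b) -> dict:
    """Two-sided Mann-Whitney U test on two samples.

    Exact permutation enumeration (ties handled) when both groups have at
    most 8 observations; otherwise the tie-corrected normal approximation
    with continuity correction. Returns {"statistic", "pvalue", "method"}.
    """
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size == 0 or b.size == 0:
        raise OutcomeError("both groups must be non-empty")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    center = n1 * n2 / 2.0
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        dev = abs(u - center)
        hits = total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(comb)] = True
            up = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(up - center) >= dev - 1e-12:
                hits += 1
        return {"statistic": u, "pvalue": hits / total, "method": "exact"}
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return {"statistic": u, "pvalue": 1.0, "method": "normal"}
    from scipy.stats import norm
    z = (abs(u - center) - 0.5) / np.sqrt(var)
    p = 2 * norm.sf(max(z, 0.0))
    return {"statistic": u, "pvalue": min(1.0, p), "method": "normal"}


# -- IO ---------------------------------------------------------------------

OUTCOME_COLUMNS = ["patient_id", "bdi_baseline", "bdi_post", "bdi_followup",
                   "eq5d_baseline", "eq5d_post", "eq5d_followup", "trd",
                   "followup_interval_months"]


def records_to_csv(records, path) -> None:
    pd.DataFrame([asdict(r) for r in records])[OUTCOME_COLUMNS].to_csv(
        path, index=False)


def records_from_csv(path) -> list:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        d = row.to_dict()
        for k in ("bdi_followup", "eq5d_followup"):
            if pd.isna(d.get(k)):
                d[k] = None
        if d["bdi_followup"] is not None:
            d["bdi_followup"] = int(d["bdi_followup"])
        d["bdi_baseline"] = int(d["bdi_baseline"])
        d["bdi_post"] = int(d["bdi_post"])
        d["trd"] = bool(d["trd"])
        records.append(OutcomeRecord(**d))
    return records
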