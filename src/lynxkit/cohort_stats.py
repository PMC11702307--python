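"""Questionnaire scoring and genotype-group association statistics.

State/trait anxiety inventories (STAI-like, STICSA-like) and the Creative
Behavior Inventory (CBI) are sum-score instruments: each item is rated on a
bounded scale (1–4 for the anxiety instruments) and some items are
reverse-keyed so that a higher weight always means a more
anxiety-expressing (or more creative) response.  Because the item text is
licensed, this module ships structural specifications only — item counts,
subscale membership, reverse-key id sets and thresholds — and users supply
their own keyed specs for real data.

Group contrasts between variant carriers and the reference population use
independent two-tailed t-tests (Welch by default; the carrier group is far
smaller than the reference group), two-tailed Fisher exact tests on
high-anxiety threshold tables, and Cohen's d computed from group summary
statistics with the pooled-SD formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuestionnaireSpec",
    "ParticipantRecord",
    "CohortComparison",
    "HIGH_ANXIETY_THRESHOLDS",
    "default_specs",
    "score_questionnaire",
    "classify_high_anxiety",
    "t_test_two_tailed",
    "fisher_exact_two_tailed",
    "cohens_d",
    "dsm_item_comparison",
    "cohort_report",
]

#: Published screening thresholds: a total score at or above the threshold
#: counts as high (STICSA 43, STAI 45; CBI partition at 40).
HIGH_ANXIETY_THRESHOLDS = {"STICSA": 43, "STAI": 45, "CBI": 40}


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Structural description of a sum-score instrument.

    ``items`` is an ordered tuple of (item_id, subscale) pairs; subscales
    partition the items.  ``reverse_keyed`` item weights are mirrored onto
    the anxiety-increasing continuum during scoring.
    """

    instrument: str
    items: tuple  # ((item_id, subscale), ...)
    reverse_keyed: frozenset = frozenset()
    response_min: int = 1
    response_max: int = 4
    threshold: int | None = None

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids")
        if not self.reverse_keyed <= set(ids):
            raise ValueError("reverse_keyed must be a subset of item ids")
        if not self.response_min < self.response_max:
            raise ValueError("response range must be non-degenerate")

    @property
    def subscales(self) -> tuple:
        seen = []
        for _, s in self.items:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def items_of(self, subscale: str) -> tuple:
        return tuple(i for i, s in self.items if s == subscale)


def _spec_stai_like() -> QuestionnaireSpec:
    # 20 state + 20 trait items, 1-4 response range; roughly half the items
    # of the real instrument are reverse-keyed, here the odd-numbered ones.
    items = tuple((f"s{i:02d}", "state") for i in range(1, 21)) + tuple(
        (f"t{i:02d}", "trait") for i in range(1, 21)
    )
    reverse = frozenset(f"{p}{i:02d}" for p in "st" for i in range(1, 21, 2))
    return QuestionnaireSpec("STAI", items, reverse, threshold=HIGH_ANXIETY_THRESHOLDS["STAI"])


def _spec_sticsa_like() -> QuestionnaireSpec:
    # 21 state + 21 trait items (10 cognitive + 11 somatic per scale); the
    # real instrument has no reverse-keyed items.
    items = tuple(
        (f"s{i:02d}", "state-cognitive" if i <= 10 else "state-somatic")
        for i in range(1, 22)
    ) + tuple(
        (f"t{i:02d}", "trait-cognitive" if i <= 10 else "trait-somatic")
        for i in range(1, 22)
    )
    return QuestionnaireSpec(
        "STICSA", items, frozenset(), threshold=HIGH_ANXIETY_THRESHOLDS["STICSA"]
    )


def _spec_cbi_like() -> QuestionnaireSpec:
    # CBI components summed into a total creativity score; 28 items rated
    # 1-4 here so the achievable range comfortably brackets the published
    # group means and the 40-point partition.
    components = ("literature", "music", "crafts", "art", "math_science", "performing")
    items = tuple(
        (f"{c}{i}", c) for c in components for i in range(1, 6 if c != "performing" else 4)
    )
    return QuestionnaireSpec("CBI", items, frozenset(), threshold=HIGH_ANXIETY_THRESHOLDS["CBI"])


def default_specs() -> dict:
    """Documented default structural specs keyed by instrument id."""
    specs = [_spec_stai_like(), _spec_sticsa_like(), _spec_cbi_like()]
    return {s.instrument: s for s in specs}


@dataclass
class ParticipantRecord:
    """Item-level responses for one participant."""

    participant_id: str
    genotype_class: str  # "reference" or a variant label, e.g. "Q39H"
    responses: dict  # instrument -> {item_id: int | None}
    age: float | None = None
    sex: str | None = None


@dataclass(frozen=True)
class CohortComparison:
    """Group-contrast summary for one instrument measure."""

    instrument: str
    measure: str  # subscale name or "total"
    n_reference: int
    n_carrier: int
    mean_reference: float
    mean_carrier: float
    sem_reference: float
    sem_carrier: float
    test: str
    statistic: float
    p_value: float
    cohens_d: float
    #: [[ref_below, ref_at_or_above], [carrier_below, carrier_at_or_above]]
    threshold_table: tuple | None = None
    fisher_p: float | None = None


class MissingResponseError(ValueError):
    """An item is unanswered and no missing-data policy was invoked."""


def score_questionnaire(
    record: ParticipantRecord,
    spec: QuestionnaireSpec,
    missing_policy: str = "error",
) -> dict:
    """Sum-score one instrument for one participant.

    Item weight equals the raw response for normally keyed items and
    ``response_max + response_min − response`` for reverse-keyed items, so
    weights always increase with the anxiety- (or creativity-) expressing
    direction.  Subscale scores are sums of member-item weights and the
    total is the sum over all items (state + trait for the anxiety
    instruments).

    ``missing_policy``: "error" raises on any unanswered item; "exclude"
    returns None for every subscale containing a missing item (and for the
    total if any item is missing).
    """
    if missing_policy not in ("error", "exclude"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    answers = record.responses.get(spec.instrument, {})
    weights: dict = {}
    for item_id, _subscale in spec.items:
        r = answers.get(item_id)
        if r is None:
            if missing_policy == "error":
                raise MissingResponseError(
                    f"{record.participant_id}: item {item_id} of {spec.instrument} unanswered"
                )
            weights[item_id] = None
            continue
        if not spec.response_min <= r <= spec.response_max:
            raise ValueError(
                f"response {r} for item {item_id} outside "
                f"[{spec.response_min}, {spec.response_max}]"
            )
        weights[item_id] = (
            spec.response_max + spec.response_min - r
            if item_id in spec.reverse_keyed
            else r
        )
    scores: dict = {}
    complete = True
    for subscale in spec.subscales:
        ws = [weights[i] for i in spec.items_of(subscale)]
        if any(w is None for w in ws):
            scores[subscale] = None
            complete = False
        else:
            scores[subscale] = int(sum(ws))
    scores["total"] = (
        int(sum(w for w in weights.values())) if complete else None
    )
    return scores


def classify_high_anxiety(score: float, instrument: str) -> bool:
    """True iff the total score reaches the instrument's published threshold."""
    try:
        threshold = HIGH_ANXIETY_THRESHOLDS[instrument]
    except KeyError:
        raise ValueError(f"unknown instrument {instrument!r}") from None
    return score >= threshold


def t_test_two_tailed(group_a, group_b, variant: str = "welch") -> tuple:
    """Independent two-tailed t-test; returns (statistic, p).

    ``variant`` is "welch" (default; unequal variances) or "student"
    (pooled variance).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance with unequal means")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p for a 2×2 table of counts.

    Probability-mass definition: the sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable than
    the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def cohens_d(
    mean_a: float, sem_a: float, n_a: int, mean_b: float, sem_b: float, n_b: int
) -> float:
    """Cohen's d from group summary statistics.

    Group SD is recovered as SEM·√n; the pooled SD uses (n−1) weights, and
    d is the absolute standardized mean difference.
    """
    if n_a <= 1 or n_b <= 1:
        raise ValueError("each group needs n > 1")
    sd_a = sem_a * math.sqrt(n_a)
    sd_b = sem_b * math.sqrt(n_b)
    pooled = math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return abs(mean_b - mean_a) / pooled


def _cohens_d_from_samples(a: np.ndarray, b: np.ndarray) -> float:
    n_a, n_b = a.size, b.size
    return cohens_d(
        float(a.mean()), float(a.std(ddof=1)) / math.sqrt(n_a), n_a,
        float(b.mean()), float(b.std(ddof=1)) / math.sqrt(n_b), n_b,
    )


def dsm_item_comparison(
    cohort: pd.DataFrame,
    dsm_item_ids,
    reverse_ids=(),
    spec: QuestionnaireSpec | None = None,
    carrier_label: str | None = None,
) -> pd.DataFrame:
    """Per-item group means for a set of diagnosis-aligned questions.

    Items whose phrasing runs against the anxiety-increasing continuum
    (e.g. "I feel rested") are listed in ``reverse_ids`` and re-keyed as
    ``max + min − response`` before group means are computed.  ``cohort``
    is the long-format table (participant_id, genotype_class, instrument,
    item_id, response).
    """
    dsm_item_ids = list(dsm_item_ids)
    if not dsm_item_ids:
        raise ValueError("empty DSM item set")
    lo, hi = (spec.response_min, spec.response_max) if spec else (1, 4)
    sub = cohort[cohort["item_id"].isin(dsm_item_ids)].copy()
    missing = set(dsm_item_ids) - set(sub["item_id"])
    if missing:
        raise ValueError(f"items absent from cohort table: {sorted(missing)}")
    rev = sub["item_id"].isin(set(reverse_ids))
    sub.loc[rev, "response"] = hi + lo - sub.loc[rev, "response"]
    if carrier_label is not None:
        sub = sub[sub["genotype_class"].isin(["reference", carrier_label])]
    out = (
        sub.groupby(["item_id", "genotype_class"])["response"]
        .mean()
        .unstack("genotype_class")
        .reindex(dsm_item_ids)
    )
    out.columns.name = None
    return out


def _scores_frame(cohort: pd.DataFrame, spec: QuestionnaireSpec) -> pd.DataFrame:
    """Per-participant subscale/total scores for one instrument (long cohort in)."""
    sub = cohort[cohort["instrument"] == spec.instrument]
    rows = []
    for (pid, group), part in sub.groupby(["participant_id", "genotype_class"]):
        answers = dict(zip(part["item_id"], part["response"].astype("Int64")))
        record = ParticipantRecord(pid, group, {spec.instrument: {
            k: (None if pd.isna(v) else int(v)) for k, v in answers.items()
        }})
        scores = score_questionnaire(record, spec, missing_policy="exclude")
        rows.append({"participant_id": pid, "genotype_class": group, **scores})
    return pd.DataFrame(rows)


def cohort_report(
    cohort: pd.DataFrame,
    specs: dict | None = None,
    carrier_label: str | None = None,
    t_variant: str = "welch",
) -> dict:
    """Full carrier-vs-reference report across instruments.

    For every instrument present in the cohort table: one
    :class:`CohortComparison` per subscale plus the total, with group
    means ± SEM, the two-tailed t-test, Cohen's d, and — for totals with a
    published threshold — the high/low contingency table and its
    two-tailed Fisher exact p.  Also reports the carrier tally
    (count, percentage of all participants).

    ``carrier_label``: restrict the carrier group to one genotype class;
    default pools every non-reference class.
    """
    specs = specs or default_specs()
    participants = cohort[["participant_id", "genotype_class"]].drop_duplicates()
    total_n = len(participants)
    if carrier_label is None:
        carrier_mask = participants["genotype_class"] != "reference"
    else:
        carrier_mask = participants["genotype_class"] == carrier_label
    n_carriers = int(carrier_mask.sum())
    if n_carriers == 0 or n_carriers == total_n:
        raise ValueError("need at least one carrier and one reference participant")

    comparisons = []
    for inst in sorted(cohort["instrument"].unique()):
        spec = specs[inst]
        frame = _scores_frame(cohort, spec)
        is_carrier = (
            frame["genotype_class"] != "reference"
            if carrier_label is None
            else frame["genotype_class"] == carrier_label
        )
        for measure in list(spec.subscales) + ["total"]:
            col = frame[measure].astype(float)
            a = col[~is_carrier].dropna().to_numpy()  # reference
            b = col[is_carrier].dropna().to_numpy()  # carriers
            if a.size < 2 or b.size < 2:
                continue
            statistic, p = t_test_two_tailed(a, b, variant=t_variant)
            same = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
            d = 0.0 if same else _cohens_d_from_samples(a, b)
            table = fisher_p = None
            if measure == "total" and spec.threshold is not None:
                high_a = int((a >= spec.threshold).sum())
                high_b = int((b >= spec.threshold).sum())
                table = ((a.size - high_a, high_a), (b.size - high_b, high_b))
                fisher_p = fisher_exact_two_tailed(np.array(table))
            comparisons.append(
                CohortComparison(
                    instrument=inst,
                    measure=measure,
                    n_reference=int(a.size),
                    n_carrier=int(b.size),
                    mean_reference=float(a.mean()),
                    mean_carrier=float(b.mean()),
                    sem_reference=float(a.std(ddof=1) / math.sqrt(a.size)),
                    sem_carrier=float(b.std(ddof=1) / math.sqrt(b.size)),
                    test=f"t-{t_variant}",
                    statistic=statistic,
                    p_value=p,
                    cohens_d=d,
                    threshold_table=table,
                    fisher_p=fisher_p,
                )
            )
    return {
        "n_participants": total_n,
        "n_carriers": n_carriers,
        "carrier_percent": round(100.0 * n_carriers / total_n, 1),
        "comparisons": comparisons,
    }
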