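"""Rank-based calling of differential intron-retention events.

The caller proceeds in four steps over the per-intron feature table:

1. **Removal criteria** — introns failing any of the quality criteria
   (strict inequalities, checked in a fixed order) are dropped, and the
   first failed criterion is recorded in an audit.
2. **Delta features** — per condition, IE = N_intron/N_exon,
   IJ = N_intron/N_junc (both pseudo-counted), IC = e^N_coverage; the
   treatment-over-control log2 ratios DIE, DIJ, DIC measure retention gain.
   A candidate with any non-positive delta is flagged as noise and excluded.
3. **Normalization** — each delta is divided by its maximum over the
   surviving candidate set, mapping it into (0, 1].
4. **Score and rank** — IRScore = w1*NDIE + w2*NDIJ + w3*NDIC with weights
   summing to 1 (equal by default); candidates are ranked by descending
   score and the top-n% (ceiling) are returned as IR events.

The expression-ratio criterion keeps an intron only when treatment and
control expression are similar — log2(T/C) inside the open band
(log2(2/3), log2(3/2)) — so that expression shifts between conditions are
not mistaken for retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
DEFAULT_PSEUDO = 1.0
LOG2E = math.log2(math.e)

#: ranked-output columns
CALL_COLUMNS = [
    "rank", "intron_id", "chrom", "start", "end", "strand",
    "ir_score", "ndie", "ndij", "ndic", "die", "dij", "dic",
]


@dataclass(frozen=True)
class RemovalCriteria:
    """Thresholds of the intron removal criteria; all comparisons are strict."""

    min_tn5ss: float = 3.0
    min_tn3ss: float = 3.0
    min_tncoverage: float = 0.9
    min_tnexon: float = 1.0
    min_tnexpression: float = 10.0
    min_tnintron: float = 1.0
    min_cnexpression: float = 10.0
    min_cnjunc: float = 1.0
    min_cnexon: float = 1.0
    expression_ratio_band: tuple[float, float] = (
        math.log2(2.0 / 3.0),
        math.log2(3.0 / 2.0),
    )

    def __post_init__(self) -> None:
        lo, hi = self.expression_ratio_band
        if not lo < hi:
            raise ValueError("expression_ratio_band lower bound must be < upper")


@dataclass(frozen=True)
class DeltaFeatures:
    ie_t: float
    ie_c: float
    ij_t: float
    ij_c: float
    ic_t: float
    ic_c: float
    die: float
    dij: float
    dic: float

    @property
    def is_noise(self) -> bool:
        return not (self.die > 0 and self.dij > 0 and self.dic > 0)


@dataclass
class ScoringContext:
    """Candidate-set maxima and the weights of the score."""

    max_die: float
    max_dij: float
    max_dic: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS


@dataclass
class IRCallResult:
    calls: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)
    n_input: int = 0


def apply_removal_criteria(
    record: Mapping[str, float], criteria: RemovalCriteria = RemovalCriteria()
) -> tuple[bool, str | None]:
    """Keep/drop decision with the first failed criterion's name.

    All criteria are strict: a value exactly at a threshold is dropped.
    """
    checks = [
        ("min_tn5ss", record["TN5ss"] > criteria.min_tn5ss),
        ("min_tn3ss", record["TN3ss"] > criteria.min_tn3ss),
        ("min_tncoverage", record["TNcoverage"] > criteria.min_tncoverage),
        ("min_tnexon", record["TNexon"] > criteria.min_tnexon),
        ("min_tnexpression", record["TNexpression"] > criteria.min_tnexpression),
        ("min_tnintron", record["TNintron"] > criteria.min_tnintron),
        ("min_cnexpression", record["CNexpression"] > criteria.min_cnexpression),
        ("min_cnjunc", record["CNjunc"] > criteria.min_cnjunc),
        ("min_cnexon", record["CNexon"] > criteria.min_cnexon),
    ]
    for name, ok in checks:
        if not ok:
            return False, name
    if record["CNexpression"] == 0:
        return False, "expression-ratio undefined"
    log_ratio = math.log2(record["TNexpression"] / record["CNexpression"])
    lo, hi = criteria.expression_ratio_band
    if not (lo < log_ratio < hi):
        return False, "expression_ratio"
    return True, None


def compute_deltas(
    record: Mapping[str, float], pseudo: float = DEFAULT_PSEUDO
) -> DeltaFeatures:
    """IE/IJ/IC per condition and their log2 treatment-over-control deltas.

    A pseudo-count (default 1) is added to every count entering IE and IJ so
    that zero denominators cannot occur. Check ``.is_noise`` for candidates
    with any non-positive delta.
    """
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    ie_t = (record["TNintron"] + pseudo) / (record["TNexon"] + pseudo)
    ie_c = (record["CNintron"] + pseudo) / (record["CNexon"] + pseudo)
    ij_t = (record["TNintron"] + pseudo) / (record["TNjunc"] + pseudo)
    ij_c = (record["CNintron"] + pseudo) / (record["CNjunc"] + pseudo)
    ic_t = math.exp(record["TNcoverage"])
    ic_c = math.exp(record["CNcoverage"])
    return DeltaFeatures(
        ie_t=ie_t, ie_c=ie_c, ij_t=ij_t, ij_c=ij_c, ic_t=ic_t, ic_c=ic_c,
        die=math.log2(ie_t / ie_c),
        dij=math.log2(ij_t / ij_c),
        # log2(e^ct / e^cc) reduces to (ct - cc) * log2(e)
        dic=(record["TNcoverage"] - record["CNcoverage"]) * LOG2E,
    )


def validate_weights(weights: Sequence[float]) -> tuple[float, float, float]:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x < 0 for x in w):
        raise ValueError("weights must be three non-negative numbers")
    if not math.isclose(sum(w), 1.0, abs_tol=1e-9):
        raise ValueError(f"weights must sum to 1, got {sum(w)}")
    return w  # type: ignore[return-value]


def build_scoring_context(
    candidates: Sequence[DeltaFeatures],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> ScoringContext:
    """Componentwise maxima over surviving candidates, plus validated weights."""
    if not candidates:
        raise ValueError("no candidates survive filtering; nothing to score")
    w = validate_weights(weights)
    return ScoringContext(
        max_die=max(c.die for c in candidates),
        max_dij=max(c.dij for c in candidates),
        max_dic=max(c.dic for c in candidates),
        weights=w,
    )


def ir_score(
    ndie: float, ndij: float, ndic: float,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> float:
    w1, w2, w3 = validate_weights(weights)
    return w1 * ndie + w2 * ndij + w3 * ndic


def rank_and_select(scored: pd.DataFrame, n_percent: float) -> pd.DataFrame:
    """Sort by descending score and return the top ceil(n% * count) rows.

    Ties break on descending dic, then ascending intron_id, for determinism.
    """
    if not 0 < n_percent <= 100:
        raise ValueError("n_percent must be in (0, 100]")
    if scored.empty:
        return scored.assign(rank=pd.Series(dtype=int))[CALL_COLUMNS]
    ordered = scored.sort_values(
        by=["ir_score", "dic", "intron_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    k = math.ceil(n_percent / 100.0 * len(ordered))
    top = ordered.head(k).copy()
    top.insert(0, "rank", np.arange(1, len(top) + 1))
    return top[CALL_COLUMNS]


def run_ircall(
    feature_table: pd.DataFrame,
    criteria: RemovalCriteria = RemovalCriteria(),
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    pseudo: float = DEFAULT_PSEUDO,
    n_percent: float = 10.0,
) -> IRCallResult:
    """Filter, score and rank the feature table; audit every drop.

    The audit maps each removal reason (and ``"noise"``) to the number of
    introns dropped for it, plus ``"kept"``; the counts partition the input.
    """
    if feature_table.empty:
        raise ValueError("feature table is empty")
    w = validate_weights(weights)
    audit: dict[str, int] = {}
    survivors: list[tuple[pd.Series, DeltaFeatures]] = []
    for _, row in feature_table.iterrows():
        keep, reason = apply_removal_criteria(row, criteria)
        if not keep:
            audit[reason] = audit.get(reason, 0) + 1
            continue
        deltas = compute_deltas(row, pseudo)
        if deltas.is_noise:
            audit["noise"] = audit.get("noise", 0) + 1
            continue
        survivors.append((row, deltas))
    audit["kept"] = len(survivors)

    if not survivors:
        empty = pd.DataFrame(columns=CALL_COLUMNS)
        return IRCallResult(calls=empty, audit=audit, n_input=len(feature_table))

    ctx = build_scoring_context([d for _, d in survivors], w)
    rows = []
    for row, d in survivors:
        ndie = d.die / ctx.max_die
        ndij = d.dij / ctx.max_dij
        ndic = d.dic / ctx.max_dic
        rows.append(
            {
                "intron_id": row["intron_id"],
                "chrom": row["chrom"],
                "start": row["start"],
                "end": row["end"],
                "strand": row["strand"],
                "ir_score": ir_score(ndie, ndij, ndic, w),
                "ndie": ndie, "ndij": ndij, "ndic": ndic,
                "die": d.die, "dij": d.dij, "dic": d.dic,
            }
        )
    calls = rank_and_select(pd.DataFrame(rows), n_percent)
    return IRCallResult(calls=calls, audit=audit, n_input=len(feature_table))
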