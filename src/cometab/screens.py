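"""Formate-focused host screens: diet supplementation, single-reaction
knockouts, minimal knockout-set search, and the disease-annotation join.

All screens operate on a germ-free host under a fixed diet and score a
target urine exchange (formate by default). The knockout flag threshold is
0.10 — a deletion counts when it cuts the target flux by more than 10% — and
candidate supplements are added at up to 300 mmol/d, both following the
conventions recorded in :mod:`cometab.config`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import DEFAULT_CONFIG
from .core import StoichiometricModel
from .diet import apply_diet, supplement_diet
from .errors import ValidationError
from .host import HostModel, max_urine_secretion
from .io import DietSpec
from .lp import delete_reactions, solve_fba

logger = logging.getLogger(__name__)


@dataclass
class KnockoutReport:
    """Single-deletion screen outcome for one target metabolite."""

    target: str
    baseline: float
    results: Dict[str, Tuple[float, float]]  # rid -> (ko_flux, reduction_fraction)
    flag_threshold: float
    flagged: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.flagged = sorted(
            rid for rid, (_, red) in self.results.items() if red > self.flag_threshold
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": rid, "ko_flux": ko, "reduction_fraction": red,
             "flagged": red > self.flag_threshold}
            for rid, (ko, red) in sorted(self.results.items())
        ]
        return pd.DataFrame(rows).set_index("reaction")


@dataclass
class ReactionAnnotation:
    """Static disease-annotation row for one candidate reaction."""

    reaction: str
    genes: str = ""
    ad_association: str = "none"  # positive | negative | none
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.ad_association not in ("positive", "negative", "none"):
            raise ValidationError(
                f"ad_association must be positive/negative/none, got {self.ad_association!r}"
            )


# ---------------------------------------------------------------------------
# supplementation
# ---------------------------------------------------------------------------

def supplementation_screen(
    host: HostModel,
    diet: DietSpec,
    candidates: Sequence[str],
    amount: float = DEFAULT_CONFIG.supplement_amount,
    target: str = "for",
    diet_scale: float = 1.0,
) -> pd.DataFrame:
    """Add each candidate metabolite to the diet individually and re-solve
    the maximal urine secretion of the target.

    Returns a DataFrame (candidate, baseline, supplemented, increases,
    status); infeasible supplemented runs are recorded as failed rather than
    raised.
    """
    if amount <= 0:
        raise ValidationError("supplement amount must be positive")
    base_model = apply_diet(host.base, diet, scale=diet_scale)
    baseline = max_urine_secretion(base_model, target)
    rows = []
    for cand in candidates:
        sup = supplement_diet(diet, cand, amount)
        model = apply_diet(host.base, sup, scale=diet_scale)
        try:
            supplemented = max_urine_secretion(model, target)
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            logger.warning("supplemented run for %r failed: %s", cand, exc)
            supplemented, status = float("nan"), "failed"
        rows.append({
            "candidate": cand,
            "baseline": baseline,
            "supplemented": supplemented,
            "increases": bool(status == "ok" and supplemented > baseline + 1e-6),
            "status": status,
        })
    return pd.DataFrame(rows).set_index("candidate")


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------

def _target_after_deletion(
    model: StoichiometricModel, reactions: Sequence[str], target: str
) -> float:
    ko = delete_reactions(model, reactions) if reactions else model
    return max_urine_secretion(ko, target)


def knockout_screen(
    host: HostModel,
    diet: DietSpec,
    candidates: Sequence[str],
    target: str = "for",
    flag_threshold: float = DEFAULT_CONFIG.ko_flag_threshold,
    diet_scale: float = 1.0,
) -> KnockoutReport:
    """Delete each candidate reaction singly and measure the fractional
    reduction of the maximal urine target flux."""
    model = apply_diet(host.base, diet, scale=diet_scale)
    unknown = [r for r in candidates if r not in model.reactions]
    if unknown:
        raise ValidationError(f"knockout candidates not in host: {sorted(unknown)}")
    baseline = max_urine_secretion(model, target)
    if baseline <= 0:
        raise ValidationError(
            f"baseline urine {target} flux is zero; a knockout screen is meaningless"
        )
    results: Dict[str, Tuple[float, float]] = {}
    for rid in candidates:
        ko_flux = _target_after_deletion(model, [rid], target)
        reduction = (baseline - ko_flux) / baseline
        results[rid] = (ko_flux, max(0.0, reduction))
    return KnockoutReport(target=target, baseline=baseline, results=results,
                          flag_threshold=flag_threshold)


def minimal_set_search(
    host: HostModel,
    diet: DietSpec,
    candidates: Sequence[str],
    target: str = "for",
    goal_reduction: float = 0.85,
    exhaustive_max: int = DEFAULT_CONFIG.exhaustive_max_candidates,
    diet_scale: float = 1.0,
) -> Tuple[List[str], float, bool]:
    """Find a small reaction set whose joint deletion reduces the target flux
    by at least ``goal_reduction``.

    Greedy forward selection (largest marginal reduction first) followed by a
    backward pass that drops members not needed to stay above the goal, so
    the result is minimal with respect to the greedy set. Returns
    ``(reaction_ids, achieved_reduction, goal_reached)``.
    """
    model = apply_diet(host.base, diet, scale=diet_scale)
    unknown = [r for r in candidates if r not in model.reactions]
    if unknown:
        raise ValidationError(f"candidates not in host: {sorted(unknown)}")
    baseline = max_urine_secretion(model, target)
    if baseline <= 0:
        raise ValidationError("baseline target flux is zero")

    def reduction(subset: Sequence[str]) -> float:
        flux = _target_after_deletion(model, list(subset), target)
        return (baseline - flux) / baseline

    if goal_reduction <= 0:
        return [], 0.0, True

    chosen: List[str] = []
    achieved = 0.0
    remaining = list(candidates)
    while achieved < goal_reduction and remaining:
        best, best_red = None, achieved
        for rid in remaining:
            red = reduction(chosen + [rid])
            if red > best_red + 1e-6:
                best, best_red = rid, red
        if best is None:
            break
        chosen.append(best)
        remaining.remove(best)
        achieved = best_red

    reached = achieved >= goal_reduction
    if reached:
        # backward pass: minimality w.r.t. the greedy set
        for rid in list(chosen):
            trial = [r for r in chosen if r != rid]
            if trial and reduction(trial) >= goal_reduction:
                chosen = trial
        achieved = reduction(chosen)
    if not reached:
        logger.warning(
            "goal reduction %.3g unreachable; best set of %d reaches %.3g",
            goal_reduction, len(chosen), achieved,
        )
    return chosen, achieved, reached


def exhaustive_min_set(
    host: HostModel,
    diet: DietSpec,
    candidates: Sequence[str],
    target: str = "for",
    goal_reduction: float = 0.85,
    diet_scale: float = 1.0,
) -> Tuple[List[str], float]:
    """Smallest subset reaching the goal by full enumeration (oracle for
    small candidate lists; exponential in ``len(candidates)``)."""
    model = apply_diet(host.base, diet, scale=diet_scale)
    baseline = max_urine_secretion(model, target)
    if baseline <= 0:
        raise ValidationError("baseline target flux is zero")
    for size in range(0, len(candidates) + 1):
        best: Optional[Tuple[List[str], float]] = None
        for subset in itertools.combinations(candidates, size):
            flux = _target_after_deletion(model, list(subset), target)
            red = (baseline - flux) / baseline
            if red >= goal_reduction and (best is None or red > best[1]):
                best = (list(subset), red)
        if best is not None:
            return best
    # unreachable: return the full set's reduction
    full_red = (baseline - _target_after_deletion(model, list(candidates), target)) / baseline
    return list(candidates), full_red


# ---------------------------------------------------------------------------
# annotation join
# ---------------------------------------------------------------------------

def read_annotations(path) -> List[ReactionAnnotation]:
    """Parse a static annotation TSV (reaction, genes, ad_association, evidence)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ReactionAnnotation(
            reaction=row["reaction"],
            genes=row.get("genes", ""),
            ad_association=row.get("ad_association", "none") or "none",
            evidence=row.get("evidence", ""),
        )
        for _, row in df.iterrows()
    ]


def annotate_with_ad(
    report: KnockoutReport, annotations: Iterable[ReactionAnnotation]
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Join the knockout report with disease annotations on reaction id.

    Returns the joined table plus summary counts: candidates, flagged,
    annotated (non-none association), and the flagged∩annotated overlap.
    Duplicate annotation rows for one reaction are ambiguous and raise.
    """
    ann_map: Dict[str, ReactionAnnotation] = {}
    for ann in annotations:
        if ann.reaction in ann_map:
            raise ValidationError(
                f"duplicate annotation rows for reaction {ann.reaction!r}"
            )
        ann_map[ann.reaction] = ann
    df = report.to_frame()
    df["ad_association"] = [
        ann_map[r].ad_association if r in ann_map else "none" for r in df.index
    ]
    df["genes"] = [ann_map[r].genes if r in ann_map else "" for r in df.index]
    annotated = df["ad_association"] != "none"
    summary = {
        "n_candidates": int(len(df)),
        "n_flagged": int(df["flagged"].sum()),
        "n_annotated": int(annotated.sum()),
        "n_flagged_and_annotated": int((df["flagged"] & annotated).sum()),
    }
    return df, summary
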