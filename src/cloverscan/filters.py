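"""Post-scan filtering: pseudogene labelling and the three-stage
high-confidence classification for large eukaryotic genomes.

Stage 1 removes possible pseudogenes: overall score below 55 bits *and*
primary sequence score below 10 bits or secondary structure score below
5 bits.  Stage 2 removes predictions with isotype-specific model score
below 70 bits, overall score below 50 bits, or secondary structure score
below 10 bits.  Stage 3 applies a dynamic per-anticodon threshold when an
anticodon retains more than 40 predictions: starting at 71 bits and
rising one bit at a time (to at most 95), lower-scoring hits are dropped
until no more than 40 remain.  Survivors enter the high-confidence set
only with a consistent isotype prediction and an expected anticodon.

All comparisons are strict (`score < threshold` removes), so boundary
values are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .classifier import DecodingTable, anticodon_to_isotype
from .config import FilterConfig
from .records import TRNAPrediction


def classify_pseudogene(pred: TRNAPrediction, cfg: FilterConfig = None) -> bool:
    cfg = cfg or FilterConfig()
    return (pred.overall_bits < cfg.pseudo_overall
            and (pred.primary_bits < cfg.pseudo_primary
                 or pred.secondary_bits < cfg.pseudo_secondary))


def secondary_filter(preds: list, cfg: FilterConfig = None) -> tuple:
    """Partition into (passed, removed) by the stage-2 rules."""
    cfg = cfg or FilterConfig()
    passed, removed = [], []
    for p in preds:
        if p.isotype_scores:
            iso = max(p.isotype_scores.values())
        else:
            warnings.warn("prediction without isotype score treated as -inf")
            iso = float("-inf")
        if (iso < cfg.stage2_isotype or p.overall_bits < cfg.stage2_overall
                or p.secondary_bits < cfg.stage2_secondary):
            removed.append(p)
        else:
            passed.append(p)
    return passed, removed


def tertiary_filter(preds: list, cfg: FilterConfig = None) -> tuple:
    """Dynamic per-anticodon threshold; (passed, removed)."""
    cfg = cfg or FilterConfig()
    groups = {}
    for p in preds:
        groups.setdefault(p.anticodon, []).append(p)
    passed, removed = [], []
    for anticodon in sorted(groups):
        group = groups[anticodon]
        if len(group) <= cfg.stage3_max_per_anticodon:
            passed.extend(group)
            continue
        t = cfg.stage3_start
        kept = [p for p in group if p.overall_bits >= t]
        while (len(kept) > cfg.stage3_max_per_anticodon
               and t < cfg.stage3_cap):
            t += 1
            kept = [p for p in kept if p.overall_bits >= t]
        keep_set = set(map(id, kept))
        passed.extend(kept)
        removed.extend(p for p in group if id(p) not in keep_set)
    return passed, removed


def annotate_consistency(pred: TRNAPrediction,
                         table: DecodingTable) -> TRNAPrediction:
    """Flag unexpected anticodons; IPD is set by the classifier."""
    if pred.anticodon in table.disallowed:
        pred.flags.add("unexpected_anticodon")
    else:
        pred.flags.discard("unexpected_anticodon")
    return pred


@dataclass
class FilterReport:
    """Per-stage removal counts and the resulting high-confidence set."""

    input_count: int = 0
    removed_pseudo: int = 0
    removed_stage2: int = 0
    removed_stage3: int = 0
    flagged: int = 0
    high_confidence: list = field(default_factory=list)
    labels: dict = field(default_factory=dict)   # id(pred) -> stage label

    def summary(self) -> str:
        lines = [
            "category\tcount",
            f"input predictions\t{self.input_count}",
            f"removed: possible pseudogenes\t{self.removed_pseudo}",
            f"removed: secondary filter\t{self.removed_stage2}",
            f"removed: tertiary filter\t{self.removed_stage3}",
            f"flagged (inconsistent/unexpected)\t{self.flagged}",
            f"high confidence set\t{len(self.high_confidence)}",
        ]
        return "\n".join(lines) + "\n"


def high_confidence_filter(preds: list, cfg: FilterConfig = None,
                           table: DecodingTable = None,
                           domain: str = "eukaryote") -> FilterReport:
    """Pseudogene -> secondary -> tertiary -> consistency, in that order."""
    cfg = cfg or FilterConfig()
    table = table or DecodingTable.load("eukaryote")
    if domain != "eukaryote":
        warnings.warn("high-confidence filtering is designed for eukaryotic "
                      "predictions; not needed (and not recommended) for "
                      f"{domain}")
    report = FilterReport(input_count=len(preds))

    survivors = []
    for p in preds:
        if classify_pseudogene(p, cfg):
            p.flags.add("pseudo")
            report.labels[id(p)] = "pseudo"
            report.removed_pseudo += 1
        else:
            survivors.append(p)

    survivors, removed2 = secondary_filter(survivors, cfg)
    report.removed_stage2 = len(removed2)
    for p in removed2:
        report.labels[id(p)] = "secondary"

    survivors, removed3 = tertiary_filter(survivors, cfg)
    report.removed_stage3 = len(removed3)
    for p in removed3:
        report.labels[id(p)] = "tertiary"

    for p in survivors:
        annotate_consistency(p, table)
        if "IPD" in p.flags or "unexpected_anticodon" in p.flags:
            report.flagged += 1
            report.labels[id(p)] = "flagged"
        else:
            report.labels[id(p)] = "high_confidence"
            report.high_confidence.append(p)
    return report
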