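"""Isotype classification: anticodon decoding and comparative model scoring.

A predicted tRNA's isotype is determined two ways and cross-checked: from
its anticodon via the domain decoding table (reverse-complement codon,
standard or vertebrate-mitochondrial genetic code), and from the highest
scoring isotype-specific model.  Disagreement raises the IPD (isotype
prediction disagreement) flag.  CAU-anticodon genes are three-way
ambiguous (initiator methionine, elongator methionine, or the modified
AUA-decoding isoleucine) and are resolved by comparative scoring of the
three subtype models; UCA maps to selenocysteine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .dp import score_sequence
from .records import TRNAPrediction

CAU_SUBTYPES = ("Ile2", "Met", "fMet", "iMet")


@dataclass
class DecodingTable:
    domain: str
    map: dict                 # anticodon -> isotype
    specials: dict            # overrides (CAT ambiguity set, TCA -> SeC)
    disallowed: frozenset     # anticodons not used in this domain

    @classmethod
    def load(cls, name: str) -> "DecodingTable":
        """Load a packaged table: eukaryote | bacteria | archaea | mito_vert."""
        path = resources.files("cloverscan.data") / f"decoding_{name}.json"
        data = json.loads(path.read_text())
        return cls(domain=data["domain"], map=data["map"],
                   specials=data["specials"],
                   disallowed=frozenset(data["disallowed"]))


def anticodon_to_isotype(anticodon: str, table: DecodingTable):
    """Isotype for an anticodon; a list for the CAU three-way ambiguity."""
    if anticodon == "NNN" or "N" in anticodon:
        return "Undet"
    if anticodon in table.specials:
        return table.specials[anticodon]
    return table.map[anticodon]


def score_isotypes(residues: str, registry: dict) -> dict:
    """Global structural score of a mature tRNA against every registry model."""
    if not registry:
        raise ValueError("empty isotype model registry")
    return {
        name: score_sequence(model, residues, mode="global").score
        for name, model in sorted(registry.items())
    }


def _argmax_scores(scores: dict):
    best = max(scores.values())
    winners = sorted(k for k, v in scores.items() if v == best)
    return winners[0], len(winners) > 1


def classify(pred: TRNAPrediction, table: DecodingTable,
             registry: dict, residues: str = None) -> TRNAPrediction:
    """Fill in both isotype predictions and flag disagreements.

    ``residues`` is the mature tRNA sequence (introns removed); when given
    and isotype scores are not yet present they are computed here.
    """
    if not pred.isotype_scores and residues is not None and registry:
        pred.isotype_scores = score_isotypes(residues, registry)
    by_ac = anticodon_to_isotype(pred.anticodon, table)
    if isinstance(by_ac, list):
        # CAU subtype decision: top scorer among the three subtype models
        subtype_scores = {
            name: s for name, s in pred.isotype_scores.items()
            if registry.get(name) is not None
            and registry[name].isotype in CAU_SUBTYPES
        }
        if subtype_scores:
            name, _ = _argmax_scores(subtype_scores)
            by_ac = registry[name].isotype
        else:
            by_ac = "Met"
    pred.isotype_by_anticodon = by_ac
    if pred.isotype_scores:
        name, tied = _argmax_scores(pred.isotype_scores)
        pred.isotype_by_model = (
            registry[name].isotype if name in registry else name
        )
        if tied:
            pred.flags.add("IPD")
        if pred.isotype_by_model != pred.isotype_by_anticodon:
            pred.flags.add("IPD")
        elif not tied:
            pred.flags.discard("IPD")
    return pred
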