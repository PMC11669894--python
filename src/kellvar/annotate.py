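"""Rule-based phenotype annotation of Kell missense variants.

The guideline distilled from the structural analysis scores seven
conditions per variant:

1. known site — the position is a known antigenic (AgWT/AgV) or
   destabilizing (NullV/ModV) position,
2. sequence conservation among the 39 Kell orthologs,
3. structural conservation in at least one of the three structurally
   characterized M13 relatives,
4. a relevant physicochemical change (proline involvement, side-chain
   volume change, surface charge change, buried hydrophobic-to-hydrophilic
   or exposed hydrophilic-to-hydrophobic transition),
5. the substitution involves an immunogenicity hotspot residue
   (Arg, Gln, Trp or Pro),
6. structural location — (a) not inside the tolerant central cavity or
   membrane-proximal, (b) within a predicted conformational epitope,
7. an MPC deleteriousness score above 0.4.

Conditions lacking their required inputs evaluate to ``unknown`` (None),
never to False, so partial annotation cannot bias a variant toward
neutral. The default combination strategy encodes the structural
narrative: buried-or-half-buried + conserved + property change predicts a
destabilizing (K0/Kmod-like) variant; accessible position + hotspot or
surface charge change or epitope membership predicts an antigenic
candidate. Conditions 1 and 7 contribute supporting evidence to the score
but never decide a verdict alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog import Catalog, SubKey, format_substitution, parse_protein_substitution
from .conservation import ConservationProfile
from .errors import ParseError
from .properties import PropertyScale, SubstitutionProfile, build_substitution_profile
from .structure import ResidueContext

logger = logging.getLogger(__name__)

CONDITION_KEYS = (
    "c1_known_site",
    "c2_seq_conserved",
    "c3_struct_conserved",
    "c4_property_change",
    "c5_hotspot_residue",
    "c6a_not_cavity_or_proximal",
    "c6b_in_epitope",
    "c7_mpc_above",
)

PREDICTIONS = ("destabilizing", "antigenic", "neutral", "indeterminate")

#: catalog labels that make a position a "known site"
KNOWN_SITE_LABELS = ("AgWT", "AgV", "NullV", "ModV")


@dataclass
class RuleConfig:
    """Tunable parameters of the annotation guideline."""

    conservation_cutoff: float = 90.0  # percent ortholog identity
    mpc_cutoff: float = 0.4
    epitope_segments: list[tuple[int, int]] = field(default_factory=list)
    cavity_positions: set[int] = field(default_factory=set)
    weights: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "RuleConfig":
        rules = cfg.get("rules", {})
        segments = [tuple(s) for s in cfg.get("epitopes", {}).get("segments", [])]
        return cls(
            conservation_cutoff=float(rules.get("conservation_cutoff", 90.0)),
            mpc_cutoff=float(rules.get("mpc_cutoff", 0.4)),
            epitope_segments=segments,
            cavity_positions=set(rules.get("cavity_positions", []) or []),
            weights=dict(rules.get("weights", {}) or {}),
        )

    def weight(self, key: str) -> float:
        return float(self.weights.get(key, 1.0))


@dataclass
class AnnotationVerdict:
    """Evidence trace and predicted phenotype class for one variant."""

    variant_key: SubKey
    conditions: dict[str, Optional[bool]]
    prediction: str
    evidence_score: float
    trace: list[str]

    @property
    def substitution(self) -> str:
        return format_substitution(self.variant_key)


def evaluate_conditions(
    key: SubKey,
    context: Optional[ResidueContext],
    conservation: Optional[ConservationProfile],
    profile: Optional[SubstitutionProfile],
    catalog: Optional[Catalog],
    config: RuleConfig,
    mpc: Optional[float] = None,
) -> dict[str, Optional[bool]]:
    """Tri-state evaluation of the seven guideline conditions.

    Missing inputs yield ``None`` (unknown) for the affected condition.
    """
    position = key[0]
    conditions: dict[str, Optional[bool]] = {}

    if catalog is None:
        conditions["c1_known_site"] = None
    else:
        conditions["c1_known_site"] = position in catalog.positions_with_label(
            *KNOWN_SITE_LABELS
        )

    if conservation is None:
        conditions["c2_seq_conserved"] = None
    else:
        conditions["c2_seq_conserved"] = (
            conservation.ortholog_pct >= config.conservation_cutoff
        )

    if conservation is None or conservation.structural_count is None:
        conditions["c3_struct_conserved"] = None
    else:
        conditions["c3_struct_conserved"] = conservation.structural_count >= 1

    if profile is None:
        conditions["c4_property_change"] = None
        conditions["c5_hotspot_residue"] = None
    else:
        conditions["c4_property_change"] = profile.any_property_change
        conditions["c5_hotspot_residue"] = profile.hotspot_residue

    # 6a: inside the tolerant cavity or near the membrane disqualifies an
    # antigenic location. Cavity membership decides on its own; certifying
    # the condition additionally needs a known membrane distance.
    if position in config.cavity_positions:
        conditions["c6a_not_cavity_or_proximal"] = False
    elif context is not None and context.membrane_proximal is not None:
        conditions["c6a_not_cavity_or_proximal"] = not context.membrane_proximal
    else:
        conditions["c6a_not_cavity_or_proximal"] = None

    if not config.epitope_segments:
        conditions["c6b_in_epitope"] = None
    else:
        conditions["c6b_in_epitope"] = any(
            start <= position <= end for start, end in config.epitope_segments
        )

    if mpc is None:
        conditions["c7_mpc_above"] = None
    else:
        conditions["c7_mpc_above"] = mpc > config.mpc_cutoff

    return conditions


def predict_phenotype(
    conditions: Mapping[str, Optional[bool]],
    context: Optional[ResidueContext],
    profile: Optional[SubstitutionProfile],
    config: RuleConfig,
    key: Optional[SubKey] = None,
) -> AnnotationVerdict:
    """Combine the evaluated conditions into a phenotype prediction.

    Default strategy: a buried or half-buried position that is conserved
    (sequentially or structurally) and undergoes a relevant property change
    is called destabilizing; an accessible position not excluded by its
    location, with a hotspot residue, surface charge change or epitope
    membership, is called antigenic; if neither rule fires and both the
    property-change and hotspot conditions are affirmatively false the
    variant is neutral; anything else is indeterminate. Unknown conditions
    never count as satisfied.
    """
    key = key or (profile.position if profile else 0, "A", "G")
    trace: list[str] = []
    burial = context.burial if context is not None else None

    c2 = conditions.get("c2_seq_conserved")
    c3 = conditions.get("c3_struct_conserved")
    c4 = conditions.get("c4_property_change")
    c5 = conditions.get("c5_hotspot_residue")
    c6a = conditions.get("c6a_not_cavity_or_proximal")
    c6b = conditions.get("c6b_in_epitope")

    destabilizing = (
        burial in ("buried", "half_buried")
        and (c2 is True or c3 is True)
        and c4 is True
    )
    if destabilizing:
        trace.append(
            f"destabilizing rule fired: burial={burial}, conserved="
            f"{'sequence' if c2 else 'structure'}, property change present"
        )

    surface_charge = profile.surface_charge_change if profile is not None else False
    antigenic = (
        burial in ("half_buried", "exposed")
        and c6a is not False
        and (c5 is True or surface_charge or c6b is True)
    )
    if antigenic and not destabilizing:
        reasons = []
        if c5 is True:
            reasons.append("hotspot residue")
        if surface_charge:
            reasons.append("surface charge change")
        if c6b is True:
            reasons.append("within predicted epitope")
        trace.append(
            f"antigenic rule fired: burial={burial}, location not excluded, "
            + ", ".join(reasons)
        )

    if destabilizing:
        prediction = "destabilizing"
    elif antigenic:
        prediction = "antigenic"
    elif c4 is False and c5 is False:
        prediction = "neutral"
        trace.append("no rule fired; property-change and hotspot conditions false")
    else:
        prediction = "indeterminate"
        unknowns = [k for k, v in conditions.items() if v is None]
        trace.append(
            "no rule fired; insufficient evidence"
            + (f" (unknown: {', '.join(unknowns)})" if unknowns else "")
        )

    score = sum(config.weight(k) for k, v in conditions.items() if v is True)
    return AnnotationVerdict(
        variant_key=key,
        conditions=dict(conditions),
        prediction=prediction,
        evidence_score=float(score),
        trace=trace,
    )


@dataclass
class AnnotationResources:
    """Everything the rule engine can draw on for a structure-wide screen."""

    catalog: Optional[Catalog] = None
    contexts: Mapping[int, ResidueContext] = field(default_factory=dict)
    conservation: Mapping[int, ConservationProfile] = field(default_factory=dict)
    scales: Optional[Mapping[str, PropertyScale]] = None
    volume_dz_threshold: float = 0.5


def annotate_variant(
    key: SubKey,
    resources: AnnotationResources,
    config: RuleConfig,
    mpc: Optional[float] = None,
) -> AnnotationVerdict:
    """Evaluate and combine the guideline for one substitution key."""
    position, wt, var = key
    context = resources.contexts.get(position)
    conservation = resources.conservation.get(position)
    profile = None
    if context is not None:
        profile = build_substitution_profile(
            position, wt, var, context,
            scales=resources.scales,
            volume_dz_threshold=resources.volume_dz_threshold,
        )
    conditions = evaluate_conditions(
        key, context, conservation, profile, resources.catalog, config, mpc
    )
    return predict_phenotype(conditions, context, profile, config, key=key)


@dataclass
class ScreenReport:
    """Cohort screening result: verdicts on novel variants, known ones routed."""

    verdicts: list[AnnotationVerdict]
    known: list[SubKey]
    unresolved: list[tuple[str, str]]  # (input text, reason)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in PREDICTIONS}
        for v in self.verdicts:
            counts[v.prediction] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            row = {
                "substitution": v.substitution,
                "position": v.variant_key[0],
                "prediction": v.prediction,
                "evidence_score": v.evidence_score,
            }
            for ckey, cval in v.conditions.items():
                row[ckey] = "unknown" if cval is None else str(cval).lower()
            row["trace"] = " | ".join(v.trace)
            rows.append(row)
        return pd.DataFrame(rows)


def screen_cohort(
    variants: Iterable[str | SubKey | tuple[SubKey, Optional[float]]],
    resources: AnnotationResources,
    config: RuleConfig,
) -> ScreenReport:
    """Annotate a list of (possibly novel) missense variants.

    Accepts substitution strings ("Thr193Met"), keys, or (key, mpc) pairs.
    Variants already present in the catalog are routed to the known-allele
    list instead of being re-screened; the rest are annotated and ranked by
    evidence score (descending), ties broken by position.
    """
    verdicts: list[AnnotationVerdict] = []
    known: list[SubKey] = []
    unresolved: list[tuple[str, str]] = []
    seen: set[SubKey] = set()
    for item in variants:
        mpc: Optional[float] = None
        try:
            if isinstance(item, str):
                keys = parse_protein_substitution(item)
            elif (
                isinstance(item, tuple)
                and len(item) == 2
                and isinstance(item[0], tuple)
            ):
                keys = [item[0]]
                mpc = item[1]
            else:
                keys = [tuple(item)]  # type: ignore[list-item]
        except ParseError as exc:
            unresolved.append((str(item), str(exc)))
            continue
        for key in keys:
            if key in seen:
                continue
            seen.add(key)
            if resources.catalog is not None and resources.catalog.get(key) is not None:
                known.append(key)
                continue
            verdicts.append(annotate_variant(key, resources, config, mpc=mpc))
    verdicts.sort(key=lambda v: (-v.evidence_score, v.variant_key[0]))
    known.sort()
    return ScreenReport(verdicts=verdicts, known=known, unresolved=unresolved)
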