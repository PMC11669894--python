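"""Kell missense-variant catalog: parsing, merging and summary counts.

The catalog collects every known full-length Kell protein variant together
with its phenotype class labels:

* ``NullV`` — missense variants abolishing Kell surface expression (K0),
* ``ModV`` — variants drastically reducing expression (Kmod),
* ``AgWT`` / ``AgV`` — variants at antigenic positions where the wild-type
  (reference allele KEL*02) or the variant residue carries an antigen,
* ``MinusAllele`` — substitutions that abolish a wild-type antigen without
  creating a new specificity,
* ``CtrlV`` — frequent population variants with no recorded phenotype, used
  as non-antigenic controls,
* ``Uncharacterized`` — anything else.

A variant is identified by its substitution key ``(position, wt, var)``;
ISBT allele names are attributes of a variant, not identities, because one
substitution may define several alleles (e.g. Pro560Ala under KEL*01N.01 and
KEL*02N.18) and one allele may carry two substitutions in cis.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .aminoacids import ONE_TO_THREE, to_one_letter
from .config import data_path
from .errors import ConsistencyError, ParseError

logger = logging.getLogger(__name__)

LABELS = ("NullV", "ModV", "AgWT", "AgV", "MinusAllele", "CtrlV", "Uncharacterized")

#: default control-group inclusion cutoff: European minor allele frequency
DEFAULT_MAF_CUTOFF = 3.0e-05

#: full-length Kell protein (UniProt P23276)
PROTEIN_LENGTH = 732

_SUB_TOKEN = re.compile(r"([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})")

SubKey = tuple[int, str, str]


def parse_protein_substitution(
    text: str, protein_length: int = PROTEIN_LENGTH
) -> list[SubKey]:
    """Parse one or more concatenated three-letter substitutions.

    ``"Thr193Met"`` yields ``[(193, "T", "M")]``; alleles carrying two
    mutations in cis are printed concatenated, e.g. ``"Leu260PheArg675Gln"``
    yields both substitutions in order of appearance.

    Raises :class:`ParseError` for malformed tokens, non-standard residues,
    out-of-range positions, or silent (wt == var) exchanges.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty substitution string")
    out: list[SubKey] = []
    pos = 0
    while pos < len(text):
        m = _SUB_TOKEN.match(text, pos)
        if m is None:
            raise ParseError(f"malformed substitution token at {text[pos:]!r} in {text!r}")
        wt3, num, var3 = m.groups()
        try:
            wt = to_one_letter(wt3)
            var = to_one_letter(var3)
        except KeyError as exc:
            raise ParseError(f"unknown residue name in token {m.group(0)!r}: {exc}") from None
        position = int(num)
        if not 1 <= position <= protein_length:
            raise ParseError(
                f"position {position} outside 1-{protein_length} in token {m.group(0)!r}"
            )
        if wt == var:
            raise ParseError(f"silent exchange {m.group(0)!r}: wild type equals variant")
        out.append((position, wt, var))
        pos = m.end()
    return out


def format_substitution(key: SubKey) -> str:
    """Render a substitution key back to three-letter notation."""
    position, wt, var = key
    return f"{ONE_TO_THREE[wt]}{position}{ONE_TO_THREE[var]}"


@dataclass
class Variant:
    """One amino-acid substitution in the Kell protein."""

    position: int
    wt_aa: str  # one-letter
    var_aa: str  # one-letter
    allele_names: set[str] = field(default_factory=set)
    maf_eur: Optional[float] = None
    labels: set[str] = field(default_factory=set)
    single_exchange_causal: bool = False
    cis_partner: Optional[SubKey] = None
    agwt_antigens: set[str] = field(default_factory=set)
    agv_antigens: set[str] = field(default_factory=set)
    minus_alleles: set[str] = field(default_factory=set)
    combination_with: set[str] = field(default_factory=set)

    @property
    def key(self) -> SubKey:
        return (self.position, self.wt_aa, self.var_aa)

    @property
    def substitution(self) -> str:
        return format_substitution(self.key)

    def __post_init__(self) -> None:
        self.wt_aa = to_one_letter(self.wt_aa)
        self.var_aa = to_one_letter(self.var_aa)
        if self.wt_aa == self.var_aa:
            raise ValueError(f"silent exchange at position {self.position}")
        if self.maf_eur is not None and not 0.0 < self.maf_eur < 1.0:
            raise ValueError(f"maf_eur {self.maf_eur} outside (0, 1)")


@dataclass
class Catalog:
    """Deduplicated collection of variants keyed by substitution."""

    variants: dict[SubKey, Variant] = field(default_factory=dict)
    maf_cutoff: float = DEFAULT_MAF_CUTOFF
    provenance: dict[SubKey, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(sorted(self.variants.values(), key=lambda v: v.key))

    def get(self, key: SubKey) -> Optional[Variant]:
        return self.variants.get(key)

    def positions_with_label(self, *labels: str) -> set[int]:
        return {v.position for v in self.variants.values() if v.labels & set(labels)}

    def with_label(self, label: str) -> list[Variant]:
        return [v for v in self if label in v.labels]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self:
            rows.append(
                {
                    "substitution": v.substitution,
                    "position": v.position,
                    "wt_aa": v.wt_aa,
                    "var_aa": v.var_aa,
                    "alleles": ";".join(sorted(v.allele_names)),
                    "maf_eur": v.maf_eur,
                    "labels": ";".join(sorted(v.labels)),
                    "single_exchange_causal": v.single_exchange_causal,
                    "cis_partner": format_substitution(v.cis_partner) if v.cis_partner else "",
                    "agwt_antigens": ";".join(sorted(v.agwt_antigens)),
                    "agv_antigens": ";".join(sorted(v.agv_antigens)),
                    "sources": ";".join(sorted(self.provenance.get(v.key, set()))),
                }
            )
        return pd.DataFrame(rows)


_LABEL_BY_SOURCE = {"T1_null": "NullV", "T1_mod": "ModV", "T3": "CtrlV"}


def _merge_row(
    catalog: Catalog,
    key: SubKey,
    source: str,
    allele: str,
    maf: Optional[float],
    combination_with: str,
    labels: set[str],
    agwt: str,
    agv: str,
    minus: bool,
    causal: bool,
    cis_partner: Optional[SubKey],
) -> None:
    position, wt, var = key
    existing_wt = {k[1] for k in catalog.variants if k[0] == position}
    if existing_wt and wt not in existing_wt:
        raise ConsistencyError(
            f"conflicting wild-type residues at position {position}: "
            f"{sorted(existing_wt)} vs {wt}"
        )
    v = catalog.variants.get(key)
    if v is None:
        v = Variant(position=position, wt_aa=wt, var_aa=var)
        catalog.variants[key] = v
        catalog.provenance[key] = set()
    catalog.provenance[key].add(source)
    if allele:
        v.allele_names.add(allele)
    if maf is not None:
        if v.maf_eur is not None and abs(v.maf_eur - maf) > 1e-12:
            logger.warning(
                "conflicting MAF for %s: keeping %g, ignoring %g",
                format_substitution(key), v.maf_eur, maf,
            )
        elif v.maf_eur is None:
            v.maf_eur = maf
    if combination_with:
        v.combination_with.add(combination_with)
    v.labels |= labels
    if agwt:
        v.agwt_antigens.add(agwt)
        v.labels.add("AgWT")
    if agv:
        v.agv_antigens.add(agv)
        v.labels.add("AgV")
    if minus:
        v.labels.add("MinusAllele")
        if allele:
            v.minus_alleles.add(allele)
    v.single_exchange_causal = v.single_exchange_causal or causal
    if cis_partner is not None:
        v.cis_partner = cis_partner


def load_catalog(
    source: str | Path | pd.DataFrame | None = None,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
) -> Catalog:
    """Build the variant catalog from the tabulated variant classes.

    ``source`` is a TSV (or pre-loaded DataFrame) with columns
    ``substitution, source_table, allele, maf_eur, combination_with,
    cis_group, agwt_antigen, agv_antigen, minus_flag``. Without an argument
    the packaged transcription of the published Kell tables is used.

    Rows are deduplicated on the substitution key; labels, alleles and
    antigen names are merged across tables. A substitution is marked
    ``single_exchange_causal`` when at least one of its rows attributes the
    phenotype to that exchange alone (no combination partner, not part of a
    two-mutations-in-cis allele).
    """
    if source is None:
        source = data_path("kell_variant_tables.tsv")
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    catalog = Catalog(maf_cutoff=maf_cutoff)
    if df.empty:
        logger.warning("empty variant table: building an empty catalog")
        return catalog

    for row in df.itertuples(index=False):
        subs = parse_protein_substitution(row.substitution)
        source_table = row.source_table
        label = _LABEL_BY_SOURCE.get(source_table)
        labels = {label} if label else set()
        maf = float(row.maf_eur) if str(row.maf_eur).strip() else None
        combination = str(getattr(row, "combination_with", "") or "").strip()
        minus = str(getattr(row, "minus_flag", "0")).strip() in {"1", "true", "True"}
        agwt = str(getattr(row, "agwt_antigen", "") or "").strip()
        agv = str(getattr(row, "agv_antigen", "") or "").strip()
        multi = len(subs) > 1
        causal = not combination and not multi
        for i, key in enumerate(subs):
            partner = None
            if multi:
                others = [k for j, k in enumerate(subs) if j != i]
                partner = others[0] if others else None
            _merge_row(
                catalog, key, source_table, str(row.allele).strip(), maf,
                combination,
                labels,
                # antigen names describe the allele; attach to every member
                agwt, agv if not multi else "",
                minus, causal, partner,
            )

    for v in catalog.variants.values():
        if not v.labels:
            v.labels.add("Uncharacterized")
        if "CtrlV" in v.labels and (v.maf_eur is None or v.maf_eur < maf_cutoff):
            raise ConsistencyError(
                f"control variant {v.substitution} has MAF {v.maf_eur} "
                f"below cutoff {maf_cutoff}"
            )
    return catalog


def apply_maf_filter(
    candidates: Iterable[Variant], cutoff: float = DEFAULT_MAF_CUTOFF
) -> tuple[list[Variant], list[Variant]]:
    """Split candidates into (retained, no-frequency) by the MAF cutoff.

    Retains exactly the variants with ``maf_eur >= cutoff``. Variants without
    a recorded frequency cannot be promoted to controls (their antigenicity
    may simply never have been probed) and are returned separately.
    """
    if cutoff <= 0:
        raise ValueError(f"MAF cutoff must be positive, got {cutoff}")
    retained: list[Variant] = []
    no_frequency: list[Variant] = []
    for v in candidates:
        if v.maf_eur is None:
            no_frequency.append(v)
        elif v.maf_eur >= cutoff:
            retained.append(v)
    return retained, no_frequency


def catalog_summary(catalog: Catalog) -> dict:
    """Headline counts of the catalog.

    Antigen counts are antigen-level (one entry per KEL antigen name; the
    two-residue KEL:35 counts once), while the arginine count is
    position-level, matching how the published totals are tallied.
    """
    variants = list(catalog.variants.values())
    per_label = {label: sum(1 for v in variants if label in v.labels) for label in LABELS}
    single_exchange = {
        cls: sum(1 for v in variants if cls in v.labels and v.single_exchange_causal)
        for cls in ("NullV", "ModV")
    }
    minus_alleles = set().union(*(v.minus_alleles for v in variants)) if variants else set()
    agwt_antigens = set().union(*(v.agwt_antigens for v in variants)) if variants else set()
    agv_antigens = set().union(*(v.agv_antigens for v in variants)) if variants else set()
    agwt_arg_positions = {
        v.position for v in variants if v.agwt_antigens and v.wt_aa == "R"
    }
    ctrl = [v for v in variants if "CtrlV" in v.labels]
    ctrl_from_minus = [v for v in ctrl if "MinusAllele" in v.labels]
    table2 = [
        v for v in variants if "T2" in catalog.provenance.get(v.key, set())
    ]
    return {
        "n_variants": len(variants),
        "per_label": per_label,
        "n_single_exchange": single_exchange,
        "n_minus_alleles": len(minus_alleles),
        "n_table2_substitutions": len(table2),
        "n_agwt_antigens": len(agwt_antigens),
        "n_agv_antigens": len(agv_antigens),
        "n_agwt_arginine_positions": len(agwt_arg_positions),
        "n_ctrlv": len(ctrl),
        "n_ctrlv_from_minus": len(ctrl_from_minus),
        "n_ctrlv_frequency_only": len(ctrl) - len(ctrl_from_minus),
    }


def summary_json(catalog: Catalog) -> str:
    return json.dumps(catalog_summary(catalog), indent=2, sort_keys=True)
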