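"""Physicochemical change per substitution: delta Z-scores and rule flags.

Each amino-acid property scale (AAIndex-style, e.g. PRAM900101
hydrophobicity, GRAR740102 polarity, GRAR740103 side-chain volume) is
Z-standardized over its 20 standard values, and a substitution is scored

    dZ = (value(variant) - mean) / sigma - (value(wildtype) - mean) / sigma
       = (value(variant) - value(wildtype)) / sigma.

The hydrophobicity scale is a transfer free energy where stronger
hydrophobicity means a lower number; it is marked ``inverted`` so that
positive dZ consistently means "more of the named property" (more
hydrophobic, larger, more polar) after substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .aminoacids import STANDARD_AA, to_one_letter
from .config import data_path
from .errors import FormatError
from .structure import ResidueContext

PACKAGED_SCALES = {
    "PRAM900101": ("aaindex_PRAM900101.tsv", True),  # hydrophobicity, inverted
    "GRAR740102": ("aaindex_GRAR740102.tsv", False),  # polarity
    "GRAR740103": ("aaindex_GRAR740103.tsv", False),  # side-chain volume
}

HOTSPOT_RESIDUES = frozenset("RQWP")
POSITIVE_RESIDUES = frozenset("RKH")
NEGATIVE_RESIDUES = frozenset("DE")

VOLUME_DZ_THRESHOLD = 0.5


@dataclass
class PropertyScale:
    """One amino-acid property scale with precomputed Z-standardization."""

    scale_id: str
    values: dict[str, float]
    inverted: bool = False
    mean: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != STANDARD_AA:
            raise FormatError(
                f"scale {self.scale_id}: expected 20 standard residues, "
                f"missing {sorted(STANDARD_AA - keys)}, extra {sorted(keys - STANDARD_AA)}"
            )
        arr = np.array([self.values[a] for a in sorted(self.values)], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise FormatError(f"scale {self.scale_id}: non-finite values")
        self.mean = float(arr.mean())
        self.sigma = float(arr.std(ddof=0))
        if self.sigma == 0:
            raise FormatError(f"scale {self.scale_id}: constant values (sigma = 0)")

    def zscore(self, aa: str) -> float:
        """Z-standardized (and sign-corrected, if inverted) property value."""
        v = self.values[to_one_letter(aa)]
        z = (v - self.mean) / self.sigma
        return -z if self.inverted else z


def load_property_table(
    path: str | Path, scale_id: Optional[str] = None, inverted: bool = False
) -> PropertyScale:
    """Load a ``residue<TAB>value`` scale file."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"residue", "value"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns residue, value")
    values = {to_one_letter(str(r.residue)): float(r.value) for r in df.itertuples(index=False)}
    return PropertyScale(scale_id or path.stem, values, inverted=inverted)


def load_packaged_scales() -> dict[str, PropertyScale]:
    """The three scales the analysis ships with, keyed by AAIndex id."""
    out = {}
    for scale_id, (fname, inverted) in PACKAGED_SCALES.items():
        out[scale_id] = load_property_table(data_path(fname), scale_id, inverted)
    return out


def delta_z(scale: PropertyScale, wt_aa: str, var_aa: str) -> float:
    """Standardized property change of a substitution on one scale.

    Antisymmetric by construction: ``delta_z(a, b) == -delta_z(b, a)``; an
    identity substitution scores 0 on every scale.
    """
    return scale.zscore(var_aa) - scale.zscore(wt_aa)


def _charge(aa: str) -> int:
    if aa in POSITIVE_RESIDUES:
        return 1
    if aa in NEGATIVE_RESIDUES:
        return -1
    return 0


def charge_change(wt_aa: str, var_aa: str) -> str:
    """Category of the signed side-chain charge transition.

    Charge assignment: Arg/Lys/His positive, Asp/Glu negative, others
    neutral. Categories: ``none``, ``gain_positive``, ``loss_positive``,
    ``gain_negative``, ``loss_negative``, ``sign_flip``.
    """
    cw = _charge(to_one_letter(wt_aa))
    cv = _charge(to_one_letter(var_aa))
    if cw == cv:
        return "none"
    if cw != 0 and cv != 0:
        return "sign_flip"
    if cv == 1:
        return "gain_positive"
    if cw == 1:
        return "loss_positive"
    if cv == -1:
        return "gain_negative"
    return "loss_negative"


@dataclass
class SubstitutionProfile:
    """Physicochemical evidence for one substitution in its structural context."""

    position: int
    wt_aa: str
    var_aa: str
    delta_z: dict[str, float]
    charge_change: str
    proline_involved: bool  # 4a: substitution from or to proline
    volume_change: bool  # 4b: |dZ volume| above threshold
    surface_charge_change: bool  # 4c: charge transition at an accessible site
    buried_hydrophobic_to_hydrophilic: bool  # 4d
    exposed_hydrophilic_to_hydrophobic: bool  # 4e
    hotspot_residue: bool  # condition 5: Arg/Gln/Trp/Pro on either side

    @property
    def any_property_change(self) -> bool:
        """Condition 4: any of the 4a-4e property-change flags."""
        return (
            self.proline_involved
            or self.volume_change
            or self.surface_charge_change
            or self.buried_hydrophobic_to_hydrophilic
            or self.exposed_hydrophilic_to_hydrophobic
        )


def build_substitution_profile(
    position: int,
    wt_aa: str,
    var_aa: str,
    context: Optional[ResidueContext],
    scales: Optional[Mapping[str, PropertyScale]] = None,
    volume_dz_threshold: float = VOLUME_DZ_THRESHOLD,
    hotspot_residues: frozenset[str] = HOTSPOT_RESIDUES,
) -> SubstitutionProfile:
    """All per-substitution flags feeding the annotation guideline.

    The hydrophobic/hydrophilic dichotomy for flags 4d/4e is the sign of the
    (inversion-corrected) hydrophobicity Z-score: positive means hydrophobic.
    Flags that require a burial class (4c/4d/4e) are False when ``context``
    is None; delta-Z values and the context-free flags (4a, 4b, 5) are
    always computed.
    """
    wt = to_one_letter(wt_aa)
    var = to_one_letter(var_aa)
    if context is None:
        raise ValueError(f"missing residue context for position {position}")
    if scales is None:
        scales = load_packaged_scales()
    dz = {sid: delta_z(s, wt, var) for sid, s in scales.items()}
    cc = charge_change(wt, var)
    hydro = scales.get("PRAM900101")
    wt_hydrophobic = hydro is not None and hydro.zscore(wt) > 0
    var_hydrophobic = hydro is not None and hydro.zscore(var) > 0
    burial = context.burial
    return SubstitutionProfile(
        position=position,
        wt_aa=wt,
        var_aa=var,
        delta_z=dz,
        charge_change=cc,
        proline_involved="P" in (wt, var),
        volume_change=abs(dz.get("GRAR740103", 0.0)) >= volume_dz_threshold,
        surface_charge_change=burial in ("half_buried", "exposed") and cc != "none",
        buried_hydrophobic_to_hydrophilic=(
            burial == "buried" and wt_hydrophobic and not var_hydrophobic
        ),
        exposed_hydrophilic_to_hydrophobic=(
            burial == "exposed" and not wt_hydrophobic and var_hydrophobic
        ),
        hotspot_residue=bool({wt, var} & hotspot_residues),
    )


def profile_to_row(profile: SubstitutionProfile) -> dict:
    row = {
        "position": profile.position,
        "wt_aa": profile.wt_aa,
        "var_aa": profile.var_aa,
        "charge_change": profile.charge_change,
        "proline_involved": profile.proline_involved,
        "volume_change": profile.volume_change,
        "surface_charge_change": profile.surface_charge_change,
        "buried_hydrophobic_to_hydrophilic": profile.buried_hydrophobic_to_hydrophilic,
        "exposed_hydrophilic_to_hydrophobic": profile.exposed_hydrophilic_to_hydrophobic,
        "hotspot_residue": profile.hotspot_residue,
    }
    for sid, value in profile.delta_z.items():
        row[f"dz_{sid}"] = round(value, 4)
    return row
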