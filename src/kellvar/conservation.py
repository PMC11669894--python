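"""Per-position conservation from an ortholog MSA and homolog structures.

Sequence conservation of a human Kell position is the percentage of
ortholog rows carrying the identical residue in the aligned column; the
human reference row is excluded from the denominator (39 orthologs in the
published alignment of 40 sequences), and a gap counts as a mismatch.

Structural conservation is a 0-3 count over residue-correspondence maps to
the three structurally characterized M13 family relatives (ECE-1, NEP and
the bacterial Zmp1): the number of partners whose spatially equivalent
residue is the identical amino acid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import AlignIO

from .aminoacids import to_one_letter
from .errors import FormatError

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


@dataclass
class Alignment:
    """Aligned sequences plus the reference coordinate map."""

    rows: dict[str, str]  # id -> aligned sequence (uppercase)
    reference_id: str
    position_to_column: dict[int, int]  # ungapped reference position -> column

    @property
    def ortholog_ids(self) -> list[str]:
        return [i for i in self.rows if i != self.reference_id]

    @property
    def n_orthologs(self) -> int:
        return len(self.rows) - 1


def read_msa(path: str | Path, reference_id: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA file and index it against a reference row.

    All sequences must have equal (aligned) length. ``reference_id`` may be
    a full or prefix match of a record id; by default the first record is
    the reference. Columns where the reference has a gap carry no reference
    position and are skipped by the position map.
    """
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise FormatError(f"cannot read alignment {path}: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(rows) < len(aln):
        raise FormatError(f"duplicate sequence ids in {path}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    ids = list(rows)
    if reference_id is None:
        ref = ids[0]
    else:
        matches = [i for i in ids if i == reference_id or i.startswith(reference_id)]
        if not matches:
            raise FormatError(f"reference id {reference_id!r} not found in {path}")
        ref = matches[0]
    pos_map: dict[int, int] = {}
    position = 0
    for col, ch in enumerate(rows[ref]):
        if ch not in GAP_CHARS:
            position += 1
            pos_map[position] = col
    return Alignment(rows=rows, reference_id=ref, position_to_column=pos_map)


def ortholog_conservation(alignment: Alignment, position: int) -> float:
    """Percent of orthologs matching the human residue at ``position``.

    ``position`` is an ungapped 1-based residue number of the reference
    sequence. Returns a percentage in [0, 100].
    """
    col = alignment.position_to_column.get(position)
    if col is None:
        raise KeyError(f"position {position} is not mapped to an alignment column")
    ref_aa = alignment.rows[alignment.reference_id][col]
    orthologs = alignment.ortholog_ids
    if not orthologs:
        raise ValueError("alignment has no ortholog rows")
    matches = sum(1 for i in orthologs if alignment.rows[i][col] == ref_aa)
    return 100.0 * matches / len(orthologs)


@dataclass
class CorrespondenceMap:
    """Partial residue correspondence between Kell and one homolog structure."""

    partner_name: str
    pairs: dict[int, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        partner_positions = [p for p, _ in self.pairs.values()]
        if len(partner_positions) != len(set(partner_positions)):
            raise FormatError(
                f"correspondence map {self.partner_name}: mapping is not injective"
            )


def read_correspondence_map(path: str | Path, partner_name: Optional[str] = None) -> CorrespondenceMap:
    """Read a 3-column TSV ``kell_pos, partner_pos, partner_aa``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"kell_pos", "partner_pos", "partner_aa"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    pairs = {
        int(r.kell_pos): (int(r.partner_pos), to_one_letter(str(r.partner_aa)))
        for r in df.itertuples(index=False)
    }
    return CorrespondenceMap(partner_name or path.stem, pairs)


def structural_conservation(
    maps: Sequence[CorrespondenceMap], position: int, kell_aa: str
) -> int:
    """Number of homolog structures conserving the identical residue (0-3).

    Positions absent from a map contribute 0 for that map (no structural
    equivalent found by the structural alignment).
    """
    kell_aa = to_one_letter(kell_aa)
    count = 0
    for m in maps:
        pair = m.pairs.get(position)
        if pair is None:
            logger.debug("position %d not mapped in %s", position, m.partner_name)
            continue
        if pair[1] == kell_aa:
            count += 1
    return count


@dataclass
class ConservationProfile:
    """Conservation evidence for one residue position.

    ``structural_count`` is None when no correspondence maps were supplied
    (structural conservation unknown, as opposed to conserved in zero maps).
    """

    position: int
    ortholog_pct: float
    structural_count: Optional[int]


def build_conservation_profiles(
    alignment: Alignment,
    positions: Sequence[int],
    maps: Sequence[CorrespondenceMap] = (),
    kell_sequence: Optional[Mapping[int, str]] = None,
) -> dict[int, ConservationProfile]:
    """Conservation profiles for a set of reference positions.

    ``kell_sequence`` maps position to residue for structural matching; by
    default the reference row of the alignment is used.
    """
    out: dict[int, ConservationProfile] = {}
    for pos in positions:
        pct = ortholog_conservation(alignment, pos)
        col = alignment.position_to_column[pos]
        aa = (
            kell_sequence[pos]
            if kell_sequence is not None
            else alignment.rows[alignment.reference_id][col]
        )
        out[pos] = ConservationProfile(
            position=pos,
            ortholog_pct=pct,
            structural_count=structural_conservation(maps, pos, aa) if maps else None,
        )
    return out


def profiles_to_frame(profiles: Mapping[int, ConservationProfile]) -> pd.DataFrame:
    rows = [
        {
            "position": p.position,
            "ortholog_pct": round(p.ortholog_pct, 2),
            "structural_count": p.structural_count,
        }
        for p in sorted(profiles.values(), key=lambda p: p.position)
    ]
    return pd.DataFrame(rows)
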