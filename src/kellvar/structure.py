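"""Per-residue structural context and conformational-epitope clustering.

Solvent accessibility is computed with a rolling-probe sphere-point method
(Shrake-Rupley): each heavy atom is covered with a quasi-uniform point
lattice on its probe-expanded sphere, and the accessible area is the
fraction of points not occluded by any neighbouring probe-expanded sphere.
Relative solvent accessibility (RSA) divides the residue area by a
residue-specific theoretical maximum, and residues are binned into the
half-open burial classes

* buried:       0.00 <= RSA < 0.05
* half-buried:  0.05 <= RSA < 0.25
* exposed:      0.25 <= RSA <= 1

Antigenic sites are clustered into candidate conformational epitopes by
single-linkage connected components of the Calpha distance graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .aminoacids import THREE_TO_ONE
from .config import data_path, load_config
from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

#: van der Waals radii by element (Angstrom); heavy-atom set
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
    "ZN": 1.39,
}
DEFAULT_RADIUS = 1.80
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

BURIED_MAX = 0.05
HALF_BURIED_MAX = 0.25

DOMAIN_LABELS = ("IC", "TM", "MPD", "MDD", "extracellular_unassigned")


# ---------------------------------------------------------------------------
# structure reading


@dataclass
class ResidueTable:
    """Flat atom arrays plus per-residue bookkeeping for one chain."""

    positions: list[int]
    aa: dict[int, str]  # position -> one-letter code ("X" if non-standard)
    atom_coords: np.ndarray  # (n_atoms, 3)
    atom_radii: np.ndarray  # (n_atoms,)
    atom_position: np.ndarray  # (n_atoms,) residue position per atom
    ca_coords: dict[int, np.ndarray]
    missing_positions: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)

    def atoms_of(self, position: int) -> np.ndarray:
        return np.flatnonzero(self.atom_position == position)


def read_structure(
    path: str | Path,
    chain: Optional[str] = None,
    include_hetero: bool = False,
) -> ResidueTable:
    """Read a PDB/mmCIF file into a residue table (author numbering).

    Alternate locations are resolved to the highest-occupancy conformer,
    hydrogens are dropped, and hetero compounds (waters, the active-site
    zinc) are excluded unless ``include_hetero`` is set. Gaps in the author
    numbering are reported as missing residues.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unreadable structure file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"no models/chains in {path}")
    st.setup_entities()
    model = st[0]
    if chain is None:
        polymer_chains = [ch for ch in model if any(r.name in THREE_TO_ONE for r in ch)]
        if not polymer_chains:
            raise FormatError(f"no protein atoms in {path}")
        if len(polymer_chains) > 1:
            raise FormatError(
                f"{path} has {len(polymer_chains)} protein chains; select one "
                f"explicitly ({', '.join(ch.name for ch in polymer_chains)})"
            )
        ch = polymer_chains[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise FormatError(f"chain {chain!r} not found in {path}")

    positions: list[int] = []
    aa: dict[int, str] = {}
    coords: list[list[float]] = []
    radii: list[float] = []
    atom_pos: list[int] = []
    ca: dict[int, np.ndarray] = {}
    for res in ch:
        standard = res.name in THREE_TO_ONE
        if not standard and not include_hetero:
            continue
        if res.is_water():
            continue
        num = res.seqid.num
        if num in aa:
            raise FormatError(f"duplicate residue number {num} in {path}")
        positions.append(num)
        aa[num] = THREE_TO_ONE.get(res.name, "X")
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.element.name == "H" or atom.element.name == "D":
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        for name, atom in best.items():
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            radii.append(VDW_RADII.get(atom.element.name.upper(), DEFAULT_RADIUS))
            atom_pos.append(num)
            if name == "CA":
                ca[num] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    if not positions:
        raise FormatError(f"no protein atoms in {path}")
    missing = []
    lo, hi = min(positions), max(positions)
    present = set(positions)
    missing = [p for p in range(lo, hi + 1) if p not in present]
    if missing:
        logger.info("%d missing residues in %s (e.g. %s)", len(missing), path, missing[:5])
    return ResidueTable(
        positions=positions,
        aa=aa,
        atom_coords=np.asarray(coords, dtype=float),
        atom_radii=np.asarray(radii, dtype=float),
        atom_position=np.asarray(atom_pos, dtype=int),
        ca_coords=ca,
        missing_positions=missing,
    )


# ---------------------------------------------------------------------------
# accessible surface area


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden-spiral construction)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area (A^2) by the sphere-point method."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius <= 0:
        raise ValueError(f"probe_radius must be positive, got {probe_radius}")
    if n_points < 100:
        raise ValueError(f"n_points must be >= 100, got {n_points}")
    n = len(coords)
    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    out = np.zeros(n)
    if n == 0:
        return out
    tree = cKDTree(coords)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + expanded.max())
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        out[i] = 4.0 * math.pi * ri * ri * accessible.sum() / n_points
    return out


def compute_accessible_surface(
    residues: ResidueTable,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[int, float]:
    """Per-residue absolute ASA: sum of its atoms' contributions."""
    per_atom = atom_asa(residues.atom_coords, residues.atom_radii, probe_radius, n_points)
    out: dict[int, float] = {}
    for pos in residues.positions:
        idx = residues.atoms_of(pos)
        if idx.size == 0:
            logger.warning("residue %d has no atoms; excluded from ASA", pos)
            continue
        out[pos] = float(per_atom[idx].sum())
    return out


# ---------------------------------------------------------------------------
# relative accessibility and burial


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Residue-specific maximum reference areas (Gly-X-Gly theoretical)."""
    if path is None:
        path = data_path("max_asa_theoretical.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    table = {str(r.residue): float(r.max_asa) for r in df.itertuples(index=False)}
    missing = set(THREE_TO_ONE.values()) - set(table)
    if missing:
        raise FormatError(f"max-ASA table missing residues: {sorted(missing)}")
    return table


def burial_class(
    rsa: float,
    buried_max: float = BURIED_MAX,
    half_buried_max: float = HALF_BURIED_MAX,
) -> str:
    """Half-open burial partition; each boundary belongs to the upper class."""
    if not 0.0 <= rsa <= 1.0:
        raise ValueError(f"rsa {rsa} outside [0, 1]")
    if rsa < buried_max:
        return "buried"
    if rsa < half_buried_max:
        return "half_buried"
    return "exposed"


def compute_rsa(
    asa_abs: float,
    aa: str,
    max_asa: Optional[Mapping[str, float]] = None,
) -> tuple[float, str]:
    """Relative solvent accessibility (clamped to [0, 1]) and burial class."""
    if asa_abs < 0:
        raise ValueError(f"negative ASA {asa_abs}")
    table = load_max_asa() if max_asa is None else max_asa
    if aa not in table:
        raise KeyError(f"no max-ASA reference for residue {aa!r}")
    rsa = min(1.0, asa_abs / table[aa])
    return rsa, burial_class(rsa)


# ---------------------------------------------------------------------------
# topological domains and membrane proximity


def _intervals(config_domains: Mapping[str, Sequence[Sequence[int]]]) -> list[tuple[str, int, int]]:
    out = []
    for label, spans in config_domains.items():
        if label == "extracellular":
            continue  # umbrella region; MPD/MDD refine it
        for span in spans or []:
            start, end = int(span[0]), int(span[1])
            if start > end:
                raise ConfigError(f"bad domain interval {label}: {span}")
            out.append((label, start, end))
    out.sort(key=lambda t: (t[1], t[2]))
    for (la, sa, ea), (lb, sb, eb) in zip(out, out[1:]):
        if sb <= ea:
            raise ConfigError(
                f"overlapping domain intervals {la} [{sa},{ea}] and {lb} [{sb},{eb}]"
            )
    return out


def assign_domain(
    position: int,
    boundaries: Optional[Mapping[str, Sequence[Sequence[int]]]] = None,
) -> str:
    """Topological domain of a residue position.

    Positions in the extracellular region that fall outside any configured
    membrane-proximal (MPD) / membrane-distal (MDD) interval are labelled
    ``extracellular_unassigned``.
    """
    if boundaries is None:
        boundaries = load_config()["domains"]
    for label, start, end in _intervals(boundaries):
        if start <= position <= end:
            return label
    return "extracellular_unassigned"


def membrane_distance(ca_coord: Sequence[float], plane: Mapping) -> float:
    """Signed distance (Angstrom) of a point to the membrane plane."""
    point = np.asarray(plane["point"], dtype=float)
    normal = np.asarray(plane["normal"], dtype=float)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ValueError("membrane plane normal has zero length")
    return float(np.dot(np.asarray(ca_coord, dtype=float) - point, normal) / norm)


def membrane_proximity(
    ca_coord: Sequence[float],
    plane: Mapping,
    threshold: float = 15.0,
) -> bool:
    """True when the signed distance along the membrane normal is < threshold."""
    return membrane_distance(ca_coord, plane) < threshold


# ---------------------------------------------------------------------------
# residue context assembly


@dataclass
class ResidueContext:
    """Structural context of one residue position."""

    position: int
    aa: str
    ca_coord: Optional[np.ndarray]
    asa_abs: float
    rsa: float
    burial: str
    domain: str
    membrane_distance: Optional[float] = None
    membrane_proximal: Optional[bool] = None


def build_residue_contexts(
    residues: ResidueTable,
    config: Optional[Mapping] = None,
    probe_radius: Optional[float] = None,
    n_points: Optional[int] = None,
) -> dict[int, ResidueContext]:
    """Compute ASA/RSA/burial/domain (and membrane proximity if configured)
    for every residue of a structure."""
    cfg = load_config() if config is None else config
    probe = cfg["asa"]["probe_radius"] if probe_radius is None else probe_radius
    npts = cfg["asa"]["n_points"] if n_points is None else n_points
    asa = compute_accessible_surface(residues, probe, npts)
    max_table = load_max_asa()
    plane = cfg.get("membrane", {}).get("plane")
    threshold = cfg.get("membrane", {}).get("threshold", 15.0)
    out: dict[int, ResidueContext] = {}
    for pos in residues.positions:
        if pos not in asa:
            continue
        aa = residues.aa[pos]
        if aa in max_table:
            rsa, burial = compute_rsa(asa[pos], aa, max_table)
        else:
            rsa, burial = 0.0, "buried"
            logger.warning("no max-ASA reference for residue %s%d; RSA set to 0", aa, pos)
        ca = residues.ca_coords.get(pos)
        dist = prox = None
        if plane is not None and ca is not None:
            dist = membrane_distance(ca, plane)
            prox = dist < threshold
        out[pos] = ResidueContext(
            position=pos,
            aa=aa,
            ca_coord=ca,
            asa_abs=asa[pos],
            rsa=rsa,
            burial=burial,
            domain=assign_domain(pos, cfg["domains"]),
            membrane_distance=dist,
            membrane_proximal=prox,
        )
    return out


def contexts_to_frame(contexts: Mapping[int, ResidueContext]) -> pd.DataFrame:
    rows = [
        {
            "position": c.position,
            "aa": c.aa,
            "asa_abs": round(c.asa_abs, 3),
            "rsa": round(c.rsa, 4),
            "burial": c.burial,
            "domain": c.domain,
            "membrane_distance": c.membrane_distance,
        }
        for c in sorted(contexts.values(), key=lambda c: c.position)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conformational epitope clustering


@dataclass
class EpitopeCandidate:
    """Spatial cluster of antigenic residue positions."""

    member_positions: set[int]
    segments: list[tuple[int, int]]
    diameter: float
    indirect_members: set[int] = field(default_factory=set)  # buried contributors

    @property
    def is_singleton(self) -> bool:
        return len(self.member_positions) == 1


def _runs(positions: Iterable[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive sequence positions."""
    ordered = sorted(set(positions))
    if not ordered:
        return []
    runs = [[ordered[0], ordered[0]]]
    for p in ordered[1:]:
        if p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [(a, b) for a, b in runs]


def cluster_epitope_candidates(
    positions: Iterable[int],
    contexts: Mapping[int, ResidueContext],
    linkage_distance: float = 12.0,
) -> tuple[list[EpitopeCandidate], list[int]]:
    """Single-linkage clusters of antigenic sites in 3D.

    Two sites join the same candidate epitope when their Calpha atoms are
    within ``linkage_distance`` (possibly through intermediates). Returns
    the clusters ordered by smallest member position, plus the positions
    lacking coordinates (unclusterable). Buried members (RSA < 0.05) stay in
    their cluster but are flagged as indirect contributors.
    """
    wanted = sorted(set(positions))
    clusterable = []
    unclusterable = []
    for p in wanted:
        ctx = contexts.get(p)
        if ctx is None or ctx.ca_coord is None:
            unclusterable.append(p)
        else:
            clusterable.append(p)
    if not clusterable:
        return [], unclusterable
    coords = np.array([contexts[p].ca_coord for p in clusterable])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(linkage_distance, output_type="ndarray")
    n = len(clusterable)
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters: list[EpitopeCandidate] = []
    for comp in range(n_comp):
        members = [clusterable[i] for i in np.flatnonzero(labels == comp)]
        member_coords = coords[[clusterable.index(m) for m in members]]
        if len(members) > 1:
            d = np.linalg.norm(member_coords[:, None] - member_coords[None, :], axis=-1)
            diameter = float(d.max())
        else:
            diameter = 0.0
        clusters.append(
            EpitopeCandidate(
                member_positions=set(members),
                segments=_runs(members),
                diameter=diameter,
                indirect_members={m for m in members if contexts[m].rsa < BURIED_MAX},
            )
        )
    clusters.sort(key=lambda c: min(c.member_positions))
    return clusters, unclusterable


def epitopes_to_bed(
    clusters: Sequence[EpitopeCandidate], name: str = "kell"
) -> pd.DataFrame:
    """BED-like interval table (0-based half-open) of cluster segments."""
    rows = []
    for i, cluster in enumerate(clusters, start=1):
        for start, end in cluster.segments:
            rows.append(
                {
                    "chrom": name,
                    "start": start - 1,
                    "end": end,
                    "name": f"epitope_{i}",
                    "n_members": len(cluster.member_positions),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "n_members"])
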