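"""Antibody–antigen contact tables and nearest-atom distances.

Works on already-docked atomic models (PDB; mmCIF via gemmi): finds all
antibody/antigen residue pairs whose minimum heavy-atom distance falls below
a cutoff, labels antigen residues with user-supplied domain ranges, and
measures exact nearest-atom distances between arbitrary selections (e.g.
from a mutation site to the whole antibody fragment).  Docking itself is out
of scope; chain roles (antigen / antibody heavy / antibody light) come from
configuration, not sequence analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomicModel",
    "ContactRecord",
    "NearestPair",
    "read_model",
    "nearest_atom_distance",
    "contact_table",
    "annotate_domains",
    "contacts_to_frame",
]

_ATOM_COLUMNS = ["serial", "chain", "resname", "resseq", "icode",
                 "atom", "element", "x", "y", "z", "occupancy", "b"]


@dataclass
class AtomicModel:
    """Flat atom table of a model, with chain-level role labels.

    ``atoms`` columns: serial, chain, resname, resseq, icode, atom, element,
    x, y, z (Å), occupancy, b.  ``roles`` maps chain id to a label such as
    "antigen", "heavy" or "light".
    """

    atoms: pd.DataFrame
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("model contains no atoms")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite atom coordinates")

    def select(self, chain=None, resseq=None, atom=None) -> pd.DataFrame:
        """Subset of the atom table by chain id(s), residue number(s), atom name(s)."""
        df = self.atoms
        for col, value in (("chain", chain), ("resseq", resseq), ("atom", atom)):
            if value is None:
                continue
            values = [value] if np.isscalar(value) or isinstance(value, str) \
                else list(value)
            df = df[df[col].isin(values)]
        return df

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))


@dataclass
class ContactRecord:
    antibody_chain: str
    antibody_role: str
    antibody_resname: str
    antibody_resseq: int
    antigen_chain: str
    antigen_resname: str
    antigen_resseq: int
    min_distance: float
    domain: str = "unassigned"


@dataclass
class NearestPair:
    distance: float
    serial_a: int
    serial_b: int


def read_model(path, roles: dict | None = None) -> AtomicModel:
    """Read a PDB (or mmCIF) file into an :class:`AtomicModel`.

    All ATOM/HETATM records are kept; among alternate locations of an atom
    the highest-occupancy one is retained; exact duplicates keep the first
    occurrence with a warning.
    """
    st = gemmi.read_structure(str(path))
    rows = []
    serial = 0
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    serial += 1
                    rows.append((serial, chain.name, residue.name,
                                 residue.seqid.num, residue.seqid.icode.strip(),
                                 atom.name, atom.element.name,
                                 atom.pos.x, atom.pos.y, atom.pos.z,
                                 atom.occ, atom.b_iso))
        break  # first model only
    if not rows:
        raise ValueError(f"no atoms found in {path!s}")
    df = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    key = ["chain", "resseq", "icode", "atom"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        before = len(df)
        df = (df.sort_values("occupancy", ascending=False, kind="stable")
                .drop_duplicates(subset=key, keep="first")
                .sort_values("serial"))
        n_same = before - len(df)
        if n_same:
            warnings.warn(f"dropped {n_same} duplicate/altloc atoms "
                          f"(kept highest occupancy)", stacklevel=2)
    return AtomicModel(atoms=df.reset_index(drop=True), roles=roles or {})


def nearest_atom_distance(selection_a: pd.DataFrame,
                          selection_b: pd.DataFrame) -> NearestPair:
    """Exact minimum Euclidean distance between two atom selections (Å).

    Ties are broken by the lowest atom serial in selection A, then B.
    """
    for name, sel in (("A", selection_a), ("B", selection_b)):
        if len(sel) == 0:
            raise ValueError(f"selection {name} is empty")
    xa = selection_a[["x", "y", "z"]].to_numpy(dtype=float)
    xb = selection_b[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(xb)
    dists, nearest = tree.query(xa)
    dmin = dists.min()
    cand = np.flatnonzero(dists <= dmin + 1e-9)
    sa = selection_a["serial"].to_numpy()
    sb = selection_b["serial"].to_numpy()
    order = np.lexsort((sb[nearest[cand]], sa[cand]))
    i = cand[order[0]]
    return NearestPair(distance=float(dists[i]), serial_a=int(sa[i]),
                       serial_b=int(sb[nearest[i]]))


def contact_table(model: AtomicModel, antibody_chains, antigen_chains,
                  cutoff: float = 4.5,
                  domain_ranges: pd.DataFrame | None = None,
                  ) -> list[ContactRecord]:
    """All antibody/antigen residue pairs with min atom distance ≤ cutoff.

    Uses a k-d tree over antigen atoms so the search is near-linear in atom
    count.  ``antibody_chains`` / ``antigen_chains`` are chain-id lists and
    must not overlap; chain roles for the antibody come from ``model.roles``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ab_set, ag_set = set(antibody_chains), set(antigen_chains)
    if ab_set & ag_set:
        raise ValueError(f"chains {sorted(ab_set & ag_set)} assigned to both roles")
    ab = model.select(chain=sorted(ab_set))
    ag = model.select(chain=sorted(ag_set))
    if len(ab) == 0 or len(ag) == 0:
        raise ValueError("empty antibody or antigen selection")
    ag_xyz = ag[["x", "y", "z"]].to_numpy(dtype=float)
    ab_xyz = ab[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(ag_xyz)
    pairs: dict[tuple, float] = {}
    info_ab = ab[["chain", "resname", "resseq"]].to_numpy(dtype=object)
    info_ag = ag[["chain", "resname", "resseq"]].to_numpy(dtype=object)
    for i, neighbors in enumerate(tree.query_ball_point(ab_xyz, cutoff)):
        for j in neighbors:
            d = float(np.linalg.norm(ab_xyz[i] - ag_xyz[j]))
            key = (tuple(info_ab[i]), tuple(info_ag[j]))
            if d < pairs.get(key, np.inf):
                pairs[key] = d
    records = []
    for ((ab_ch, ab_rn, ab_rs), (ag_ch, ag_rn, ag_rs)), d in sorted(
            pairs.items(), key=lambda kv: (kv[0][1][0], kv[0][1][2],
                                           kv[0][0][0], kv[0][0][2])):
        records.append(ContactRecord(
            antibody_chain=ab_ch, antibody_role=model.roles.get(ab_ch, ""),
            antibody_resname=ab_rn, antibody_resseq=int(ab_rs),
            antigen_chain=ag_ch, antigen_resname=ag_rn,
            antigen_resseq=int(ag_rs), min_distance=d))
    if domain_ranges is not None:
        records = annotate_domains(records, domain_ranges)
    return records


def annotate_domains(contacts: list[ContactRecord],
                     domain_ranges: pd.DataFrame) -> list[ContactRecord]:
    """Label each contact's antigen residue with its containing domain range.

    ``domain_ranges`` is a table with columns ``label``, ``start``, ``end``
    (inclusive residue numbers) and optionally ``chain``; ranges must not
    overlap within a chain.  Residues outside every range get "unassigned".
    Domain boundaries are configuration data — they are not derivable from a
    coordinate file.
    """
    ranges = domain_ranges.copy()
    if "chain" not in ranges.columns:
        ranges["chain"] = None
    for chain, grp in ranges.groupby(ranges["chain"].astype(str)):
        g = grp.sort_values("start")
        if np.any(g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]):
            raise ValueError(f"overlapping domain ranges for chain {chain}")
    out = []
    for rec in contacts:
        label = "unassigned"
        for _, row in ranges.iterrows():
            if row["chain"] not in (None, rec.antigen_chain):
                continue
            if row["start"] <= rec.antigen_resseq <= row["end"]:
                label = str(row["label"])
                break
        out.append(ContactRecord(**{**rec.__dict__, "domain": label}))
    return out


def contacts_to_frame(contacts: list[ContactRecord]) -> pd.DataFrame:
    """Contact records as a table (TSV-ready, one row per residue pair)."""
    return pd.DataFrame([rec.__dict__ for rec in contacts])
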