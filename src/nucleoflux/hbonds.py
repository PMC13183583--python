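"""Static backbone hydrogen-bond detection and interstrand counting.

Backbone amide N atoms act as donors and carbonyl O atoms as acceptors.
A candidate pair of non-adjacent residues (|i - j| >= 2 in the same chain;
any separation across chains) is accepted as hydrogen-bonded when the
donor-to-acceptor heavy-atom distance is at most 4 A and, when the amide
hydrogen is present, the D-H...A geometry deviates from linearity by at
most 30 degrees (i.e. the N-H...O angle is at least 150 degrees).  When no
hydrogen is present the bond is accepted on distance alone and flagged as a
fallback.  These are the standard contact-analysis criteria for counting
the interstrand "mechanical clamp" bonds that set the unfolding force of
beta-sandwich domains such as titin Ig27.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HBond",
    "parse_structure",
    "find_backbone_hbonds",
    "interstrand_count",
    "assign_strands",
]

_AMIDE_H_NAMES = ("H", "HN", "H1")


@dataclass(frozen=True)
class HBond:
    """One backbone hydrogen bond with its geometry.

    ``donor`` and ``acceptor`` are (chain, residue number, residue name,
    atom name).  ``angle`` is the deviation from a linear D-H...A
    arrangement in degrees (NaN when the hydrogen was absent and the
    distance-only fallback applied).
    """

    donor: tuple
    acceptor: tuple
    distance: float
    angle: float
    fallback: bool = False


def parse_structure(path, model: int | None = None):
    """Parse a PDB file into a biotite AtomArray.

    Keeps the first model by default (NMR ensembles), the highest-occupancy
    altloc per atom, and any hydrogens present.
    """
    import biotite.structure.io.pdb as pdbio

    pdb = pdbio.PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError("no models in PDB file")
    atoms = pdb.get_structure(model=model if model is not None else 1, altloc="occupancy")
    if atoms.array_length() == 0:
        raise ValueError("selected model is empty")
    return atoms


def _residue_table(atoms):
    """Map (chain, res_id) -> {atom_name: coord} for backbone atoms."""
    table: dict = {}
    names = atoms.atom_name
    keep = np.isin(names, ("N", "O", "C", "CA") + _AMIDE_H_NAMES)
    for i in np.nonzero(keep)[0]:
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        entry = table.setdefault(key, {"res_name": str(atoms.res_name[i])})
        entry[str(names[i])] = atoms.coord[i]
    return table


def _linearity_deviation(d, h, a):
    """Degrees away from a straight D-H...A arrangement."""
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle_dha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle_dha


def find_backbone_hbonds(atoms, d_cut: float = 4.0, angle_cut: float = 30.0):
    """Detect backbone N-H...O=C hydrogen bonds under geometric cutoffs.

    Returns a list of :class:`HBond`.  Donors are backbone amide N atoms,
    acceptors backbone carbonyl O atoms of residues at least two apart in
    sequence (or in different chains).
    """
    table = _residue_table(atoms)
    if not any("N" in v or "O" in v for v in table.values()):
        raise ValueError("no backbone N/O atoms found")

    keys = sorted(table)
    donors = [(k, table[k]) for k in keys if "N" in table[k]]
    acceptors = [(k, table[k]) for k in keys if "O" in table[k]]
    if not donors or not acceptors:
        return []

    don_xyz = np.array([v["N"] for _, v in donors])
    acc_xyz = np.array([v["O"] for _, v in acceptors])
    # pairwise distances; structures of interest are small (<= few 1,000 res)
    diff = don_xyz[:, None, :] - acc_xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    bonds = []
    for di, ai in zip(*np.nonzero(dist <= d_cut)):
        (dchain, dres), dv = donors[di]
        (achain, ares), av = acceptors[ai]
        if dchain == achain and abs(dres - ares) < 2:
            continue
        h = next((dv[nm] for nm in _AMIDE_H_NAMES if nm in dv), None)
        if h is not None:
            dev = _linearity_deviation(dv["N"], h, av["O"])
            if dev > angle_cut:
                continue
            bonds.append(
                HBond(
                    donor=(dchain, dres, dv["res_name"], "N"),
                    acceptor=(achain, ares, av["res_name"], "O"),
                    distance=float(dist[di, ai]),
                    angle=float(dev),
                )
            )
        else:
            bonds.append(
                HBond(
                    donor=(dchain, dres, dv["res_name"], "N"),
                    acceptor=(achain, ares, av["res_name"], "O"),
                    distance=float(dist[di, ai]),
                    angle=float("nan"),
                    fallback=True,
                )
            )
    return bonds


def _as_residue_set(rng):
    """Accept a set of res_ids, (chain, res_id) pairs, or (lo, hi) spans."""
    out = set()
    for item in rng:
        if isinstance(item, tuple) and len(item) == 2 and all(
            isinstance(x, (int, np.integer)) for x in item
        ):
            # ambiguous: treat small-int pair as a residue span
            lo, hi = item
            out.update(range(int(lo), int(hi) + 1))
        elif isinstance(item, (int, np.integer)):
            out.add(int(item))
        else:
            out.add(item)
    return out


def interstrand_count(hbonds, range_a, range_b) -> int:
    """Count hydrogen bonds with one partner in each residue range.

    ``range_a``/``range_b`` are iterables of residue numbers (chain-blind)
    or (lo, hi) spans; they must be disjoint.  The count is symmetric in
    the two ranges and includes bonds in either donor/acceptor direction.
    """
    a = _as_residue_set(range_a)
    b = _as_residue_set(range_b)
    if a & b:
        raise ValueError("residue ranges must be disjoint")
    n = 0
    for hb in hbonds:
        rd, ra = hb.donor[1], hb.acceptor[1]
        if (rd in a and ra in b) or (rd in b and ra in a):
            n += 1
    return n


def assign_strands(atoms, chain: str | None = None):
    """Beta-strand residue spans from CA-geometry secondary structure.

    Uses the P-SEA annotation of the parsed coordinates (no external
    assignment files) and returns an ordered list of (start_res, end_res)
    spans labelled "b".  Strands are indexed in sequence order, so for an
    Ig-like domain the first spans correspond to the A/A' strands and the
    last one to the G strand.
    """
    import biotite.structure as struc

    if chain is None:
        chain = str(atoms.chain_id[0])
    sel = atoms[(atoms.chain_id == chain) & struc.filter_amino_acids(atoms)]
    sse = struc.annotate_sse(sel)
    res_ids = np.unique(sel.res_id)
    spans = []
    start = None
    for rid, code in zip(res_ids, sse):
        if code == "b" and start is None:
            start = rid
        elif code != "b" and start is not None:
            spans.append((int(start), int(prev)))
            start = None
        prev = rid
    if start is not None:
        spans.append((int(start), int(prev)))
    return spans
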