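import numpy as np
import pytest

from nucleoflux.kinetics import TransportParams
from nucleoflux.simulate import CellSimSpec


MCHERRY_KE = 1.87
MCHERRY_K = 4.94e-3  # s^-1  (4.94 ks^-1)


@pytest.fixture
def mcherry_params():
    """Import-forward mCherry-like kinetic truth (K_e, k in s^-1, v)."""
    return TransportParams.from_accumulation(MCHERRY_KE, MCHERRY_K, 1.0)


@pytest.fixture
def recovery_only_spec(mcherry_params):
    """Noiseless recovery-phase-only simulation (nucleus starts empty)."""
    return CellSimSpec(
        params=mcherry_params,
        activation_duration=0.0,
        recovery_duration=2700.0,
        frame_interval=60.0,
        noise_cv=0.0,
        seed=0,
    )


def ideal_sheet_atoms(separation_extra=0.0, with_hydrogens=True):
    """Construct an idealized two-strand beta-sheet backbone.

    Geometry is built so that exactly four linear N-H...O ladder bonds of
    length 2.9 A connect strand 1 (residues 1-4) and strand 2 (residues
    21-24).  ``separation_extra`` shifts strand 2 away along y (a 2 A shift
    pushes every ladder bond beyond the 4 A cutoff).
    """
    import biotite.structure as struc

    dy = separation_extra
    # (res_id, atom_name, x, y, z); strand 1 at y~0, strand 2 at y~4.6
    spec = [
        # strand 1
        (1, "N", 0.0, 0.0, 0.0), (1, "H", 0.0, 1.0, 0.0),
        (1, "CA", 1.2, -0.8, 0.0), (1, "C", 2.4, 0.0, 0.0),
        (2, "N", 3.5, 0.0, 0.0), (2, "H", 3.5, -1.0, 0.0),
        (2, "CA", 4.0, 0.6, 0.0), (2, "C", 4.7, 0.5, 0.0), (2, "O", 4.7, 1.7, 0.0),
        (3, "N", 7.0, 0.0, 0.0), (3, "H", 7.0, 1.0, 0.0),
        (3, "CA", 8.0, -0.8, 0.0), (3, "C", 8.2, 0.0, 0.0),
        (4, "N", 10.5, 0.0, 0.0), (4, "H", 10.5, -1.0, 0.0),
        (4, "CA", 10.9, 0.6, 0.0), (4, "C", 11.2, 0.5, 0.0), (4, "O", 11.2, 1.7, 0.0),
        # strand 2 (shifted by dy when pulled apart)
        (21, "C", -1.0, 3.5, 0.0), (21, "O", 0.0, 2.9, 0.0),
        (21, "CA", -1.6, 4.0, 0.0), (21, "N", -2.2, 4.2, 0.0), (21, "H", -2.2, 5.2, 0.0),
        (22, "N", 4.7, 4.6, 0.0), (22, "H", 4.7, 3.6, 0.0),
        (22, "CA", 5.4, 5.2, 0.0), (22, "C", 6.1, 4.9, 0.0),
        (23, "C", 7.9, 3.4, 0.0), (23, "O", 7.0, 2.9, 0.0),
        (23, "CA", 8.4, 4.0, 0.0), (23, "N", 9.0, 4.2, 0.0), (23, "H", 9.0, 5.2, 0.0),
        (24, "N", 11.2, 4.6, 0.0), (24, "H", 11.2, 3.6, 0.0),
        (24, "CA", 11.8, 5.2, 0.0), (24, "C", 12.5, 4.9, 0.0),
    ]
    if not with_hydrogens:
        spec = [s for s in spec if s[1] != "H"]
    atoms = struc.AtomArray(len(spec))
    for i, (rid, name, x, y, z) in enumerate(spec):
        shifted = y + dy if rid >= 21 else y
        atoms.coord[i] = (x, shifted, z)
        atoms.res_id[i] = rid
        atoms.atom_name[i] = name
        atoms.res_name[i] = "GLY"
        atoms.chain_id[i] = "A"
        atoms.element[i] = name[0]
    return atoms


# expected ladder of the ideal sheet: (donor res, acceptor res)
IDEAL_SHEET_BONDS = {(1, 21), (3, 23), (22, 2), (24, 4)}
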