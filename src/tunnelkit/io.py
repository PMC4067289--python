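"""PDB input/output.

Reading goes through Biopython's :class:`Bio.PDB.PDBParser` in strict mode, so
malformed ATOM/HETATM records raise an error naming the offending line.  A
multi-model file becomes an :class:`~tunnelkit.structures.Ensemble` with one
member per MODEL; frame *i* is stamped ``i * time_step_ps``.

Tunnels are written in the Caver sphere convention: one MODEL per tunnel, one
HETATM per sphere, sphere radius in the occupancy column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .structures import (
    Atom,
    CRYSTAL_TIME_PS,
    Ensemble,
    MINIMIZED_TIME_PS,
    Structure,
    TopologyError,
    element_from_name,
    vdw_radius_for,
)

ION_RESNAMES = {"NA", "CL", "ZN", "MG", "K", "CA"}


class PDBParseError(ValueError):
    pass


def _atom_from_biopython(bp_atom, serial: int) -> Atom:
    residue = bp_atom.get_parent()
    chain = residue.get_parent().id
    hetflag, resseq, icode = residue.id
    resname = residue.get_resname().strip()
    element = (bp_atom.element or "").strip().upper()
    if not element:
        element = element_from_name(bp_atom.get_name())
    if resname in ION_RESNAMES and len(residue) == 1:
        element = resname  # monatomic ion: residue name is the element
    return Atom(
        serial=serial,
        name=bp_atom.get_name(),
        element=element,
        residue_id=(chain, resseq, icode.strip()),
        residue_name=resname,
        coord=np.array(bp_atom.get_coord(), dtype=float),
        vdw_radius=vdw_radius_for(element),
        is_hetatm=hetflag.strip() != "",
    )


def read_structures(
    path,
    state_tag: str = "synthetic",
    time_step_ps: float = 100.0,
    source_tag: Optional[str] = None,
    label: Optional[str] = None,
) -> Ensemble:
    """Read a single- or multi-model PDB file into an Ensemble.

    Frames get ``time_ps = model_index * time_step_ps``.  A single-model file
    read with ``source_tag='crystal'`` (or ``'minimized'``) instead gets the
    sentinel time -2 ps (-1 ps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        bp_structure = parser.get_structure(label or path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBParseError(f"{path}: {exc}") from None

    models = list(bp_structure)
    if not models:
        raise PDBParseError(f"{path}: no models found")

    members = []
    n_atoms_ref = None
    for idx, model in enumerate(models):
        atoms = []
        serial = 0
        for bp_atom in model.get_atoms():
            serial += 1
            atoms.append(_atom_from_biopython(bp_atom, serial))
        if n_atoms_ref is None:
            n_atoms_ref = len(atoms)
        elif len(atoms) != n_atoms_ref:
            raise TopologyError(
                f"{path}: model {idx} has {len(atoms)} atoms, expected {n_atoms_ref}"
            )
        tag = source_tag or "frame"
        if tag == "crystal":
            t = CRYSTAL_TIME_PS
        elif tag == "minimized":
            t = MINIMIZED_TIME_PS
        else:
            t = idx * time_step_ps
        name = label or path.stem
        member_label = name if len(models) == 1 else f"{name}#{idx}"
        members.append(Structure(atoms, member_label, t, tag, state_tag))
    return Ensemble(members, name=label or path.stem)


# --------------------------------------------------------------------------
# writing


def _format_atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    icode: str,
    coord,
    occupancy: float,
    bfactor: float,
    element: str,
) -> str:
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial % 100000:>5d} {name_field:<4s} {resname:<3s} "
        f"{(chain or 'A')[:1]}{resseq % 10000:>4d}{(icode or ' ')[:1]}   "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}          {element:>2s}\n"
    )


def write_structures(ensemble_or_structure, path) -> None:
    """Write structure(s) to a (multi-model) PDB file (wwPDB v3.3 columns)."""
    if isinstance(ensemble_or_structure, Structure):
        members = [ensemble_or_structure]
    else:
        members = list(ensemble_or_structure)
    path = Path(path)
    multi = len(members) > 1
    with open(path, "w") as fh:
        for i, s in enumerate(members):
            if multi:
                fh.write(f"MODEL     {i + 1:>4d}\n")
            for a in s.atoms:
                chain, resseq, icode = a.residue_id
                fh.write(
                    _format_atom_line(
                        "HETATM" if a.is_hetatm else "ATOM",
                        a.serial,
                        a.name,
                        a.residue_name,
                        str(chain),
                        int(resseq),
                        str(icode),
                        a.coord,
                        1.00,
                        0.00,
                        a.element[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_tunnels_pdb(tunnels: Sequence, path) -> None:
    """Write tunnels as sphere files: one MODEL per tunnel, radius in occupancy."""
    path = Path(path)
    if not tunnels:
        warnings.warn("write_tunnels_pdb called with no tunnels; nothing written")
        return
    with open(path, "w") as fh:
        for i, t in enumerate(tunnels):
            fh.write(f"MODEL     {i + 1:>4d}\n")
            for j, (center, radius) in enumerate(zip(t.centers, t.radii), start=1):
                fh.write(
                    _format_atom_line(
                        "HETATM", j, "S", "TUN", "T", i + 1, " ",
                        center, float(radius), 0.00, "S",
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_tunnels_pdb(path, sources: Optional[Sequence[tuple]] = None) -> list:
    """Read a sphere file written by :func:`write_tunnels_pdb` back into Tunnels.

    ``sources`` optionally supplies ``(label, time_ps)`` per tunnel.
    """
    from .tunnelfinder import Tunnel

    tunnels = []
    centers: list = []
    radii: list = []

    def flush():
        if centers:
            idx = len(tunnels)
            label, t = ("", 0.0)
            if sources is not None and idx < len(sources):
                label, t = sources[idx]
            tunnels.append(
                Tunnel(
                    centers=np.array(centers, float),
                    radii=np.array(radii, float),
                    source_label=label,
                    source_time_ps=t,
                )
            )
            centers.clear()
            radii.clear()

    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                flush()
            elif line.startswith(("ATOM", "HETATM")):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ = float(line[54:60])
                except ValueError:
                    raise PDBParseError(f"{path}: bad sphere record: {line.rstrip()}")
                centers.append((x, y, z))
                radii.append(occ)
    flush()
    return tunnels


def write_manifest(ensemble: Ensemble, path) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble.manifest(), fh, indent=2)
        fh.write("\n")
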