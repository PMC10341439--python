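"""Readers and writers for multi-frame coordinate data and result tables.

Supported inputs:

* multi-model PDB (``MODEL``/``ENDMDL`` records), read through MDAnalysis;
* concatenated GRO frames (several single-frame GRO blocks appended to one
  file; nm converted to Å on read);
* the package's own plain-text xyz-frames format (extension ``.mxf``):
  per frame one header line ``natoms Dx Dy Dz`` followed by one line per
  atom, ``species residue x y z charge mass tags`` with tags comma-joined
  (``-`` when empty), frames concatenated.

Species/residue labels in generic files carry no role tags or charges, so
those come from a sidecar mapping (YAML or dict), e.g.::

    residues:
      POPE: {tags: [lipid]}
    species:
      P:    {tags: [phosphate_P], charge: 1.1, mass: 30.97}
      K+:   {tags: [ion], charge: 1.0, mass: 39.10}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ensemble import FrameEnsemble

__all__ = ["load_frames", "write_frames", "write_report", "apply_tag_map"]

_FORMATS = ("pdb_multimodel", "gro_stream", "xyz_frames", "auto")


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        return "pdb_multimodel"
    if suffix == ".gro":
        return "gro_stream"
    if suffix in (".mxf", ".xyzf"):
        return "xyz_frames"
    with open(path) as fh:
        head = fh.readline()
    if head.startswith(("MODEL", "ATOM", "HETATM", "CRYST1", "REMARK", "TITLE")):
        return "pdb_multimodel"
    parts = head.split()
    if len(parts) == 4:
        try:
            [float(p) for p in parts]
            return "xyz_frames"
        except ValueError:
            pass
    return "gro_stream"


def load_frames(
    path,
    format_hint: str = "auto",
    tag_map: Mapping | str | Path | None = None,
) -> FrameEnsemble:
    """Read a multi-frame coordinate file into a :class:`FrameEnsemble`.

    Parameters
    ----------
    path
        Input file.
    format_hint
        One of ``pdb_multimodel``, ``gro_stream``, ``xyz_frames`` or
        ``auto`` (sniff from extension/content).
    tag_map
        Sidecar mapping (dict or YAML path) assigning tags/charges/masses
        by residue and species label; required for meaningful selections
        on PDB/GRO inputs, ignored fields already present in ``.mxf``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint not in _FORMATS:
        raise ValueError(f"format_hint must be one of {_FORMATS}")
    fmt = _sniff_format(path) if format_hint == "auto" else format_hint
    if fmt == "pdb_multimodel":
        ens = _read_pdb_multimodel(path)
    elif fmt == "gro_stream":
        ens = _read_gro_stream(path)
    else:
        ens = _read_xyz_frames(path)
    if tag_map is not None:
        ens = apply_tag_map(ens, tag_map)
    return ens


def _read_pdb_multimodel(path: Path) -> FrameEnsemble:
    import warnings

    import MDAnalysis as mda

    # a single header CRYST1 (outside MODEL blocks) applies to all frames
    header_box = None
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("CRYST1"):
                header_box = np.array(
                    [float(ln[6:15]), float(ln[15:24]), float(ln[24:33])]
                )
                break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = []
        box = []
        for _ in u.trajectory:
            coords.append(u.atoms.positions.astype(float).copy())
            if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
                box.append(u.dimensions[:3].astype(float).copy())
            elif header_box is not None:
                box.append(header_box.copy())
            else:
                raise ValueError(f"{path}: no box (CRYST1) record")
        species = np.array([a.name for a in u.atoms], dtype=object)
        residues = np.array([a.resname for a in u.atoms], dtype=object)
    n_atoms = len(species)
    return FrameEnsemble(
        coords=np.asarray(coords),
        box=np.asarray(box),
        species=species,
        residues=residues,
        charges=np.zeros(n_atoms),
        masses=np.zeros(n_atoms),
        tags=[frozenset()] * n_atoms,
    )


def _read_gro_stream(path: Path) -> FrameEnsemble:
    # Fixed-column GRO: title / natoms / natoms atom lines / box (nm).
    lines = path.read_text().splitlines()
    coords, box = [], []
    species = residues = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}: malformed GRO frame at line {i + 1}") from err
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ValueError(f"{path}: truncated GRO frame")
        frame_species, frame_res, xyz = [], [], []
        for ln in atom_lines:
            frame_res.append(ln[5:10].strip())
            frame_species.append(ln[10:15].strip())
            xyz.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
        box_parts = lines[i + 2 + natoms].split()
        if len(box_parts) < 3:
            raise ValueError(f"{path}: missing GRO box line")
        if species is None:
            species, residues = frame_species, frame_res
        elif len(frame_species) != len(species):
            raise ValueError(f"{path}: inconsistent atom counts across frames")
        coords.append(np.asarray(xyz) * 10.0)  # nm -> Å
        box.append([float(b) * 10.0 for b in box_parts[:3]])
        i += 3 + natoms
    if not coords:
        raise ValueError(f"{path}: no frames found")
    n_atoms = len(species)
    return FrameEnsemble(
        coords=np.asarray(coords),
        box=np.asarray(box),
        species=np.array(species, dtype=object),
        residues=np.array(residues, dtype=object),
        charges=np.zeros(n_atoms),
        masses=np.zeros(n_atoms),
        tags=[frozenset()] * n_atoms,
    )


def _read_xyz_frames(path: Path) -> FrameEnsemble:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    coords, box = [], []
    species = residues = charges = masses = tags = None
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 4:
            raise ValueError(f"{path}: bad frame header at line {i + 1}")
        natoms = int(head[0])
        frame_box = [float(v) for v in head[1:]]
        atom_lines = lines[i + 1 : i + 1 + natoms]
        if len(atom_lines) < natoms:
            raise ValueError(f"{path}: truncated frame")
        f_species, f_res, f_xyz, f_q, f_m, f_tags = [], [], [], [], [], []
        for ln in atom_lines:
            parts = ln.split()
            if len(parts) != 8:
                raise ValueError(f"{path}: bad atom line {ln!r}")
            f_species.append(parts[0])
            f_res.append(parts[1])
            f_xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            f_q.append(float(parts[5]))
            f_m.append(float(parts[6]))
            f_tags.append(
                frozenset() if parts[7] == "-" else frozenset(parts[7].split(","))
            )
        if species is None:
            species, residues, charges, masses, tags = f_species, f_res, f_q, f_m, f_tags
        elif len(f_species) != len(species):
            raise ValueError(f"{path}: inconsistent atom counts across frames")
        coords.append(f_xyz)
        box.append(frame_box)
        i += 1 + natoms
    if not coords:
        raise ValueError(f"{path}: no frames found")
    return FrameEnsemble(
        coords=np.asarray(coords, dtype=float),
        box=np.asarray(box),
        species=np.array(species, dtype=object),
        residues=np.array(residues, dtype=object),
        charges=np.asarray(charges, dtype=float),
        masses=np.asarray(masses, dtype=float),
        tags=tags,
    )


def write_frames(ensemble: FrameEnsemble, path) -> Path:
    """Write an ensemble in the internal xyz-frames format (Å, 3 decimals)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            bx, by, bz = ensemble.box[f]
            fh.write(f"{ensemble.n_atoms} {bx:.3f} {by:.3f} {bz:.3f}\n")
            for a in range(ensemble.n_atoms):
                x, y, z = ensemble.coords[f, a]
                tag_str = ",".join(sorted(ensemble.tags[a])) or "-"
                fh.write(
                    f"{ensemble.species[a]} {ensemble.residues[a]} "
                    f"{x:.3f} {y:.3f} {z:.3f} "
                    f"{ensemble.charges[a]:.6g} {ensemble.masses[a]:.6g} {tag_str}\n"
                )
    return path


def apply_tag_map(ensemble: FrameEnsemble, tag_map: Mapping | str | Path) -> FrameEnsemble:
    """Return a copy of the ensemble with tags/charges/masses from a sidecar map.

    Residue entries apply first, species entries second (tags union,
    charge/mass override).  Atoms not matched keep their current metadata.
    """
    if isinstance(tag_map, (str, Path)):
        with open(tag_map) as fh:
            tag_map = yaml.safe_load(fh)
    by_res = tag_map.get("residues", {}) or {}
    by_species = tag_map.get("species", {}) or {}
    tags = [set(t) for t in ensemble.tags]
    charges = ensemble.charges.copy()
    masses = ensemble.masses.copy()
    for i in range(ensemble.n_atoms):
        for source, key in ((by_res, ensemble.residues[i]), (by_species, ensemble.species[i])):
            entry = source.get(key)
            if entry is None:
                continue
            tags[i] |= set(entry.get("tags", []))
            if "charge" in entry:
                charges[i] = float(entry["charge"])
            if "mass" in entry:
                masses[i] = float(entry["mass"])
    return FrameEnsemble(
        coords=ensemble.coords,
        box=ensemble.box,
        species=ensemble.species,
        residues=ensemble.residues,
        charges=charges,
        masses=masses,
        tags=[frozenset(t) for t in tags],
    )


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def write_report(tables: Mapping[str, pd.DataFrame], outdir) -> dict:
    """Write named tables as CSV plus one JSON summary; byte-stable output.

    Floats are formatted to 6 significant digits so identical inputs give
    byte-identical files.  Returns a dict of written paths.
    """
    if not tables:
        raise ValueError("no tables to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    summary = {}
    for name in sorted(tables):
        df = tables[name]
        if df is None or len(df) == 0:
            raise ValueError(f"table {name!r} is empty")
        formatted = df.copy()
        for col in formatted.columns:
            formatted[col] = [_format_value(v) for v in formatted[col]]
        csv_path = outdir / f"{name}.csv"
        formatted.to_csv(csv_path, index=False, lineterminator="\n")
        written[name] = csv_path
        summary[name] = {"rows": int(len(df)), "columns": list(map(str, df.columns))}
    json_path = outdir / "report_summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["summary"] = json_path
    return written
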